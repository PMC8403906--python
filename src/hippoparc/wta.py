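"""Winner-take-all parcellation of hippocampal voxels.

Each voxel is assigned to the cortical network with the greatest *positive*
Fisher-z connectivity among a candidate set; voxels with no positive
candidate remain unassigned. A runner-up network is recorded when its
connectivity reaches a fixed fraction (default 66%) of the winner's. The
two-alternative "forced choice" variant assigns every voxel to the stronger
member of a network pair regardless of sign (weak winners, z <= 0, are
flagged rather than dropped).

Organised statsmodels-style: :class:`WinnerTakeAll` is the model,
:meth:`WinnerTakeAll.fit` returns a :class:`WtaParcellation` results object.
Module-level ``winner_take_all``/``forced_choice`` are thin conveniences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import VoxelNetworkFC

__all__ = ["UNASSIGNED", "WinnerTakeAll", "WtaParcellation",
           "winner_take_all", "forced_choice"]

#: sentinel label for voxels with no positive candidate (or invalid upstream)
UNASSIGNED = -1


class WinnerTakeAll:
    """Winner-take-all model over a voxel x network connectivity matrix.

    Parameters
    ----------
    fc : VoxelNetworkFC
    candidates : iterable of int, optional
        Candidate network labels (default: all networks in ``fc``). At least
        two unless ``allow_single=True``.
    pair : (int, int), optional
        Run in two-alternative forced-choice mode restricted to this pair;
        positivity is then not required and weak winners are flagged.
    runner_up_fraction : float, optional
        When given, annotate each assigned voxel with the best non-winner
        candidate whose positive z is at least this fraction of the winner's.
    hemisphere : array-like, optional
        Per-voxel 'L'/'R', enabling by-hemisphere proportions.
    """

    def __init__(self, fc: VoxelNetworkFC, candidates=None, *, pair=None,
                 runner_up_fraction: float | None = None, hemisphere=None,
                 allow_single: bool = False):
        self.fc = fc
        self.pair = None
        if pair is not None:
            a, b = (int(pair[0]), int(pair[1]))
            if a == b:
                raise ValueError("forced-choice pair must be two distinct labels")
            self.pair = (a, b)
            candidates = [a, b]
        if candidates is None:
            candidates = fc.labels.tolist()
        self.candidates = np.asarray(sorted(int(c) for c in candidates), dtype=int)
        missing = set(self.candidates.tolist()) - set(fc.labels.tolist())
        if missing:
            raise ValueError(f"candidate networks {sorted(missing)} not in FC matrix")
        if self.candidates.size < 2 and not allow_single:
            raise ValueError("need at least 2 candidate networks (or allow_single=True)")
        if runner_up_fraction is not None and not 0.0 < runner_up_fraction <= 1.0:
            raise ValueError("runner_up_fraction must lie in (0, 1]")
        self.runner_up_fraction = runner_up_fraction
        self.hemisphere = None if hemisphere is None else np.asarray(hemisphere)

    def fit(self) -> "WtaParcellation":
        z = np.column_stack([self.fc.column(c) for c in self.candidates])
        n = z.shape[0]
        # argmax over ascending labels -> ties break to the lowest label
        order = np.argmax(z, axis=1)
        strength = z[np.arange(n), order]
        ties = (z == strength[:, None]).sum(axis=1) > 1
        if ties.any():
            warnings.warn(f"{int(ties.sum())} voxel(s) had tied winners; "
                          "assigned to the lowest network label")
        winner = self.candidates[order]
        weak = np.zeros(n, dtype=bool)
        if self.pair is None:
            # strict reading of "greatest positive": all-negative -> unassigned
            winner = np.where(strength > 0, winner, UNASSIGNED)
        else:
            weak = strength <= 0
            if weak.any():
                warnings.warn(f"{int(weak.sum())} forced-choice voxel(s) have "
                              "non-positive winner connectivity (flagged weak)")
        winner = np.where(self.fc.valid, winner, UNASSIGNED)
        strength = np.where(winner == UNASSIGNED, np.nan, strength)

        runner = np.full(n, UNASSIGNED, dtype=int)
        if self.runner_up_fraction is not None:
            z_masked = z.copy()
            z_masked[np.arange(n), order] = -np.inf  # drop the winner column
            ru_order = np.argmax(z_masked, axis=1)
            ru_strength = z_masked[np.arange(n), ru_order]
            ok = (
                (winner != UNASSIGNED)
                & (ru_strength > 0)
                & (ru_strength >= self.runner_up_fraction * strength)
            )
            runner[ok] = self.candidates[ru_order[ok]]

        return WtaParcellation(
            labels=winner,
            strength=strength,
            runner_up=runner,
            weak_winner=weak,
            candidates=self.candidates,
            pair=self.pair,
            fc=self.fc,
            hemisphere=self.hemisphere,
        )


@dataclass
class WtaParcellation:
    """Results of a winner-take-all fit.

    ``labels`` holds the winner network per voxel (:data:`UNASSIGNED` where no
    candidate had positive connectivity in multi-network mode, or where the
    voxel was invalid upstream); ``strength`` the winner's z(r); ``runner_up``
    the second-place network (``UNASSIGNED`` when none qualified).
    """

    labels: np.ndarray
    strength: np.ndarray
    runner_up: np.ndarray
    weak_winner: np.ndarray
    candidates: np.ndarray
    pair: tuple | None
    fc: VoxelNetworkFC | None = None
    hemisphere: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return self.labels.shape[0]

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    def mask(self, label: int) -> np.ndarray:
        """Boolean parcel mask for one winner network."""
        return self.labels == int(label)

    def masks(self) -> dict[int, np.ndarray]:
        """Binary parcel masks for every candidate network."""
        return {int(c): self.mask(c) for c in self.candidates}

    def proportions(self, by_hemisphere: bool = False, over: str = "assigned") -> dict:
        """Fraction of voxels won by each network.

        ``over='assigned'`` normalises by assigned voxels (so fractions sum
        to 1); ``over='all'`` by the full voxel count, leaving an implicit
        unassigned remainder. With ``by_hemisphere`` the result is keyed
        ``{'L': {...}, 'R': {...}}``.
        """
        if over not in ("assigned", "all"):
            raise ValueError("over must be 'assigned' or 'all'")
        if by_hemisphere:
            if self.hemisphere is None:
                raise ValueError("no hemisphere labels attached to this parcellation")
            return {
                h: self._props(self.hemisphere == h, over)
                for h in np.unique(self.hemisphere)
            }
        return self._props(np.ones(self.n_voxels, dtype=bool), over)

    def _props(self, sel: np.ndarray, over: str) -> dict:
        assigned = self.assigned & sel
        if not assigned.any():
            raise ValueError("no assigned voxels in selection")
        denom = int(sel.sum()) if over == "all" else int(assigned.sum())
        return {
            int(c): float((self.labels[assigned] == c).sum() / denom)
            for c in self.candidates
        }

    def anterior_fraction(self, label: int) -> float:
        """Fraction of assigned voxels won by ``label`` -- for an anterior
        parcel this is the anterior fraction of the structure it occupies."""
        assigned = self.assigned
        if not assigned.any():
            raise ValueError("no assigned voxels")
        return float((self.labels[assigned] == int(label)).sum() / assigned.sum())

    def mean_strength(self) -> dict[int, float]:
        """Mean winner-network z(r) over each parcel's voxels."""
        out = {}
        for c in self.candidates:
            sel = self.mask(c)
            if sel.any():
                out[int(c)] = float(np.nanmean(self.strength[sel]))
        return out

    def verify_strength(self, floor: float = 0.2) -> dict:
        """Check each parcel's mean winner connectivity against a z(r) floor."""
        means = self.mean_strength()
        return {
            label: {"mean_z": mz, "floor": float(floor), "pass": bool(mz >= floor)}
            for label, mz in means.items()
        }

    def summary(self) -> str:
        lines = ["Winner-take-all parcellation"]
        mode = f"forced-choice {self.pair}" if self.pair else \
            f"multi-network over {self.candidates.tolist()}"
        lines.append(f"  mode: {mode}")
        lines.append(f"  voxels: {self.n_voxels} ({int(self.assigned.sum())} assigned)")
        props = self.proportions()
        for label, frac in sorted(props.items()):
            lines.append(f"  network {label}: {frac:6.1%} of assigned voxels")
        if self.weak_winner.any():
            lines.append(f"  weak (z<=0) winners flagged: {int(self.weak_winner.sum())}")
        return "\n".join(lines)


def winner_take_all(fc: VoxelNetworkFC, candidates=None, **kw) -> WtaParcellation:
    """Multi-network winner-take-all (see :class:`WinnerTakeAll`)."""
    return WinnerTakeAll(fc, candidates=candidates, **kw).fit()


def forced_choice(fc: VoxelNetworkFC, pair, **kw) -> WtaParcellation:
    """Two-alternative forced-choice winner-take-all on a network pair."""
    return WinnerTakeAll(fc, pair=pair, **kw).fit()
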