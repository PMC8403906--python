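"""Participant-specific null distributions for parcel-to-network connectivity.

To show that a DMN/PMN forced-choice parcellation did not arise by chance,
the same two-alternative winner-take-all is rerun on every *other* unordered
pair of usable networks; each resulting parcel contributes its mean
winner-network Fisher-z to the null. The observed parcels' means are then
ranked against that null with a +1-corrected empirical p-value,

    p = (1 + #{null >= observed}) / (1 + N),

which never reports p = 0 and makes the resolution limit of a small null
explicit. By default the usable label set is every atlas network minus the
fronto-parietal network (FPN); a narrower set can be configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .connectivity import VoxelNetworkFC
from .wta import forced_choice

__all__ = ["ParcelNullModel", "NullDistribution", "empirical_p"]


def empirical_p(obs: float, null, side: str = "greater") -> float:
    """Rank-based empirical p-value with +1 correction (ties count as >=)."""
    if side != "greater":
        raise ValueError("only side='greater' is defined for this test")
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + (null >= obs).sum()) / (1 + null.size))


class ParcelNullModel:
    """Null model for one observed forced-choice pair.

    Parameters
    ----------
    fc : VoxelNetworkFC
    observed_pair : (int, int)
        The pair whose parcels are being tested (e.g. DMN, PMN labels).
    labels : iterable of int, optional
        Usable network labels (default: all labels in ``fc``).
    excluded : iterable of int, optional
        Labels removed from the pair set before enumeration (default: none).
    """

    def __init__(self, fc: VoxelNetworkFC, observed_pair, labels=None, excluded=()):
        self.fc = fc
        self.observed_pair = tuple(sorted(int(x) for x in observed_pair))
        pool = set(int(l) for l in (labels if labels is not None else fc.labels))
        self.excluded = set(int(l) for l in excluded)
        self.usable = sorted((pool - self.excluded) | set(self.observed_pair))
        if len(self.usable) < 3:
            raise ValueError("need at least 3 usable labels to form a null")

    def fit(self) -> "NullDistribution":
        rows = []
        for pair in combinations(self.usable, 2):
            if pair == self.observed_pair:
                continue
            rows.extend(self._pair_means(pair))
        if not rows:
            raise ValueError("null distribution is empty (all pairs degenerate)")
        observed = dict(self._obs_means())
        entries = pd.DataFrame(rows, columns=["pair_a", "pair_b", "parcel_label", "mean_z"])
        p_values = {
            label: empirical_p(mz, entries["mean_z"].to_numpy())
            for label, mz in observed.items()
        }
        return NullDistribution(
            entries=entries,
            observed=observed,
            p_values=p_values,
            observed_pair=self.observed_pair,
            excluded_labels=frozenset(self.excluded),
        )

    def _pair_means(self, pair):
        with warnings.catch_warnings():
            # weak winners are the norm for irrelevant network pairs
            warnings.filterwarnings("ignore", message=".*non-positive winner.*")
            parc = forced_choice(self.fc, pair)
        out = []
        for label in pair:
            sel = parc.mask(label)
            if not sel.any():
                warnings.warn(f"pair {pair}: parcel {label} empty, entry skipped")
                continue
            out.append((pair[0], pair[1], label, float(np.nanmean(parc.strength[sel]))))
        return out

    def _obs_means(self):
        parc = forced_choice(self.fc, self.observed_pair)
        for label in self.observed_pair:
            sel = parc.mask(label)
            if not sel.any():
                raise ValueError(f"observed parcel {label} is empty")
            yield int(label), float(np.nanmean(parc.strength[sel]))


@dataclass
class NullDistribution:
    """Null entries, observed parcel means and their empirical p-values."""

    entries: pd.DataFrame
    observed: dict
    p_values: dict
    observed_pair: tuple
    excluded_labels: frozenset

    @property
    def n_null(self) -> int:
        return len(self.entries)

    def summary(self) -> str:
        lines = [
            f"Parcel null model (observed pair {self.observed_pair}, "
            f"{self.n_null} null values, excluded {sorted(self.excluded_labels)})"
        ]
        for label in sorted(self.observed):
            lines.append(
                f"  parcel {label}: mean z(r) = {self.observed[label]:.4f}, "
                f"empirical p = {self.p_values[label]:.4g} "
                f"(resolution 1/{self.n_null + 1})"
            )
        return "\n".join(lines)
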