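"""Finite-impulse-response (FIR) task GLM and deactivation contrasts.

Event responses are modelled with delta-function regressors at each of eight
post-onset frames per condition (no assumed haemodynamic shape), plus a
sustained block regressor and an intercept; the baseline is otherwise
unmodelled. Deactivation is summarised by the contrast "mean of the 3rd and
4th post-onset timepoints over all conditions" -- where the haemodynamic
response peaks -- and z-scored across sessions (mean over session estimates
divided by its standard error). Group comparison of DMN vs PMN deactivation
uses a paired, two-sided sign-flip permutation across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BoldMatrix

__all__ = ["FirDesign", "build_fir_design", "GlmFit", "fit_glm",
           "DeactivationContrast", "deactivation_contrast",
           "region_deactivation_compare"]


@dataclass
class FirDesign:
    """FIR regressor matrix with named columns."""

    matrix: np.ndarray       # (n_frames, p)
    names: list              # column names, e.g. 'task:lag3', 'block', 'intercept'
    conditions: list         # event condition names
    n_lags: int

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def event_columns(self, lags=None, conditions=None) -> np.ndarray:
        """Indices of event-lag columns, optionally filtered by 1-indexed lag
        and/or condition name."""
        idx = []
        for k, name in enumerate(self.names):
            if ":" not in name:
                continue
            cond, lag = name.split(":lag")
            if lags is not None and int(lag) not in lags:
                continue
            if conditions is not None and cond not in conditions:
                continue
            idx.append(k)
        return np.asarray(idx, dtype=int)


def build_fir_design(
    events: pd.DataFrame,
    n_frames: int,
    n_lags: int = 8,
    blocks=None,
    include_intercept: bool = True,
) -> FirDesign:
    """Assemble the FIR design matrix.

    ``events`` needs columns ``condition`` and ``onset_frame``. For every
    condition, column ``cond:lagK`` (K = 1..n_lags) is 1 at frames
    ``onset + K - 1``; overlapping events sum. ``blocks`` is an iterable of
    ``(start, stop)`` frame spans covered by one sustained regressor. A rank
    deficiency raises, listing the collinear columns.
    """
    if n_lags < 1:
        raise ValueError("need at least one lag")
    conditions = sorted(events["condition"].unique())
    cols, names = [], []
    for cond in conditions:
        onsets = events.loc[events["condition"] == cond, "onset_frame"].to_numpy(int)
        if (onsets < 0).any() or (onsets + n_lags > n_frames).any():
            raise ValueError(f"condition {cond}: events do not fit within the run")
        for k in range(1, n_lags + 1):
            c = np.zeros(n_frames)
            np.add.at(c, onsets + k - 1, 1.0)
            cols.append(c)
            names.append(f"{cond}:lag{k}")
    if blocks:
        c = np.zeros(n_frames)
        for b0, b1 in blocks:
            if not 0 <= b0 < b1 <= n_frames:
                raise ValueError("block outside run")
            c[b0:b1] = 1.0
        cols.append(c)
        names.append("block")
    if include_intercept:
        cols.append(np.ones(n_frames))
        names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via the QR diagonal
        _, r = np.linalg.qr(X)
        bad = [names[k] for k in np.flatnonzero(np.abs(np.diag(r)) < 1e-10)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return FirDesign(matrix=X, names=names, conditions=conditions, n_lags=n_lags)


@dataclass
class GlmFit:
    """Per-unit OLS estimates for one session."""

    betas: np.ndarray        # (p, n_units)
    resid_var: np.ndarray    # (n_units,)
    df_resid: int
    design: FirDesign


def fit_glm(bold: BoldMatrix, design: FirDesign) -> GlmFit:
    """Ordinary least squares per unit (voxel or vertex)."""
    X = design.matrix
    if bold.n_timepoints != X.shape[0]:
        raise ValueError("BOLD and design frame counts differ")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    betas, _, _, _ = np.linalg.lstsq(X, bold.data, rcond=None)
    resid = bold.data - X @ betas
    df = bold.n_timepoints - X.shape[1]
    resid_var = (resid**2).sum(axis=0) / max(df, 1)
    return GlmFit(betas=betas, resid_var=resid_var, df_resid=df, design=design)


@dataclass
class DeactivationContrast:
    """Session-level deactivation contrasts and their across-session z-score."""

    per_session: np.ndarray  # (n_sessions, n_units)
    mean: np.ndarray         # (n_units,)
    z: np.ndarray            # mean / SE across sessions (NaN when undefined)
    flags: list

    @property
    def n_sessions(self) -> int:
        return self.per_session.shape[0]


def deactivation_contrast(
    fits, timepoints=(3, 4), include_cues: bool = True
) -> DeactivationContrast:
    """Mean of the FIR betas at the given 1-indexed timepoints, over all
    event conditions, per session; z-scored across sessions.

    ``include_cues=False`` drops conditions whose name starts with 'cue'.
    With a single session (or zero variance across sessions) the raw contrast
    is returned with the z flagged undefined.
    """
    if not fits:
        raise ValueError("need at least one session fit")
    rows = []
    for fit in fits:
        design = fit.design
        conds = design.conditions
        if not include_cues:
            conds = [c for c in conds if not c.startswith("cue")]
        idx = design.event_columns(lags=set(timepoints), conditions=conds)
        if idx.size == 0:
            raise ValueError("no event columns match the contrast definition")
        rows.append(fit.betas[idx].mean(axis=0))
    per_session = np.vstack(rows)
    mean = per_session.mean(axis=0)
    flags = []
    n = per_session.shape[0]
    if n < 2:
        flags.append("single session: z undefined, raw contrast returned")
        z = np.full(mean.shape, np.nan)
    else:
        se = per_session.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = mean / se
        if (se == 0).any():
            flags.append("zero across-session SE for some units: z undefined there")
            z = np.where(se == 0, np.nan, z)
    return DeactivationContrast(per_session=per_session, mean=mean, z=z, flags=flags)


def region_deactivation_compare(
    contrast_maps,
    region_masks: dict,
    scope_mask=None,
    n_flips: int = 10000,
    seed: int | None = None,
    regions: tuple = ("DMN", "PMN"),
) -> dict:
    """Compare mean deactivation between two region classes across subjects.

    ``contrast_maps`` is a list of per-unit contrast vectors (one per
    subject); ``region_masks`` maps region name -> boolean unit mask; the
    optional ``scope_mask`` restricts the comparison (whole cortex, medial
    parietal, hippocampus ...). With >= 2 subjects a paired two-sided
    sign-flip permutation of the per-subject differences is run.
    """
    a, b = regions
    n_subjects = len(contrast_maps)
    if n_subjects == 0:
        raise ValueError("no subjects")
    means = {a: [], b: []}
    for cmap in contrast_maps:
        cmap = np.asarray(cmap, dtype=float)
        for name in regions:
            sel = np.asarray(region_masks[name], dtype=bool)
            if scope_mask is not None:
                sel = sel & np.asarray(scope_mask, dtype=bool)
            if not sel.any():
                raise ValueError(f"region {name} empty within the requested scope")
            means[name].append(float(np.nanmean(cmap[sel])))
    means = {k: np.asarray(v) for k, v in means.items()}
    diffs = means[a] - means[b]
    result = {
        f"mean_{a}": float(means[a].mean()),
        f"mean_{b}": float(means[b].mean()),
        "mean_difference": float(diffs.mean()),
        "n_subjects": n_subjects,
        "p_value": None,
    }
    if n_subjects < 2:
        warnings.warn("single subject: means only, no test")
        return result
    rng = np.random.default_rng(seed)
    obs = abs(diffs.mean())
    flips = rng.choice([-1.0, 1.0], size=(n_flips, n_subjects))
    perm = np.abs((flips * diffs).mean(axis=1))
    result["p_value"] = float((1 + (perm >= obs).sum()) / (1 + n_flips))
    result["n_flips"] = int(n_flips)
    result["seed"] = seed
    return result
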