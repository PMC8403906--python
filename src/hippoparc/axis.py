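"""Longitudinal-axis coordinates and gradient-vs-parcel variance partition.

The scientific question: is the anterior-posterior organisation of
hippocampal connectivity better described as a smooth *gradient* or as
discrete *parcels*? Per voxel the response is the connectivity difference
dFC = z(r to DMN) - z(r to PMN). Three OLS models are fitted:

    gradient only : dFC ~ 1 + axis
    parcel only   : dFC ~ 1 + parcel
    full          : dFC ~ 1 + axis + parcel

and each factor's semi-partial r-squared is the full-model r2 minus the r2 of
the model lacking that factor, with a partial F test for the increment. The
"ANOVA with a continuous regressor" is thus an ordinary regression r2;
continuous mm coordinates are the default, with per-slice binning available.

Axis coordinates are oriented so the anterior end maps to 0 and values grow
toward the posterior; hemispheres are handled separately (their point clouds
are disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .connectivity import VoxelNetworkFC
from .data import HippocampusMask

__all__ = ["AxisAssignment", "axis_coordinates", "delta_fc",
           "AxisVariancePartition", "AxisModelResult"]

#: default anatomical-anterior direction in world space (RAS: +y = anterior)
ANTERIOR_RAS = (0.0, 1.0, 0.0)


@dataclass
class AxisAssignment:
    """Per-voxel longitudinal-axis coordinate (mm; anterior = 0)."""

    coord: np.ndarray
    hemisphere: np.ndarray
    method: str
    basis: dict  # hemisphere -> unit axis vector

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        spans = [np.ptp(self.coord[self.hemisphere == h]) for h in np.unique(self.hemisphere)]
        if any(s <= 0 for s in spans):
            raise ValueError("axis coordinates must span a positive length")

    def normalized(self) -> np.ndarray:
        """Coordinates rescaled to [0, 1] within each hemisphere."""
        out = np.empty_like(self.coord)
        for h in np.unique(self.hemisphere):
            sel = self.hemisphere == h
            c = self.coord[sel]
            out[sel] = (c - c.min()) / np.ptp(c)
        return out


def axis_coordinates(
    hippo: HippocampusMask,
    method: str = "pca",
    anterior_direction=ANTERIOR_RAS,
) -> AxisAssignment:
    """Assign each voxel a coordinate along the longitudinal (A-P) axis.

    ``method='pca'`` takes the first principal axis of the voxel world
    coordinates per hemisphere; ``method='y_axis'`` projects directly onto
    the world A-P direction. The sign is fixed so the anatomically anterior
    end (larger projection on ``anterior_direction``) maps to lower values,
    and the anterior end is offset to coordinate 0.
    """
    d = np.asarray(anterior_direction, dtype=float)
    d = d / np.linalg.norm(d)
    world = hippo.world_coords
    coord = np.empty(hippo.n_voxels)
    basis = {}
    for h in np.unique(hippo.hemisphere):
        sel = hippo.hemisphere == h
        pts = world[sel]
        if pts.shape[0] < 3:
            raise ValueError(f"hemisphere {h}: need at least 3 voxels")
        anteriorness = pts @ d
        if method == "y_axis":
            u = d.copy()
            proj = anteriorness
        elif method == "pca":
            centred = pts - pts.mean(axis=0)
            cov = centred.T @ centred
            if np.allclose(cov, 0):
                raise ValueError(f"hemisphere {h}: degenerate (zero-extent) voxel cloud")
            w, v = np.linalg.eigh(cov)
            u = v[:, -1]  # first principal axis
            proj = pts @ u
            if np.ptp(proj) == 0:
                raise ValueError(f"hemisphere {h}: degenerate voxel cloud")
            # orient the axis to point anterior (so anterior gets low values below)
            c = np.cov(proj, anteriorness)[0, 1]
            if c < 0:
                u, proj = -u, -proj
            elif c == 0:
                raise ValueError(
                    f"hemisphere {h}: principal axis orthogonal to the anterior "
                    "direction; orientation is ambiguous"
                )
        else:
            raise ValueError("method must be 'pca' or 'y_axis'")
        # anterior (large projection on the anterior direction) -> coordinate 0
        coord[sel] = proj.max() - proj
        basis[str(h)] = -u  # stored basis points anterior -> posterior
    return AxisAssignment(coord=coord, hemisphere=hippo.hemisphere,
                          method=method, basis=basis)


def delta_fc(fc: VoxelNetworkFC, pair) -> np.ndarray:
    """Per-voxel dFC = z(first label) - z(second label); NaN where invalid."""
    a, b = pair
    d = fc.column(a) - fc.column(b)
    return np.where(fc.valid, d, np.nan)


def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    model = sm.OLS(y, X).fit()
    return float(model.rsquared), int(X.shape[1])


class AxisVariancePartition:
    """OLS variance partition of dFC into gradient and parcel factors.

    Parameters
    ----------
    delta : array-like
        Per-voxel dFC (NaNs dropped with their voxels).
    axis_coord : array-like
        Longitudinal-axis coordinate per voxel.
    parcel : array-like
        Parcel identity per voxel (binary indicator after coding); a
        single-parcel input yields a gradient-only result, flagged.
    bins : int, optional
        When given, the axis coordinate is replaced by per-slice bin centres
        (the discretised coding variant).
    """

    def __init__(self, delta, axis_coord, parcel, bins: int | None = None):
        delta = np.asarray(delta, dtype=float)
        axis_coord = np.asarray(axis_coord, dtype=float)
        parcel = np.asarray(parcel)
        keep = np.isfinite(delta)
        self.delta = delta[keep]
        self.axis = axis_coord[keep]
        self.parcel = parcel[keep]
        if self.delta.size < 3:
            raise ValueError("need at least 3 voxels")
        if bins is not None:
            edges = np.linspace(self.axis.min(), self.axis.max(), bins + 1)
            centres = 0.5 * (edges[:-1] + edges[1:])
            idx = np.clip(np.digitize(self.axis, edges[1:-1]), 0, bins - 1)
            self.axis = centres[idx]
        levels = np.unique(self.parcel)
        self.single_parcel = levels.size < 2
        if levels.size > 2:
            raise ValueError("parcel factor must be binary (two parcels)")
        self.indicator = (self.parcel == levels[-1]).astype(float)

    def fit(self) -> "AxisModelResult":
        y = self.delta
        n = y.size
        ones = np.ones((n, 1))
        Xg = np.c_[ones, self.axis]
        r2_grad, _ = _r2(y, Xg)
        if self.single_parcel:
            return AxisModelResult(
                n=n, r2_gradient=r2_grad, r2_parcel=np.nan, r2_full=r2_grad,
                sp_gradient=np.nan, sp_parcel=np.nan,
                f_gradient=np.nan, f_parcel=np.nan,
                p_gradient=np.nan, p_parcel=np.nan,
                df_resid=n - 2, gradient_only=True,
                delta=y, axis=self.axis, parcel=self.indicator,
            )
        Xp = np.c_[ones, self.indicator]
        Xf = np.c_[ones, self.axis, self.indicator]
        r2_par, _ = _r2(y, Xp)
        r2_full, p_full = _r2(y, Xf)
        df_resid = n - p_full
        sp_grad = r2_full - r2_par
        sp_par = r2_full - r2_grad

        def partial_f(increment):
            if df_resid <= 0:
                return np.nan, np.nan
            denom = (1.0 - r2_full) / df_resid
            if denom <= 0:
                return np.inf, 0.0
            f = max(increment, 0.0) / 1.0 / denom
            return f, float(stats.f.sf(f, 1, df_resid))

        f_grad, pv_grad = partial_f(sp_grad)
        f_par, pv_par = partial_f(sp_par)
        return AxisModelResult(
            n=n, r2_gradient=r2_grad, r2_parcel=r2_par, r2_full=r2_full,
            sp_gradient=sp_grad, sp_parcel=sp_par,
            f_gradient=f_grad, f_parcel=f_par,
            p_gradient=pv_grad, p_parcel=pv_par,
            df_resid=df_resid, gradient_only=False,
            delta=y, axis=self.axis, parcel=self.indicator,
        )


@dataclass
class AxisModelResult:
    """Gradient/parcel r2 decomposition with partial F tests."""

    n: int
    r2_gradient: float
    r2_parcel: float
    r2_full: float
    sp_gradient: float   # semi-partial r2 of the gradient, controlling parcel
    sp_parcel: float     # semi-partial r2 of the parcel, controlling gradient
    f_gradient: float
    f_parcel: float
    p_gradient: float
    p_parcel: float
    df_resid: int
    gradient_only: bool
    delta: np.ndarray | None = None
    axis: np.ndarray | None = None
    parcel: np.ndarray | None = None

    def to_dict(self) -> dict:
        keys = ["n", "r2_gradient", "r2_parcel", "r2_full", "sp_gradient",
                "sp_parcel", "f_gradient", "f_parcel", "p_gradient",
                "p_parcel", "df_resid", "gradient_only"]
        return {k: getattr(self, k) for k in keys}

    def summary(self) -> str:
        lines = [f"Gradient vs parcel variance partition (n = {self.n} voxels)"]
        lines.append(f"  r2 gradient-only : {self.r2_gradient:.4f}")
        if self.gradient_only:
            lines.append("  single parcel present: parcel terms undefined")
            return "\n".join(lines)
        lines.append(f"  r2 parcel-only   : {self.r2_parcel:.4f}")
        lines.append(f"  r2 full model    : {self.r2_full:.4f}")
        lines.append(
            f"  semi-partial r2  : gradient {self.sp_gradient:.4f} "
            f"(F(1,{self.df_resid}) = {self.f_gradient:.2f}, p = {self.p_gradient:.3g})"
        )
        lines.append(
            f"                     parcel   {self.sp_parcel:.4f} "
            f"(F(1,{self.df_resid}) = {self.f_parcel:.2f}, p = {self.p_parcel:.3g})"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of dFC against the axis coordinate, coloured by parcel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for val, color, name in ((0.0, "tab:red", "anterior parcel"),
                                 (1.0, "tab:blue", "posterior parcel")):
            sel = self.parcel == val
            ax.scatter(self.axis[sel], self.delta[sel], s=8, color=color, label=name)
        ax.set_xlabel("longitudinal axis coordinate (mm, anterior = 0)")
        ax.set_ylabel(r"$\Delta$FC  z(DMN) $-$ z(PMN)")
        ax.legend(frameon=False)
        return ax
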