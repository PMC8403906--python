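"""Voxel-to-network functional connectivity, seed maps and group averages.

All correlations are Pearson r on full concatenated runs, Fisher
z-transformed (``z(r) = atanh(r)``, r clipped to ``1 - 1e-7`` so degenerate
synthetic inputs stay finite). Network time courses are unweighted means over
the cortical vertices of a network that lie beyond an exclusion radius
(default 20 mm, Euclidean in world mm) from any hippocampal voxel centre --
a guard against signal bleed between hippocampus and nearby cortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data import BoldMatrix, CorticalAtlas, HippocampusMask, SeedMap, fisher_z

__all__ = [
    "VoxelNetworkFC",
    "NetworkTimecourses",
    "exclusion_mask",
    "network_timecourses",
    "voxel_network_fc",
    "seed_map",
    "difference_map",
    "group_average",
]


@dataclass
class VoxelNetworkFC:
    """Hippocampal voxel x cortical network Fisher-z connectivity matrix."""

    z: np.ndarray          # (n_voxels, K)
    labels: np.ndarray     # (K,) network labels, ascending
    valid: np.ndarray      # (n_voxels,) False where a zero-variance series occurred

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z.shape != (self.valid.size, self.labels.size):
            raise ValueError("z must be (n_voxels, K)")
        if np.any(np.diff(self.labels) <= 0):
            raise ValueError("network labels must be strictly ascending")

    @property
    def n_voxels(self) -> int:
        return self.z.shape[0]

    def column(self, label: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == int(label))
        if idx.size == 0:
            raise KeyError(f"network {label} not in FC matrix")
        return self.z[:, idx[0]]

    def subset(self, labels) -> "VoxelNetworkFC":
        labels = sorted(int(l) for l in labels)
        cols = [int(np.flatnonzero(self.labels == l)[0]) for l in labels]
        return VoxelNetworkFC(z=self.z[:, cols], labels=np.array(labels), valid=self.valid)


@dataclass
class NetworkTimecourses:
    """Per-network mean cortical BOLD time courses."""

    data: np.ndarray          # (T, K)
    labels: np.ndarray        # (K,)
    n_vertices_included: dict  # label -> count


def exclusion_mask(
    atlas: CorticalAtlas, hippo: HippocampusMask, radius_mm: float = 20.0
) -> np.ndarray:
    """Boolean include-vector: True where a vertex lies strictly more than
    ``radius_mm`` (Euclidean, world mm) from every hippocampal voxel centre.

    Raises if any network loses all of its vertices, naming the network.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    tree = cKDTree(hippo.world_coords)
    dist, _ = tree.query(atlas.coords, k=1)
    include = dist > radius_mm
    for label in atlas.network_labels:
        sel = atlas.labels == label
        if not include[sel].any():
            raise ValueError(
                f"network {int(label)} has no vertices beyond the {radius_mm} mm "
                "exclusion radius"
            )
    return include


def network_timecourses(
    bold_ctx: BoldMatrix,
    atlas: CorticalAtlas,
    include: np.ndarray | None = None,
    networks=None,
) -> NetworkTimecourses:
    """Unweighted mean BOLD time course per network over included vertices."""
    if bold_ctx.n_units != atlas.n_vertices:
        raise ValueError("BOLD column count does not match atlas vertex count")
    if include is None:
        include = np.ones(atlas.n_vertices, dtype=bool)
    labels = np.asarray(sorted(networks) if networks is not None else atlas.network_labels, int)
    cols = np.empty((bold_ctx.n_timepoints, labels.size))
    counts = {}
    for j, label in enumerate(labels):
        sel = (atlas.labels == label) & include
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"network {int(label)} has no included vertices")
        cols[:, j] = bold_ctx.data[:, sel].mean(axis=1)
        counts[int(label)] = n
    return NetworkTimecourses(data=cols, labels=labels, n_vertices_included=counts)


def _corr_columns(x: np.ndarray, y: np.ndarray):
    """Pearson r between every column of x and every column of y.

    Returns (r, x_ok, y_ok) where the ok vectors flag nonzero-variance
    columns; r rows/cols for degenerate columns are set to 0.
    """
    t = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xs = np.sqrt((xc * xc).sum(axis=0))
    ys = np.sqrt((yc * yc).sum(axis=0))
    x_ok = xs > 0
    y_ok = ys > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(np.where(x_ok, xs, 1.0), np.where(y_ok, ys, 1.0))
    r[~x_ok, :] = 0.0
    r[:, ~y_ok] = 0.0
    return r, x_ok, y_ok


def voxel_network_fc(bold_hip: BoldMatrix, tcs: NetworkTimecourses) -> VoxelNetworkFC:
    """Fisher-z Pearson correlation of every hippocampal voxel with every
    network mean time course. Zero-variance voxels are flagged invalid (and
    excluded from parcellation downstream); a zero-variance network course is
    an error."""
    if bold_hip.n_timepoints != tcs.data.shape[0]:
        raise ValueError("time dimensions differ between voxel and network series")
    r, vox_ok, net_ok = _corr_columns(bold_hip.data, tcs.data)
    if not net_ok.all():
        bad = tcs.labels[~net_ok].tolist()
        raise ValueError(f"zero-variance network time course(s): {bad}")
    if not vox_ok.all():
        warnings.warn(
            f"{int((~vox_ok).sum())} zero-variance voxel(s) flagged invalid and "
            "excluded downstream"
        )
    return VoxelNetworkFC(z=fisher_z(r), labels=tcs.labels, valid=vox_ok)


def seed_map(
    bold_ctx: BoldMatrix,
    bold_hip: BoldMatrix,
    parcel: np.ndarray,
    include: np.ndarray | None = None,
    subject: str = "",
    name: str = "",
) -> SeedMap:
    """Seed-based map: mean time course of a voxel parcel correlated with
    every cortical vertex, Fisher z-transformed.

    ``parcel`` is a boolean or index vector over hippocampal voxels. No
    exclusion radius is applied by default (display convention); pass
    ``include`` to zero out excluded vertices.
    """
    parcel = np.asarray(parcel)
    if parcel.dtype == bool:
        parcel = np.flatnonzero(parcel)
    if parcel.size == 0:
        raise ValueError("empty seed parcel")
    seed_tc = bold_hip.data[:, parcel].mean(axis=1, keepdims=True)
    r, seed_ok, ctx_ok = _corr_columns(seed_tc, bold_ctx.data)
    if not seed_ok[0]:
        raise ValueError("seed parcel mean time course has zero variance")
    values = fisher_z(r[0])
    if include is not None:
        values = np.where(include, values, 0.0)
    return SeedMap(values=values, subject=subject, parcel=name)


def difference_map(a: SeedMap, b: SeedMap) -> SeedMap:
    """Elementwise a - b (e.g. DMN parcel map minus PMN parcel map)."""
    if a.values.shape != b.values.shape:
        raise ValueError("seed maps are on different vertex spaces")
    return SeedMap(values=a.values - b.values, subject=a.subject,
                   parcel=f"{a.parcel}-{b.parcel}")


def group_average(maps: list[SeedMap]) -> SeedMap:
    """Vertexwise mean of Fisher-z maps (averaging happens in z-space)."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    n = maps[0].values.shape
    if any(m.values.shape != n for m in maps):
        raise ValueError("maps are on different vertex spaces")
    stacked = np.stack([m.values for m in maps])
    return SeedMap(values=stacked.mean(axis=0), subject="group", parcel=maps[0].parcel)
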