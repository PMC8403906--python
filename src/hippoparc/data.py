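"""Shared domain containers and file I/O.

The pipeline operates on three in-memory objects: a :class:`CorticalAtlas`
(vertex coordinates plus an integer functional-network label per vertex), a
:class:`HippocampusMask` (voxel indices in a volume grid with an affine), and
:class:`BoldMatrix` (time x unit signal matrices for cortex and hippocampus).
Volumes are NIfTI-1 (via nibabel); vertex tables are tab-delimited text with
columns ``vertex_id  x  y  z  hemisphere  label``.

Preprocessing (motion correction, nuisance regression, frame censoring) is
assumed to have happened upstream: BOLD matrices must be dense and NaN-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "CorticalAtlas",
    "HippocampusMask",
    "BoldMatrix",
    "SeedMap",
    "PipelineConfig",
    "load_volume",
    "load_atlas",
    "load_bold_nifti",
    "load_bold_table",
]

#: correlations are clipped to +/- this bound before atanh so degenerate
#: (noiseless) inputs still yield finite Fisher-z values
R_CLIP = 1.0 - 1e-7

# hemisphere codes used in NIfTI mask volumes
_HEMI_CODE = {"L": 1, "R": 2}
_CODE_HEMI = {v: k for k, v in _HEMI_CODE.items()}


def fisher_z(r, clip: float = R_CLIP):
    """Fisher z-transform ``z(r) = atanh(r)``, variance-stabilising Pearson r.

    Values are clipped to ``+/- clip`` first so perfectly correlated
    (synthetic, noiseless) series map to a large finite z rather than inf.
    """
    r = np.asarray(r, dtype=float)
    return np.arctanh(np.clip(r, -clip, clip))


def inverse_fisher_z(z):
    """Inverse transform ``r = tanh(z)``."""
    return np.tanh(np.asarray(z, dtype=float))


@dataclass
class CorticalAtlas:
    """Cortical vertex set with per-vertex functional network labels.

    Parameters
    ----------
    vertex_id : (n,) int array
    coords : (n, 3) float array, world mm
    hemisphere : (n,) array of 'L'/'R'
    labels : (n,) int array, network label in 1..K
    """

    vertex_id: np.ndarray
    coords: np.ndarray
    hemisphere: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.vertex_id = np.asarray(self.vertex_id, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.vertex_id.shape[0]
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_vertices, 3)")
        if self.hemisphere.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("per-vertex arrays must share one length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("vertex coordinates must be finite")

    @property
    def n_vertices(self) -> int:
        return self.vertex_id.shape[0]

    @property
    def network_labels(self) -> np.ndarray:
        """Sorted distinct network labels present (K of them)."""
        return np.unique(self.labels)

    @property
    def n_networks(self) -> int:
        return self.network_labels.size

    def network_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}

    def vertices_of(self, label: int) -> np.ndarray:
        """Indices (positions, 0-based) of vertices with the given label."""
        return np.flatnonzero(self.labels == int(label))

    def to_table(self, path) -> None:
        df = pd.DataFrame(
            {
                "vertex_id": self.vertex_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "hemisphere": self.hemisphere,
                "label": self.labels,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def load_atlas(coords_path, labels_path=None, name_map: dict | None = None) -> CorticalAtlas:
    """Read a cortical atlas from delimited text.

    ``coords_path`` holds columns ``vertex_id x y z hemisphere [label]``.
    When the label column is absent, ``labels_path`` must give one integer
    label per row (same order). Labels missing from ``name_map`` (when one is
    supplied) are retained as anonymous networks with a warning.
    """
    import warnings

    df = pd.read_csv(coords_path, sep="\t")
    required = {"vertex_id", "x", "y", "z", "hemisphere"}
    if not required <= set(df.columns):
        raise ValueError(f"atlas table missing columns: {sorted(required - set(df.columns))}")
    if "label" in df.columns:
        labels = df["label"].to_numpy()
    else:
        if labels_path is None:
            raise ValueError("no label column and no labels_path given")
        labels = pd.read_csv(labels_path, sep="\t", header=None)[0].to_numpy()
        if labels.shape[0] != len(df):
            raise ValueError("coordinate and label tables have unequal row counts")
    if not np.issubdtype(np.asarray(labels).dtype, np.integer):
        as_float = np.asarray(labels, dtype=float)
        if not np.all(as_float == np.round(as_float)):
            raise ValueError("network labels must be integers")
        labels = as_float.astype(int)
    atlas = CorticalAtlas(
        vertex_id=df["vertex_id"].to_numpy(),
        coords=df[["x", "y", "z"]].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(),
        labels=labels,
    )
    if name_map is not None:
        known = set(int(v) for v in name_map.values())
        anonymous = sorted(set(atlas.network_labels.tolist()) - known)
        if anonymous:
            warnings.warn(
                f"labels {anonymous} not in configured network name map; "
                "retained as anonymous networks"
            )
    return atlas


@dataclass
class HippocampusMask:
    """Hippocampal voxel set on a volume grid.

    ``voxel_ijk`` are 0-based integer indices; world coordinates always go
    through the affine (never a hard-coded voxel size), so 4 mm and 2.6 mm
    grids are handled identically.
    """

    voxel_ijk: np.ndarray
    affine: np.ndarray
    hemisphere: np.ndarray
    shape: tuple | None = None

    def __post_init__(self):
        self.voxel_ijk = np.asarray(self.voxel_ijk, dtype=int)
        self.affine = np.asarray(self.affine, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.voxel_ijk.ndim != 2 or self.voxel_ijk.shape[1] != 3:
            raise ValueError("voxel_ijk must be (n_voxels, 3)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        uniq = np.unique(self.voxel_ijk, axis=0)
        if uniq.shape[0] != self.voxel_ijk.shape[0]:
            raise ValueError("duplicate voxels in mask")
        if self.hemisphere.shape[0] != self.voxel_ijk.shape[0]:
            raise ValueError("hemisphere must be per-voxel")
        if self.shape is None:
            self.shape = tuple(int(m) + 3 for m in self.voxel_ijk.max(axis=0))

    @property
    def n_voxels(self) -> int:
        return self.voxel_ijk.shape[0]

    @property
    def world_coords(self) -> np.ndarray:
        """(n, 3) voxel-center world coordinates: affine applied to (i,j,k,1)."""
        homo = np.c_[self.voxel_ijk, np.ones(self.n_voxels)]
        return (homo @ self.affine.T)[:, :3]

    def hemisphere_index(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def to_nifti(self, path) -> None:
        vol = np.zeros(self.shape, dtype=np.int16)
        codes = np.array([_HEMI_CODE[str(h)] for h in self.hemisphere], dtype=np.int16)
        vol[tuple(self.voxel_ijk.T)] = codes
        nib.save(nib.Nifti1Image(vol, self.affine), str(path))


def load_volume(path) -> HippocampusMask:
    """Load a hippocampal mask volume (NIfTI; 1 = left, 2 = right).

    Raises a format/validation error for malformed files or a non-invertible
    affine. Round-trips with :meth:`HippocampusMask.to_nifti` bit-exactly.
    """
    try:
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several format error types
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    affine = img.affine
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("volume affine is not invertible")
    ijk = np.argwhere(vol != 0)
    codes = vol[tuple(ijk.T)].astype(int)
    bad = sorted(set(codes.tolist()) - set(_CODE_HEMI))
    if bad:
        raise ValueError(f"mask values must be 1 (left) or 2 (right); found {bad}")
    hemi = np.array([_CODE_HEMI[c] for c in codes])
    return HippocampusMask(voxel_ijk=ijk, affine=affine, hemisphere=hemi, shape=vol.shape)


@dataclass
class BoldMatrix:
    """Time x unit BOLD signal matrix.

    `unit_space` records whether columns are hippocampal voxels or cortical
    vertices; the column order must match the mask/atlas order. NaNs are
    rejected -- censored frames are an upstream concern.
    """

    data: np.ndarray
    tr_seconds: float
    unit_space: str  # 'voxel' | 'vertex'

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be 2-D (time x unit)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(self.data).any():
            raise ValueError("BOLD matrix contains NaNs; censoring must be resolved upstream")
        if self.unit_space not in ("voxel", "vertex"):
            raise ValueError("unit_space must be 'voxel' or 'vertex'")
        self.tr_seconds = float(self.tr_seconds)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    def to_nifti(self, path, mask: HippocampusMask) -> None:
        """Write as a 4-D NIfTI on the mask's grid (voxel data only)."""
        if self.unit_space != "voxel":
            raise ValueError("only voxel-space matrices can be written as volumes")
        if self.n_units != mask.n_voxels:
            raise ValueError("column count does not match mask voxel count")
        vol = np.zeros(mask.shape + (self.n_timepoints,), dtype=np.float64)
        i, j, k = mask.voxel_ijk.T
        vol[i, j, k, :] = self.data.T
        img = nib.Nifti1Image(vol, mask.affine)
        img.header.set_zooms(img.header.get_zooms()[:3] + (self.tr_seconds,))
        nib.save(img, str(path))

    def to_table(self, path) -> None:
        pd.DataFrame(self.data).to_csv(path, sep="\t", index=False, header=False)


def load_bold_nifti(path, mask: HippocampusMask) -> BoldMatrix:
    """Read a 4-D NIfTI and extract the mask's voxel time series."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D BOLD volume")
    i, j, k = mask.voxel_ijk.T
    data = vol[i, j, k, :].T
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return BoldMatrix(data=data, tr_seconds=tr, unit_space="voxel")


def load_bold_table(path, tr_seconds: float, unit_space: str = "vertex") -> BoldMatrix:
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return BoldMatrix(data=data, tr_seconds=tr_seconds, unit_space=unit_space)


@dataclass
class SeedMap:
    """Per-vertex Fisher-z connectivity of one hippocampal seed parcel."""

    values: np.ndarray
    subject: str = ""
    parcel: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("seed map must be 1-D (per vertex)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("seed map values must be finite")

    def to_table(self, path) -> None:
        pd.DataFrame({"z": self.values}).to_csv(path, sep="\t", index=False)


_DEFAULT_NETWORKS = {"DMN": 1, "PMN": 2, "CAN": 3, "FPN": 4}


@dataclass
class PipelineConfig:
    """Tunable analysis parameters with their published defaults.

    exclusion_radius_mm
        cortical vertices closer than this to any hippocampal voxel are
        excluded from network time courses (signal bleed guard); default 20.
    runner_up_fraction
        a second-place network is reported when its connectivity is at least
        this fraction of the winner's; default 0.66.
    posterior_fraction
        posterior fraction of the longitudinal axis treated as the anatomical
        tail; default 0.20.
    border_radius_voxels
        Chebyshev radius (in voxel indices) defining border voxels; default 2.
    strength_floor_z
        minimum acceptable mean parcel-to-winner connectivity z(r); default 0.2.
    """

    exclusion_radius_mm: float = 20.0
    runner_up_fraction: float = 0.66
    posterior_fraction: float = 0.20
    border_radius_voxels: int = 2
    strength_floor_z: float = 0.2
    n_permutations: int = 999
    rng_seed: int = 0
    networks: dict = field(default_factory=lambda: dict(_DEFAULT_NETWORKS))
    null_exclude: tuple = ("FPN",)
    null_pair_labels: tuple | None = None  # None -> all atlas networks minus excluded
    apply_exclusion_to_seed_maps: bool = False
    include_cues: bool = True

    def __post_init__(self):
        for name in ("runner_up_fraction", "posterior_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and not (name == "runner_up_fraction" and v == 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.exclusion_radius_mm <= 0 or self.border_radius_voxels < 0:
            raise ValueError("radii must be positive")

    def label(self, name: str) -> int:
        return int(self.networks[name])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["null_exclude"] = list(self.null_exclude)
        if self.null_pair_labels is not None:
            d["null_pair_labels"] = list(self.null_pair_labels)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "null_exclude" in raw:
            raw["null_exclude"] = tuple(raw["null_exclude"])
        if raw.get("null_pair_labels") is not None:
            raw["null_pair_labels"] = tuple(raw["null_pair_labels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
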