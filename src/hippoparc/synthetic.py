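"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a precision-mapped single subject:
K functional networks with independent, temporally autocorrelated latent
time courses; cortical vertices that load one-hot on their network; and
hippocampal voxels whose signals are loading-weighted mixtures of the latent
courses. Along the hippocampal longitudinal (anterior-posterior) axis the
default-mode (DMN) vs parietal-memory (PMN) loadings are organised either as

``parcel``
    a one-hot step at ``border_position`` of the axis (anterior side DMN),
``gradient``
    DMN loading declining linearly anterior -> posterior while PMN rises, or
``mixed``
    a convex combination of the two fields with weight ``lambda_mixed``.

Everything is deterministic given the seed. The cortex is a point cloud (no
mesh); a small fraction of vertices is deliberately placed within the 20 mm
exclusion radius of the hippocampus so the exclusion rule does real work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data import BoldMatrix, CorticalAtlas, HippocampusMask

__all__ = [
    "GeneratorSpec",
    "TaskSpec",
    "GroundTruth",
    "SubjectData",
    "make_subject",
    "make_task_run",
    "exchangeable_fc",
]

#: canonical network name -> label map used by the generator
NETWORK_LABELS = {"DMN": 1, "PMN": 2, "CAN": 3, "FPN": 4}


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic subject.

    Defaults emulate a single highly sampled subject: 15 usable cortical
    networks, a 2.6 mm isotropic grid, a 16-voxel (~42 mm) hippocampal axis
    per hemisphere with a 3x3 cross-section, and 8180 frames at TR 2.2 s
    (ten 30-minute resting sessions concatenated). Noise levels are set so a
    hippocampal voxel's connectivity to its winner network lands around
    z(r) ~ 0.3-0.5, comfortably above the 0.2 floor reported for real parcels.
    """

    n_networks: int = 15
    vertices_per_network: int = 40
    near_vertices_per_network: int = 2  # placed inside the exclusion radius
    axis_len: int = 16
    cross_section: tuple = (3, 3)
    voxel_size_mm: float = 2.6
    n_timepoints: int = 8180
    tr_seconds: float = 2.2
    ar_coef: float = 0.3
    mode: str = "mixed"  # 'parcel' | 'gradient' | 'mixed'
    border_position: float = 0.8
    lambda_mixed: float = 0.5
    noise_sd: float = 2.0         # hippocampal voxel noise
    cortex_noise_sd: float = 1.0  # cortical vertex noise
    seed: int = 0

    def __post_init__(self):
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if self.axis_len < 3:
            raise ValueError("hippocampal axis must span at least 3 voxels")
        if not 0.0 < self.border_position < 1.0:
            raise ValueError("border_position must lie in (0, 1)")
        if self.mode not in ("parcel", "gradient", "mixed"):
            raise ValueError(f"unknown organisation mode {self.mode!r}")


@dataclass
class GroundTruth:
    """Per-voxel generative truth for one subject."""

    loadings: np.ndarray            # (n_voxels, K), rows sum to 1
    parcel_labels: np.ndarray       # (n_voxels,) true DMN/PMN side of the border
    axis_fraction: np.ndarray       # (n_voxels,) 0 = anterior end, 1 = posterior
    organization_mode: str
    true_border_position: float
    noise_sd: float
    n_timepoints: int
    rng_seed: int
    medial_parietal_vertices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        if (self.loadings < 0).any():
            raise ValueError("loadings must be nonnegative")
        if not np.allclose(self.loadings.sum(axis=1), 1.0):
            raise ValueError("loading rows must sum to 1")
        if not 0.0 < self.true_border_position < 1.0:
            raise ValueError("border position must lie in (0, 1)")

    def to_json(self, path) -> None:
        d = {
            "loadings": self.loadings.tolist(),
            "parcel_labels": self.parcel_labels.tolist(),
            "axis_fraction": self.axis_fraction.tolist(),
            "organization_mode": self.organization_mode,
            "true_border_position": self.true_border_position,
            "noise_sd": self.noise_sd,
            "n_timepoints": self.n_timepoints,
            "rng_seed": self.rng_seed,
            "medial_parietal_vertices": self.medial_parietal_vertices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loadings=np.array(d["loadings"], dtype=float),
            parcel_labels=np.array(d["parcel_labels"], dtype=int),
            axis_fraction=np.array(d["axis_fraction"], dtype=float),
            organization_mode=d["organization_mode"],
            true_border_position=d["true_border_position"],
            noise_sd=d["noise_sd"],
            n_timepoints=d["n_timepoints"],
            rng_seed=d["rng_seed"],
            medial_parietal_vertices=np.array(d["medial_parietal_vertices"], dtype=int),
        )


@dataclass
class SubjectData:
    """Bundle returned by :func:`make_subject`."""

    atlas: CorticalAtlas
    mask: HippocampusMask
    bold_cortex: BoldMatrix
    bold_hippo: BoldMatrix
    truth: GroundTruth


def _ar1(rng: np.random.Generator, n: int, k: int, phi: float) -> np.ndarray:
    """k independent unit-variance Gaussian AR(1) series of length n."""
    eps = rng.standard_normal((n, k))
    eps[1:] *= np.sqrt(1.0 - phi * phi)  # keeps the marginal variance at 1
    return lfilter([1.0], [1.0, -phi], eps, axis=0)


def _dmn_weight(t: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    """True DMN loading as a function of normalised axis position t (0=anterior)."""
    parcel = (t < spec.border_position).astype(float)
    gradient = 1.0 - t
    if spec.mode == "parcel":
        return parcel
    if spec.mode == "gradient":
        return gradient
    lam = spec.lambda_mixed
    return lam * parcel + (1.0 - lam) * gradient


def _hippocampus_geometry(spec: GeneratorSpec):
    """Two hemisphere boxes along the +y (anterior) axis on a RAS grid."""
    ci, ck = spec.cross_section
    L = spec.axis_len
    ijk, hemi = [], []
    # left hemisphere occupies low i indices, right is offset well clear of it
    for hlabel, i0 in (("L", 2), ("R", 2 + ci + 8)):
        for i in range(ci):
            for j in range(L):
                for k in range(ck):
                    ijk.append((i0 + i, 2 + j, 2 + k))
                    hemi.append(hlabel)
    ijk = np.array(ijk, dtype=int)
    v = spec.voxel_size_mm
    # RAS affine; translation centres the structure near the origin
    affine = np.array(
        [
            [v, 0, 0, -v * (ijk[:, 0].max() + 2) / 2],
            [0, v, 0, -v * (L / 2 + 2)],
            [0, 0, v, -v * (ck / 2 + 2)],
            [0, 0, 0, 1],
        ]
    )
    shape = tuple(int(m) + 3 for m in ijk.max(axis=0))
    mask = HippocampusMask(voxel_ijk=ijk, affine=affine, hemisphere=np.array(hemi), shape=shape)
    # normalised axis position, 0 at the anterior (high-y) end, voxel-centre convention
    j = ijk[:, 1] - 2
    t = ((L - 1 - j) + 0.5) / L
    return mask, t


def _cortex_geometry(spec: GeneratorSpec, mask: HippocampusMask, rng: np.random.Generator):
    """Random vertex cloud: most vertices 30-80 mm from the hippocampus,
    a few per network placed within 20 mm to exercise the exclusion rule."""
    centre = mask.world_coords.mean(axis=0)
    coords, labels, hemis = [], [], []
    for net in range(1, spec.n_networks + 1):
        n_far = spec.vertices_per_network - spec.near_vertices_per_network
        for _ in range(n_far):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            coords.append(centre + u * rng.uniform(35.0, 80.0))
            labels.append(net)
        for _ in range(spec.near_vertices_per_network):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            coords.append(centre + u * rng.uniform(2.0, 15.0))
            labels.append(net)
    coords = np.array(coords)
    hemis = np.where(coords[:, 0] < centre[0], "L", "R")
    atlas = CorticalAtlas(
        vertex_id=np.arange(coords.shape[0]),
        coords=coords,
        hemisphere=hemis,
        labels=np.array(labels, dtype=int),
    )
    return atlas


def make_subject(spec: GeneratorSpec) -> SubjectData:
    """Generate one ground-truth-known subject.

    Cortical vertex series are their network's latent course plus independent
    noise; hippocampal voxel series are the loading-weighted mixture of the
    DMN/PMN latents plus noise. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask, t = _hippocampus_geometry(spec)
    atlas = _cortex_geometry(spec, mask, rng)

    latents = _ar1(rng, spec.n_timepoints, spec.n_networks, spec.ar_coef)

    ctx_noise = rng.standard_normal((spec.n_timepoints, atlas.n_vertices))
    ctx = latents[:, atlas.labels - 1] + spec.cortex_noise_sd * ctx_noise
    bold_ctx = BoldMatrix(data=ctx, tr_seconds=spec.tr_seconds, unit_space="vertex")

    w_dmn = _dmn_weight(t, spec)
    loadings = np.zeros((mask.n_voxels, spec.n_networks))
    loadings[:, NETWORK_LABELS["DMN"] - 1] = w_dmn
    loadings[:, NETWORK_LABELS["PMN"] - 1] = 1.0 - w_dmn

    hip = loadings @ latents.T  # (n_voxels, T)
    hip = hip.T + spec.noise_sd * rng.standard_normal((spec.n_timepoints, mask.n_voxels))
    bold_hip = BoldMatrix(data=hip, tr_seconds=spec.tr_seconds, unit_space="voxel")

    parcel_labels = np.where(
        t < spec.border_position, NETWORK_LABELS["DMN"], NETWORK_LABELS["PMN"]
    )
    # tag half of the DMN and PMN vertices as 'medial parietal' for task scopes
    mp = []
    for name in ("DMN", "PMN"):
        idx = atlas.vertices_of(NETWORK_LABELS[name])
        mp.extend(idx[: len(idx) // 2].tolist())
    truth = GroundTruth(
        loadings=loadings,
        parcel_labels=parcel_labels,
        axis_fraction=t,
        organization_mode=spec.mode,
        true_border_position=spec.border_position,
        noise_sd=spec.noise_sd,
        n_timepoints=spec.n_timepoints,
        rng_seed=spec.seed,
        medial_parietal_vertices=np.array(sorted(mp), dtype=int),
    )
    return SubjectData(atlas=atlas, mask=mask, bold_cortex=bold_ctx, bold_hippo=bold_hip, truth=truth)


@dataclass
class TaskSpec:
    """Mixed block/event task run description.

    ``amplitudes`` maps network name -> evoked amplitude injected at the 3rd
    and 4th post-onset frames (1-indexed) of every trial, scaled per unit by
    that unit's loading on the network. Negative amplitudes model the
    task-general deactivation that defines the DMN.
    """

    n_frames: int = 200
    tr_seconds: float = 2.2
    onsets: dict = field(default_factory=lambda: {"task": [10, 40, 70, 100, 130, 160]})
    blocks: tuple = ((5, 180),)
    amplitudes: dict = field(default_factory=lambda: {"DMN": -1.0, "PMN": 0.0})
    block_amplitude: float = 0.0
    n_lags: int = 8
    response_lags: tuple = (3, 4)  # 1-indexed post-onset frames carrying signal
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for cond, ons in self.onsets.items():
            for o in ons:
                if o < 0 or o + self.n_lags > self.n_frames:
                    raise ValueError(
                        f"event at frame {o} ({cond}) does not fit in the run"
                    )
        spans = sorted(self.blocks)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("task blocks overlap")
        for a0, a1 in spans:
            if not (0 <= a0 < a1 <= self.n_frames):
                raise ValueError("block outside run")


def make_task_run(
    spec: TaskSpec, loadings: np.ndarray, network_labels: dict = NETWORK_LABELS
):
    """Simulate one task run for units with the given network loadings.

    Returns ``(bold, events, true_amplitude)`` where ``events`` is a
    DataFrame of (condition, onset_frame) and ``true_amplitude`` the per-unit
    injected amplitude at the response lags.
    """
    rng = np.random.default_rng(spec.seed)
    loadings = np.asarray(loadings, dtype=float)
    n_units = loadings.shape[0]

    amp = np.zeros(n_units)
    for name, a in spec.amplitudes.items():
        amp += a * loadings[:, network_labels[name] - 1]

    signal = np.zeros((spec.n_frames, n_units))
    rows = []
    for cond, ons in sorted(spec.onsets.items()):
        for o in ons:
            rows.append({"condition": cond, "onset_frame": int(o)})
            for lag in spec.response_lags:  # 1-indexed
                signal[o + lag - 1] += amp
    for b0, b1 in spec.blocks:
        signal[b0:b1] += spec.block_amplitude
    signal += spec.noise_sd * rng.standard_normal(signal.shape)
    events = pd.DataFrame(rows)
    bold = BoldMatrix(data=signal, tr_seconds=spec.tr_seconds, unit_space="voxel")
    return bold, events, amp


def one_hot_loadings(labels: np.ndarray, n_networks: int) -> np.ndarray:
    """(n_units, K) loading matrix with 1 at each unit's own network."""
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_networks))
    out[np.arange(labels.size), labels - 1] = 1.0
    return out


def simulate_task_sessions(subject: SubjectData, task: TaskSpec, n_sessions: int, seed: int):
    """Simulate task runs for both cortex and hippocampus across sessions.

    Cortical vertices respond one-hot through their network label; hippocampal
    voxels through their ground-truth loadings. Returns a list of
    ``(bold_ctx, bold_hip, events)`` tuples, deterministic given ``seed``.
    """
    from dataclasses import replace

    n_nets = subject.truth.loadings.shape[1]
    ctx_load = one_hot_loadings(subject.atlas.labels, n_nets)
    sessions = []
    for s in range(n_sessions):
        spec_ctx = replace(task, seed=seed + 2 * s)
        spec_hip = replace(task, seed=seed + 2 * s + 1)
        bold_ctx, events, _ = make_task_run(spec_ctx, ctx_load)
        bold_hip, _, _ = make_task_run(spec_hip, subject.truth.loadings)
        bold_ctx = BoldMatrix(data=bold_ctx.data, tr_seconds=task.tr_seconds,
                              unit_space="vertex")
        sessions.append((bold_ctx, bold_hip, events))
    return sessions


def exchangeable_fc(n_voxels: int, labels, rng, mean: float = 0.15, sd: float = 0.1):
    """Voxel x network Fisher-z matrix with fully exchangeable network labels.

    Entries are i.i.d. normal, so every network is statistically identical --
    the null world for parcel-vs-chance calibration checks.
    """
    from .connectivity import VoxelNetworkFC

    labels = np.asarray(labels, dtype=int)
    z = rng.normal(mean, sd, size=(n_voxels, labels.size))
    return VoxelNetworkFC(z=z, labels=labels, valid=np.ones(n_voxels, dtype=bool))
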