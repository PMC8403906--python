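"""End-to-end per-subject analysis and synthetic-cohort evaluation.

:func:`analyze_subject` runs the full resting-state sequence in memory --
exclusion mask, network time courses, voxel-network connectivity,
multi-network and forced-choice winner-take-all, the parcel-vs-chance null,
gradient/parcel variance partition, border ROC, anatomical segmentation and
Dice overlap -- and returns a JSON-serialisable summary plus the
intermediate objects. :func:`run_subject` wraps it with file I/O (outputs
plus a machine-readable run manifest), and :func:`run_cohort_eval` sweeps
organisation modes, noise levels and seeds over synthetic subjects,
reporting recovery against ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import HEAD_BODY, TAIL, dice_two_class, segment_percentage, segment_landmark
from .axis import AxisVariancePartition, axis_coordinates, delta_fc
from .border import BorderRoc, find_border, pair_similarities
from .connectivity import (
    exclusion_mask,
    network_timecourses,
    seed_map,
    difference_map,
    voxel_network_fc,
    _corr_columns,
)
from .data import BoldMatrix, PipelineConfig, fisher_z, load_atlas, load_volume, load_bold_nifti, load_bold_table
from .nulls import ParcelNullModel
from .synthetic import GeneratorSpec, SubjectData, GroundTruth, make_subject, simulate_task_sessions, TaskSpec, one_hot_loadings
from .taskglm import build_fir_design, deactivation_contrast, fit_glm, region_deactivation_compare
from .wta import WinnerTakeAll, forced_choice

__all__ = ["analyze_subject", "run_subject", "run_cohort_eval",
           "analyze_task_sessions", "save_subject_dir", "load_subject_dir"]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def _stage(name):
    from contextlib import contextmanager

    @contextmanager
    def cm():
        try:
            yield
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    return cm()


def analyze_subject(
    subject: SubjectData,
    config: PipelineConfig | None = None,
    landmark_slice: int | None = None,
    keep_artifacts: bool = True,
):
    """Run the full resting-state analysis on one subject.

    Returns ``(summary, artifacts)``: a JSON-serialisable summary dict and a
    dict of intermediate objects (fc, parcellations, axis assignment, ROC
    result, seed maps, ...). ``landmark_slice`` enables the landmark-based
    anatomical split alongside the percentage split.
    """
    config = config or PipelineConfig()
    atlas, mask = subject.atlas, subject.mask
    dmn, pmn = config.label("DMN"), config.label("PMN")
    summary: dict = {"config": config.to_dict(), "version": __version__}
    art: dict = {}

    with _stage("exclusion"):
        include = exclusion_mask(atlas, mask, config.exclusion_radius_mm)
        summary["n_vertices_excluded"] = int((~include).sum())

    with _stage("connectivity"):
        tcs = network_timecourses(subject.bold_cortex, atlas, include)
        fc = voxel_network_fc(subject.bold_hippo, tcs)
        art["fc"] = fc

    with _stage("wta_full"):
        full = WinnerTakeAll(
            fc, runner_up_fraction=config.runner_up_fraction, hemisphere=mask.hemisphere
        ).fit()
        art["wta_full"] = full
        summary["proportions_assigned"] = {str(k): v for k, v in full.proportions().items()}
        summary["proportions_all"] = {str(k): v for k, v in full.proportions(over="all").items()}
        summary["proportions_by_hemisphere"] = {
            h: {str(k): v for k, v in d.items()}
            for h, d in full.proportions(by_hemisphere=True).items()
        }

    with _stage("forced_choice"):
        fcw = forced_choice(fc, (dmn, pmn), hemisphere=mask.hemisphere)
        art["wta_pair"] = fcw
        summary["anterior_dmn_fraction"] = fcw.anterior_fraction(dmn)
        summary["strength_check"] = {
            str(k): v for k, v in fcw.verify_strength(config.strength_floor_z).items()
        }

    with _stage("seed_maps"):
        inc = include if config.apply_exclusion_to_seed_maps else None
        m_dmn = seed_map(subject.bold_cortex, subject.bold_hippo, fcw.mask(dmn),
                         include=inc, name="DMN")
        m_pmn = seed_map(subject.bold_cortex, subject.bold_hippo, fcw.mask(pmn),
                         include=inc, name="PMN")
        art["seed_maps"] = {"DMN": m_dmn, "PMN": m_pmn,
                            "difference": difference_map(m_dmn, m_pmn)}

    with _stage("null_models"):
        labels = (
            [config.label(n) for n in config.null_pair_labels]
            if config.null_pair_labels is not None
            else fc.labels.tolist()
        )
        excluded = [config.label(n) for n in config.null_exclude]
        null = ParcelNullModel(fc, (dmn, pmn), labels=labels, excluded=excluded).fit()
        art["null"] = null
        summary["null"] = {
            "n_null": null.n_null,
            "observed_mean_z": {str(k): v for k, v in null.observed.items()},
            "p_values": {str(k): v for k, v in null.p_values.items()},
        }

    with _stage("axis_models"):
        axis = axis_coordinates(mask, method="pca")
        delta = delta_fc(fc, (dmn, pmn))
        art["axis"] = axis
        art["delta"] = delta
        summary["axis_models"] = {}
        results = {}
        for h in np.unique(mask.hemisphere):
            sel = mask.hemisphere == h
            res = AxisVariancePartition(
                delta[sel], axis.coord[sel], fcw.labels[sel]
            ).fit()
            results[str(h)] = res
            summary["axis_models"][str(h)] = res.to_dict()
        pooled = AxisVariancePartition(delta, axis.coord, fcw.labels).fit()
        results["pooled"] = pooled
        summary["axis_models"]["pooled"] = pooled.to_dict()
        art["axis_results"] = results

    with _stage("border_roc"):
        # seed profiles: per-voxel Fisher-z to every *included* cortical vertex
        r, _, _ = _corr_columns(subject.bold_hippo.data, subject.bold_cortex.data[:, include])
        profiles = fisher_z(r)
        border = find_border(fcw, mask.voxel_ijk, radius=config.border_radius_voxels)
        pairs = pair_similarities(profiles, border)
        roc = BorderRoc(pairs, voxel_labels=border.labels).fit(
            n_permutations=config.n_permutations, seed=config.rng_seed
        )
        art["border"] = border
        art["roc"] = roc
        summary["border_roc"] = {
            "n_border_voxels": border.n_voxels,
            "n_pairs": roc.n_pairs,
            "auc": roc.auc,
            "p_value": roc.p_value,
            "n_permutations": roc.n_permutations,
            "seed": roc.seed,
        }

    with _stage("anatomy"):
        seg = segment_percentage(mask, axis, config.posterior_fraction)
        func_seg = np.where(fcw.labels == pmn, TAIL, HEAD_BODY)
        d_func = dice_two_class(seg.segment, func_seg)
        art["segmentation"] = seg
        summary["anatomy"] = {"dice_functional_vs_percentage": d_func}
        if landmark_slice is not None:
            seg_lm = segment_landmark(mask, landmark_slice)
            art["segmentation_landmark"] = seg_lm
            summary["anatomy"]["dice_percentage_vs_landmark"] = dice_two_class(
                seg.segment, seg_lm.segment
            )

    if subject.truth is not None:
        with _stage("ground_truth_eval"):
            truth = subject.truth
            recov = float((fcw.labels == truth.parcel_labels).mean())
            summary["ground_truth"] = {
                "mode": truth.organization_mode,
                "recovery_fraction": recov,
                "true_border_position": truth.true_border_position,
            }

    if not keep_artifacts:
        art = {}
    return summary, art


def analyze_task_sessions(sessions, task: TaskSpec, include_cues: bool = True):
    """FIR GLM + deactivation contrast over task sessions.

    ``sessions`` is a list of ``(bold_ctx, bold_hip, events)``. Returns a dict
    with cortex/hippocampus :class:`DeactivationContrast` objects.
    """
    fits_ctx, fits_hip = [], []
    for bold_ctx, bold_hip, events in sessions:
        design = build_fir_design(events, n_frames=bold_ctx.n_timepoints,
                                  n_lags=task.n_lags, blocks=task.blocks)
        fits_ctx.append(fit_glm(bold_ctx, design))
        fits_hip.append(fit_glm(bold_hip, design))
    return {
        "cortex": deactivation_contrast(fits_ctx, include_cues=include_cues),
        "hippocampus": deactivation_contrast(fits_hip, include_cues=include_cues),
    }


# ---------------------------------------------------------------------------
# subject directory I/O

def save_subject_dir(subject: SubjectData, outdir, task_sessions=None,
                     task: TaskSpec | None = None) -> None:
    """Write a subject to disk in the layout the CLI subcommands read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    subject.atlas.to_table(out / "atlas.tsv")
    subject.mask.to_nifti(out / "mask.nii")
    subject.bold_cortex.to_table(out / "bold_cortex.tsv")
    subject.bold_hippo.to_nifti(out / "bold_hippo.nii", subject.mask)
    meta = {"tr_seconds": subject.bold_cortex.tr_seconds}
    if subject.truth is not None:
        subject.truth.to_json(out / "truth.json")
    if task_sessions:
        tdir = out / "task"
        tdir.mkdir(exist_ok=True)
        for s, (bold_ctx, bold_hip, events) in enumerate(task_sessions):
            bold_ctx.to_table(tdir / f"session_{s:02d}.cortex.tsv")
            bold_hip.to_nifti(tdir / f"session_{s:02d}.hippo.nii", subject.mask)
            events.to_csv(tdir / f"session_{s:02d}.events.tsv", sep="\t", index=False)
        meta["task"] = {
            "n_sessions": len(task_sessions),
            "n_lags": task.n_lags if task else 8,
            "blocks": [list(b) for b in (task.blocks if task else ())],
            "tr_seconds": task.tr_seconds if task else meta["tr_seconds"],
        }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, sort_keys=True)


def load_subject_dir(path) -> tuple[SubjectData, dict]:
    """Read a subject directory written by :func:`save_subject_dir`.

    Returns ``(subject, meta)``; ``subject.truth`` is None for real data
    without a truth.json.
    """
    p = Path(path)
    for required in ("atlas.tsv", "mask.nii", "bold_cortex.tsv", "bold_hippo.nii"):
        if not (p / required).exists():
            raise FileNotFoundError(f"subject directory {p} is missing {required}")
    with open(p / "meta.json") as fh:
        meta = json.load(fh)
    atlas = load_atlas(p / "atlas.tsv")
    mask = load_volume(p / "mask.nii")
    tr = float(meta.get("tr_seconds", 1.0))
    bold_ctx = load_bold_table(p / "bold_cortex.tsv", tr_seconds=tr, unit_space="vertex")
    bold_hip = load_bold_nifti(p / "bold_hippo.nii", mask)
    truth = GroundTruth.from_json(p / "truth.json") if (p / "truth.json").exists() else None
    return SubjectData(atlas=atlas, mask=mask, bold_cortex=bold_ctx,
                       bold_hippo=bold_hip, truth=truth), meta


def load_task_sessions(path, meta: dict, mask) -> tuple[list, TaskSpec]:
    p = Path(path) / "task"
    tmeta = meta.get("task")
    if tmeta is None or not p.exists():
        raise FileNotFoundError("subject directory has no task data")
    sessions = []
    for s in range(int(tmeta["n_sessions"])):
        bold_ctx = load_bold_table(p / f"session_{s:02d}.cortex.tsv",
                                   tr_seconds=tmeta["tr_seconds"], unit_space="vertex")
        bold_hip = load_bold_nifti(p / f"session_{s:02d}.hippo.nii", mask)
        events = pd.read_csv(p / f"session_{s:02d}.events.tsv", sep="\t")
        sessions.append((bold_ctx, bold_hip, events))
    # onsets live in the per-session event files, not in the spec
    task = TaskSpec(n_frames=sessions[0][0].n_timepoints, onsets={},
                    tr_seconds=float(tmeta["tr_seconds"]),
                    blocks=tuple(tuple(b) for b in tmeta["blocks"]),
                    n_lags=int(tmeta["n_lags"]))
    return sessions, task


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_subject(
    subject_dir,
    outdir,
    config: PipelineConfig | None = None,
    landmark_slice: int | None = None,
    with_task: bool = False,
) -> Path:
    """File-level pipeline run: load a subject directory, analyse, write
    per-stage outputs, summary.json and a run manifest. Returns the run dir."""
    import nibabel as nib

    config = config or PipelineConfig()
    subject, meta = load_subject_dir(subject_dir)  # validates inputs up front
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary, art = analyze_subject(subject, config, landmark_slice=landmark_slice)

    # per-stage outputs
    mask = subject.mask
    for tag in ("wta_full", "wta_pair"):
        vol = np.zeros(mask.shape, dtype=np.int16)
        labels = np.where(art[tag].labels < 0, 0, art[tag].labels)
        vol[tuple(mask.voxel_ijk.T)] = labels
        nib.save(nib.Nifti1Image(vol, mask.affine), str(out / f"{tag}.nii"))
    for name, m in art["seed_maps"].items():
        m.to_table(out / f"seed_map_{name}.tsv")
    pd.DataFrame({
        "axis_coord": art["axis"].coord,
        "hemisphere": mask.hemisphere,
        "parcel": art["wta_pair"].labels,
        "delta_fc": art["delta"],
    }).to_csv(out / "axis_delta.csv", index=False)
    art["null"].entries.to_csv(out / "null_entries.csv", index=False)

    if with_task:
        sessions, task = load_task_sessions(subject_dir, meta, mask)
        contrasts = analyze_task_sessions(sessions, task, include_cues=config.include_cues)
        for scope_name, con in contrasts.items():
            pd.DataFrame({"contrast_mean": con.mean, "contrast_z": con.z}).to_csv(
                out / f"task_contrast_{scope_name}.csv", index=False
            )
        summary["task"] = {
            scope: {"mean_contrast": float(np.nanmean(c.mean)), "flags": c.flags}
            for scope, c in contrasts.items()
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=_json_default)

    manifest = {
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "version": __version__,
        "subject_dir": str(subject_dir),
        "stages": sorted(f.name for f in out.iterdir() if f.name != "manifest.json"),
        "hashes": {
            f.name: _sha256(f)
            for f in sorted(out.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return out


def run_cohort_eval(
    modes=("parcel", "gradient", "mixed"),
    noise_sds=(0.0, 2.0),
    seeds=(0, 1),
    base_spec: GeneratorSpec | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Sweep organisation mode x noise x seed over synthetic subjects.

    Each cell generates a subject, runs :func:`analyze_subject`, and records
    ground-truth recovery, the anterior DMN fraction, the r2 decomposition,
    border AUC and Dice. Deterministic given the seed list.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds per cell")
    base = base_spec or GeneratorSpec()
    config = config or PipelineConfig()
    rows = []
    for mode in modes:
        for noise in noise_sds:
            for seed in seeds:
                spec = replace(base, mode=mode, noise_sd=noise, seed=seed)
                subject = make_subject(spec)
                cfg = replace(config, rng_seed=seed)
                summary, _ = analyze_subject(subject, cfg, keep_artifacts=False)
                pooled = summary["axis_models"]["pooled"]
                rows.append({
                    "mode": mode,
                    "noise_sd": noise,
                    "seed": seed,
                    "recovery": summary["ground_truth"]["recovery_fraction"],
                    "anterior_dmn_fraction": summary["anterior_dmn_fraction"],
                    "r2_gradient": pooled["r2_gradient"],
                    "r2_parcel": pooled["r2_parcel"],
                    "sp_gradient": pooled["sp_gradient"],
                    "sp_parcel": pooled["sp_parcel"],
                    "auc": summary["border_roc"]["auc"],
                    "roc_p": summary["border_roc"]["p_value"],
                    "dice_tail": summary["anatomy"]["dice_functional_vs_percentage"]["tail"],
                    "null_p_max": max(summary["null"]["p_values"].values()),
                })
    return pd.DataFrame(rows)
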