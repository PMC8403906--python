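"""Anatomical head/body vs tail segmentation and Dice overlap validation.

Two segmentation routes: a percentage split along the longitudinal axis
(default: posterior 20% = tail, measured on the axis-length span per
hemisphere) and a landmark split at an externally supplied coronal slice
(the slice where the fornix appears posterior to the thalamus; identifying
it is upstream of this package). Overlap between segmentations, or between a
segmentation and a functional parcellation, is quantified with the Dice
coefficient 2|A&B| / (|A|+|B|); for two-class labelings the per-class Dice,
their mean, and the tail-class headline value are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis import AxisAssignment
from .data import HippocampusMask

__all__ = ["AnatomicalSegmentation", "segment_percentage", "segment_landmark",
           "dice", "dice_two_class"]

HEAD_BODY = "head_body"
TAIL = "tail"


@dataclass
class AnatomicalSegmentation:
    """Per-voxel head/body vs tail labelling."""

    segment: np.ndarray  # array of HEAD_BODY / TAIL
    method: str          # 'percentage' | 'landmark_slice'
    parameter: float     # fraction or slice index

    @property
    def tail(self) -> np.ndarray:
        return self.segment == TAIL

    @property
    def head_body(self) -> np.ndarray:
        return self.segment == HEAD_BODY


def segment_percentage(
    hippo: HippocampusMask, axis: AxisAssignment, posterior_fraction: float = 0.20,
    by: str = "span",
) -> AnatomicalSegmentation:
    """Split each hemisphere at ``1 - posterior_fraction`` of its axis length.

    ``by='span'`` (default) cuts the geometric axis-length span; ``by='count'``
    instead takes the posterior fraction of voxels (quantile split).
    """
    if not 0.0 < posterior_fraction < 1.0:
        raise ValueError("posterior_fraction must lie in (0, 1)")
    seg = np.empty(hippo.n_voxels, dtype=object)
    for h in np.unique(hippo.hemisphere):
        sel = hippo.hemisphere == h
        c = axis.coord[sel]
        # knife-edge guard: a voxel sitting exactly on the cut stays head/body
        # even under 1e-15 coordinate noise (e.g. after a rigid rotation)
        eps = 1e-9 * max(np.ptp(c), 1.0)
        if by == "span":
            cut = c.min() + (1.0 - posterior_fraction) * np.ptp(c)
            tail = c > cut + eps
        elif by == "count":
            tail = c > np.quantile(c, 1.0 - posterior_fraction) + eps
        else:
            raise ValueError("by must be 'span' or 'count'")
        if not tail.any() or tail.all():
            raise ValueError(
                f"hemisphere {h}: posterior_fraction={posterior_fraction} places "
                "zero voxels in one segment"
            )
        seg[np.flatnonzero(sel)[tail]] = TAIL
        seg[np.flatnonzero(sel)[~tail]] = HEAD_BODY
    return AnatomicalSegmentation(segment=seg.astype(str), method="percentage",
                                  parameter=float(posterior_fraction))


def segment_landmark(
    hippo: HippocampusMask, coronal_slice: int, posterior_axis: int = 1,
    posterior_is_low: bool = True,
) -> AnatomicalSegmentation:
    """Split at a coronal slice index: voxels strictly posterior are tail.

    With ``posterior_is_low`` (RAS grids: lower j = posterior), tail voxels
    satisfy ``ijk[posterior_axis] < coronal_slice``. The slice must lie in
    ``[j_min, j_max + 1]`` of the mask, the two ends giving the all-head/body
    and all-tail boundary cases.
    """
    j = hippo.voxel_ijk[:, posterior_axis]
    lo, hi = int(j.min()), int(j.max())
    if not lo <= coronal_slice <= hi + 1:
        raise ValueError(
            f"coronal slice {coronal_slice} outside the mask's slice range "
            f"[{lo}, {hi + 1}]"
        )
    tail = j < coronal_slice if posterior_is_low else j > coronal_slice
    seg = np.where(tail, TAIL, HEAD_BODY)
    return AnatomicalSegmentation(segment=seg, method="landmark_slice",
                                  parameter=float(coronal_slice))


def dice(a, b) -> float:
    """Dice coefficient 2|A&B| / (|A|+|B|) of two voxel sets.

    Accepts boolean masks on a common grid (preferred) or index arrays.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.dtype == bool and b.dtype == bool:
        if a.shape != b.shape:
            raise ValueError("masks must share one voxel grid")
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
    else:
        sa, sb = set(map(tuple, np.atleast_2d(a))), set(map(tuple, np.atleast_2d(b)))
        na, nb, inter = len(sa), len(sb), len(sa & sb)
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * inter / (na + nb)


def dice_two_class(seg_a: np.ndarray, seg_b: np.ndarray, classes=(HEAD_BODY, TAIL)) -> dict:
    """Per-class Dice of two 2-class labelings over the same voxels.

    Returns per-class values, their mean, and the whole-labelling agreement
    fraction. The tail class is the conventional headline.
    """
    seg_a = np.asarray(seg_a)
    seg_b = np.asarray(seg_b)
    if seg_a.shape != seg_b.shape:
        raise ValueError("labelings cover different voxel sets")
    out = {}
    for cls in classes:
        out[str(cls)] = dice(seg_a == cls, seg_b == cls)
    out["mean"] = float(np.mean([out[str(c)] for c in classes]))
    out["agreement"] = float((seg_a == seg_b).mean())
    return out
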