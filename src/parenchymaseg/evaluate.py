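"""Segmentation-quality metrics: DSC, Hausdorff distance, sensitivity,
specificity, and the cohort-level self-adaptability measure.

All metrics compare a produced binary mask against a reference mask of the
same shape, voxel-wise.  The Hausdorff distance is the exact (not
percentile) double max-min between the two boundary point sets,

    HD(A, B) = max( max_i min_j ||a_i - b_j||, max_j min_i ||a_i - b_j|| ),

with coordinates scaled by the voxel spacing so the result is in mm.
Boundaries are the foreground voxels with at least one background
face-neighbour (6-connectivity; voxels on the array edge count as
boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .errors import ShapeError, UndefinedMetricError

__all__ = [
    "MaskPair",
    "boundary_voxels",
    "dsc",
    "hausdorff",
    "hausdorff_slicewise_mean",
    "sens_spec",
    "evaluate_pair",
    "self_adaptability",
    "CohortResult",
]


@dataclass
class MaskPair:
    """A (reference, produced) mask pair with voxel spacing in mm."""

    gt: np.ndarray
    test: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=bool)
        self.test = np.asarray(self.test, dtype=bool)
        if self.gt.shape != self.test.shape:
            raise ShapeError(
                f"mask shapes differ: {self.gt.shape} vs {self.test.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)


def _as_pair(gt, test=None, spacing=(1.0, 1.0, 1.0)) -> MaskPair:
    if isinstance(gt, MaskPair):
        return gt
    return MaskPair(gt, test, spacing)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >=1 background face-neighbour (boolean mask)."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def dsc(gt, test=None, spacing=(1.0, 1.0, 1.0)) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Returns 1.0 when both masks are empty (perfect agreement on nothing)
    and 0.0 when exactly one is empty.
    """
    pair = _as_pair(gt, test, spacing)
    a, b = int(pair.gt.sum()), int(pair.test.sum())
    if a + b == 0:
        return 1.0
    inter = int(np.sum(pair.gt & pair.test))
    return 2.0 * inter / (a + b)


def _scaled_boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    pts = np.argwhere(boundary_voxels(mask)).astype(float)
    return pts * np.asarray(spacing, dtype=float)


def hausdorff(gt, test=None, spacing=(1.0, 1.0, 1.0)) -> float:
    """Exact symmetric Hausdorff distance between mask boundaries, in mm."""
    pair = _as_pair(gt, test, spacing)
    if not pair.gt.any() or not pair.test.any():
        raise UndefinedMetricError("Hausdorff distance undefined for empty masks")
    sp = pair.spacing
    if pair.gt.ndim == 2:  # allow 2-D use for the per-slice variant
        sp = sp[-2:]
    pa = _scaled_boundary_points(pair.gt, sp)
    pb = _scaled_boundary_points(pair.test, sp)
    d_ab = directed_hausdorff(pa, pb)[0]
    d_ba = directed_hausdorff(pb, pa)[0]
    return float(max(d_ab, d_ba))


def hausdorff_slicewise_mean(gt, test=None, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean of per-slice 2-D Hausdorff distances (mm), over slices where
    both masks are non-empty.  A companion to the exact per-volume HD for
    axial reporting; which slices contribute is part of the definition, so
    the variant is named explicitly.
    """
    pair = _as_pair(gt, test, spacing)
    values = []
    for s in range(pair.gt.shape[0]):
        if pair.gt[s].any() and pair.test[s].any():
            values.append(hausdorff(pair.gt[s], pair.test[s], pair.spacing))
    if not values:
        raise UndefinedMetricError("no slice has both masks non-empty")
    return float(np.mean(values))


def sens_spec(gt, test=None, spacing=(1.0, 1.0, 1.0)) -> Tuple[float, float]:
    """(sensitivity, specificity) = (TP/P, TN/N) over voxels."""
    pair = _as_pair(gt, test, spacing)
    p = int(pair.gt.sum())
    n = pair.gt.size - p
    if p == 0:
        raise UndefinedMetricError("sensitivity undefined: reference is empty")
    if n == 0:
        raise UndefinedMetricError("specificity undefined: reference covers everything")
    tp = int(np.sum(pair.gt & pair.test))
    tn = int(np.sum(~pair.gt & ~pair.test))
    return tp / p, tn / n


def evaluate_pair(gt, test=None, spacing=(1.0, 1.0, 1.0)) -> dict:
    """All per-volume metrics as a plain dict (JSON-friendly)."""
    pair = _as_pair(gt, test, spacing)
    out = {"dsc": dsc(pair)}
    try:
        out["hausdorff_mm"] = hausdorff(pair)
        out["hausdorff_slicewise_mean_mm"] = hausdorff_slicewise_mean(pair)
    except UndefinedMetricError:
        out["hausdorff_mm"] = None
        out["hausdorff_slicewise_mean_mm"] = None
    try:
        sens, spec = sens_spec(pair)
        out["sensitivity"], out["specificity"] = sens, spec
    except UndefinedMetricError:
        out["sensitivity"] = out["specificity"] = None
    return out


def _default_success(outcome: dict) -> bool:
    """A run succeeds when it returns a usable (non-empty) mask."""
    mask_nonempty = outcome.get("mask_nonempty")
    if mask_nonempty is None:
        mask_nonempty = outcome.get("dsc") is not None
    return bool(mask_nonempty)


@dataclass
class CohortResult:
    """Per-volume metric bundles plus the cohort self-adaptability."""

    per_volume: List[dict]
    success_flags: List[bool]
    self_adaptability_pct: float


def self_adaptability(
    outcomes: Sequence[dict],
    success_rule: Optional[Callable[[dict], bool]] = None,
) -> CohortResult:
    """Fraction of volumes the pipeline segments to a usable result.

    ``outcomes`` are per-volume dicts (e.g. from :func:`evaluate_pair`,
    optionally with a ``mask_nonempty`` flag).  The default success rule —
    the system returned a non-empty mask at all, without manual rescue —
    is deliberately weak: it measures robustness, not accuracy.  Returned
    as a percentage.
    """
    if len(outcomes) == 0:
        raise ValueError("self_adaptability needs at least one volume")
    rule = success_rule or _default_success
    flags = [bool(rule(o)) for o in outcomes]
    pct = 100.0 * sum(flags) / len(flags)
    return CohortResult(per_volume=list(outcomes), success_flags=flags,
                        self_adaptability_pct=pct)
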