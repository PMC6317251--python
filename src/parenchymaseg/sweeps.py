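"""Experiment harnesses: patch-size sweep and one-at-a-time hyper-parameter
sweep for the patch classifier."""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import train_test_split

from .errors import UndefinedMetricError
from .labelgen import WeakPatchLabeler, split_into_patches
from .metrics import evaluate_predictions
from .volume import LabeledVolume

__all__ = ["patch_grid_ground_truth", "patch_size_sweep", "hyperparameter_sweep"]

DEFAULT_SIZES = (64, 32, 16, 8, 4, 2)


def patch_grid_ground_truth(gt_mask: np.ndarray, patch_size: int) -> np.ndarray:
    """Patch-majority ground truth: a cell is LP if >50% of its pixels are."""
    grid, records = split_into_patches(gt_mask.astype(np.float32), patch_size)
    return records.mean > 0.5


def patch_size_sweep(
    labeled: LabeledVolume,
    sizes: Sequence[int] = DEFAULT_SIZES,
    seed: int = 0,
) -> List[Dict]:
    """Run the clustering stage at several patch sizes on one phantom.

    For each size dividing the slice dimensions, reports the patch count
    and the patch-level agreement between the generated LP labels and the
    patch-majority ground truth.  Smaller patches resolve lesions and
    boundaries better (higher agreement); non-dividing sizes are skipped
    with a warning.  Wall-clock time is not part of the comparison.
    """
    rows_px, cols_px = labeled.volume.slice_shape
    out: List[Dict] = []
    for size in sizes:
        if rows_px % size or cols_px % size:
            warnings.warn(f"patch size {size} does not divide slice shape; skipped",
                          stacklevel=2)
            continue
        labeler = WeakPatchLabeler(patch_size=size, random_state=seed)
        labeler.fit(labeled.volume)
        gt_patches = patch_grid_ground_truth(labeled.gt_parenchyma, size)
        agreement = float(np.mean(labeler.lp_mask_ == gt_patches))
        out.append({
            "patch_size": size,
            "n_patches": labeler.grid_.n_patches,
            "patches_per_slice": labeler.grid_.cells_per_slice,
            "agreement_with_gt": agreement,
        })
    return out


def hyperparameter_sweep(
    X: np.ndarray,
    y: np.ndarray,
    base_estimator,
    variations: Sequence[Dict],
    val_fraction: float = 1.0 / 8.0,
    seed: int = 0,
) -> List[Dict]:
    """One-at-a-time hyper-parameter study on a fixed train/validation split.

    ``variations`` is a list of ``{param: value}`` overrides applied to a
    clone of ``base_estimator`` (an empty dict evaluates the reference
    setting).  Each model is trained on the same stratified 7:1 split and
    scored by F_avg on the validation part.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=val_fraction, stratify=y, random_state=seed
    )
    rows: List[Dict] = []
    for overrides in variations:
        model = clone(base_estimator)
        if overrides:
            model.set_params(**overrides)
        model.fit(X_tr, y_tr)
        proba = model.predict_proba(X_val)
        pred = model.classes_[(proba[:, 1] > 0.5).astype(int)]
        row = dict(model.get_params())
        row.pop("hu_window", None)
        try:
            report = evaluate_predictions(y_val, pred, proba[:, 1])
            row["f_avg"] = report.f_avg
            row["accuracy"] = report.accuracy
        except UndefinedMetricError:
            # a collapsed model (single-class predictions) has no F-score;
            # record the row rather than aborting the whole sweep
            row["f_avg"] = None
            row["accuracy"] = float(np.mean(pred == y_val))
        rows.append(row)
    return rows
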