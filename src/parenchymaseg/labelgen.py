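"""Weak-label generation: from a raw CT volume to a balanced patch dataset.

The pipeline produces training labels with no manual annotation:

1. every 512x512 slice is tiled into non-overlapping 8x8 patches and each
   patch is summarised by its mean and minimum intensity;
2. two-class k-means is run twice over all patches of the volume(s), once
   on the mean and once on the minimum, grouping lung parenchyma and
   outside-body air into the "low" cluster;
3. cross-shaped verification discards low patches that do not see a high
   patch in all four in-slice directions (left/right/up/down rays spanning
   the whole row/column), removing outside-body air;
4. the two surviving patch volumes are intersected — the mean branch keeps
   spurious patches in the body–bed air gap, the min branch has the
   complementary artifact, and the intersection cancels both;
5. 3-D connected-component analysis over patch addresses retains the lung
   components (up to the two largest above a size floor);
6. each surviving 8x8 cell is expanded to the 32x32 pixel window sharing
   its centre, and an equal number of non-lung windows is sampled at
   random, giving a balanced two-class dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import BalanceError, DegenerateInputError, GridError, ShapeError
from .volume import CTVolume

__all__ = [
    "PatchGrid",
    "PatchRecords",
    "LabeledPatchSet",
    "split_into_patches",
    "kmeans_two_class",
    "cross_shaped_verify",
    "run_single_clustering",
    "intersect_volumes",
    "extract_lung_components",
    "expand_patch",
    "balance_addresses",
    "build_labeled_dataset",
    "WeakPatchLabeler",
]

AIR_FILL_HU = -1024.0


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping tiling of a slice stack into square patches.

    Address ``(s, i, j)`` maps to the pixel block
    ``[i*patch_size, (i+1)*patch_size) x [j*patch_size, (j+1)*patch_size)``
    of slice ``s``.
    """

    patch_size: int
    n_slices: int
    n_rows: int
    n_cols: int

    @property
    def n_patches(self) -> int:
        return self.n_slices * self.n_rows * self.n_cols

    @property
    def cells_per_slice(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class PatchRecords:
    """Per-patch statistics stored as dense struct-of-arrays.

    ``mean`` and ``min`` have shape ``(n_slices, n_rows, n_cols)``; a record
    for address ``(s, i, j)`` is the pair ``mean[s, i, j], min[s, i, j]``.
    Dense arrays keep ten-million-patch volumes tractable.
    """

    grid: PatchGrid
    mean: np.ndarray
    min: np.ndarray

    def __len__(self) -> int:
        return self.grid.n_patches

    def statistic(self, name: Literal["mean", "min"]) -> np.ndarray:
        if name not in ("mean", "min"):
            raise ValueError(f"unknown patch statistic {name!r}")
        return getattr(self, name)


def split_into_patches(
    volume: CTVolume | np.ndarray, patch_size: int = 8
) -> Tuple[PatchGrid, PatchRecords]:
    """Tile every slice into ``patch_size`` x ``patch_size`` cells.

    Returns the grid geometry and one record (mean, min intensity) per
    cell.  Raises :class:`GridError` when the slice dimensions are not
    divisible by ``patch_size``.
    """
    voxels = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    if voxels.ndim != 3:
        raise ShapeError(f"expected a 3-D slice stack, got shape {voxels.shape}")
    n, rows, cols = voxels.shape
    if patch_size <= 0 or rows % patch_size or cols % patch_size:
        raise GridError(
            f"slice shape ({rows}, {cols}) not divisible by patch size {patch_size}"
        )
    nr, nc = rows // patch_size, cols // patch_size
    blocks = voxels.reshape(n, nr, patch_size, nc, patch_size)
    mean = blocks.mean(axis=(2, 4), dtype=np.float64).astype(np.float32)
    mn = blocks.min(axis=(2, 4)).astype(np.float32)
    grid = PatchGrid(patch_size=patch_size, n_slices=n, n_rows=nr, n_cols=nc)
    return grid, PatchRecords(grid=grid, mean=mean, min=mn)


def kmeans_two_class(
    values: Sequence[float] | np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> np.ndarray:
    """Exact two-class 1-D k-means; returns False=low, True=high per value.

    For one-dimensional data the optimal two-cluster partition is always a
    threshold partition of the sorted values, so the global minimum of the
    within-cluster sum of squares can be found exactly by sweeping all
    ``n - 1`` split points with prefix sums — equivalent to Lloyd's
    algorithm run to the global optimum, but deterministic and free of
    local minima.  ``seed``, ``tol`` and ``max_iter`` are accepted for
    interface symmetry; the exact solver needs none of them.

    Raises
    ------
    DegenerateInputError
        If all values are identical (no two-cluster structure exists).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2 or np.all(v == v[0]):
        raise DegenerateInputError("k-means needs at least two distinct values")
    order = np.argsort(v, kind="stable")
    sv = v[order]
    c1 = np.cumsum(sv)
    c2 = np.cumsum(sv * sv)
    n = sv.size
    k = np.arange(1, n)  # low cluster = first k sorted values
    lo_cost = c2[k - 1] - c1[k - 1] ** 2 / k
    hi_sum = c1[-1] - c1[k - 1]
    hi_cost = (c2[-1] - c2[k - 1]) - hi_sum**2 / (n - k)
    best = int(np.argmin(lo_cost + hi_cost))  # first minimum on ties
    threshold = sv[best]
    return v > threshold


def cross_shaped_verify(low_mask: np.ndarray) -> np.ndarray:
    """Keep a low patch only if every in-slice ray hits a high patch.

    A low patch at grid position ``(i, j)`` survives iff each of the four
    rays — left ``(i, j' < j)``, right ``(i, j' > j)``, up ``(i' < i, j)``
    and down ``(i' > i, j)`` — contains at least one high (non-low) patch.
    Rays span the entire row/column of the slice, so low patches on the
    grid border are always discarded (their outward ray is empty); this is
    what removes outside-body air.
    """
    low = np.asarray(low_mask, dtype=bool)
    if low.ndim != 2:
        raise ShapeError("cross_shaped_verify expects one slice of patch addresses")
    high = ~low

    def _directional(any_high_before: np.ndarray) -> np.ndarray:
        return any_high_before

    # exclusive cumulative "any high so far" along each of the four directions
    left = np.zeros_like(high)
    left[:, 1:] = np.logical_or.accumulate(high, axis=1)[:, :-1]
    right = np.zeros_like(high)
    right[:, :-1] = np.logical_or.accumulate(high[:, ::-1], axis=1)[:, ::-1][:, 1:]
    up = np.zeros_like(high)
    up[1:, :] = np.logical_or.accumulate(high, axis=0)[:-1, :]
    down = np.zeros_like(high)
    down[:-1, :] = np.logical_or.accumulate(high[::-1, :], axis=0)[::-1, :][1:, :]

    return low & left & right & up & down


def run_single_clustering(
    records: PatchRecords,
    statistic: Literal["mean", "min"],
    seed: int = 0,
) -> np.ndarray:
    """Cluster all patches on one statistic, then verify slice by slice.

    All patches of the volume are clustered jointly; the resulting low
    mask is filtered with :func:`cross_shaped_verify` per slice.  Returns
    a boolean kept-mask over patch addresses, shape
    ``(n_slices, n_rows, n_cols)``.
    """
    values = records.statistic(statistic)
    high = kmeans_two_class(values.ravel(), seed=seed).reshape(values.shape)
    low = ~high
    kept = np.zeros_like(low)
    for s in range(low.shape[0]):
        kept[s] = cross_shaped_verify(low[s])
    return kept


def intersect_volumes(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Logical AND of two kept-masks defined on the same patch grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a & b


def extract_lung_components(
    mask: np.ndarray,
    connectivity: int = 6,
    min_size_frac: float = 0.01,
    max_components: int = 2,
) -> np.ndarray:
    """Retain the lung connected components of a patch-address mask.

    Components are labeled in 3-D over patch addresses (6- or
    26-connectivity); those with size >= ``min_size_frac`` of the total
    patch count are candidates, of which at most the ``max_components``
    largest are kept — two lungs being the anatomical prior.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("extract_lung_components: empty input mask", stacklevel=2)
        return np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n_comp = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    min_size = max(1, int(np.ceil(min_size_frac * mask.size)))
    candidates = np.flatnonzero(sizes >= min_size)
    if candidates.size == 0:
        warnings.warn("extract_lung_components: no component above size floor",
                      stacklevel=2)
        return np.zeros_like(mask)
    # stable sort: largest first, earlier label wins ties
    order = candidates[np.argsort(-sizes[candidates], kind="stable")]
    keep = order[:max_components]
    return np.isin(labels, keep)


def expand_patch(
    volume: CTVolume | np.ndarray,
    address: Tuple[int, int, int],
    out_size: int = 32,
    patch_size: int = 8,
    fill: float = AIR_FILL_HU,
) -> np.ndarray:
    """Expand a grid cell to the ``out_size`` window sharing its centre.

    For the default 8->32 expansion the window of cell ``(s, i, j)`` covers
    rows ``[8i-12, 8i+20)`` and cols ``[8j-12, 8j+20)``; parts extending
    past the slice are filled with air (-1024 HU), the physically neutral
    value, so edge patches keep a realistic intensity distribution.
    """
    voxels = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    s, i, j = address
    offset = (out_size - patch_size) // 2
    r0 = i * patch_size - offset
    c0 = j * patch_size - offset
    out = np.full((out_size, out_size), fill, dtype=np.float32)
    rows, cols = voxels.shape[1], voxels.shape[2]
    rr0, rr1 = max(r0, 0), min(r0 + out_size, rows)
    cc0, cc1 = max(c0, 0), min(c0 + out_size, cols)
    if rr0 < rr1 and cc0 < cc1:
        out[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = voxels[s, rr0:rr1, cc0:cc1]
    return out


@dataclass
class LabeledPatchSet:
    """The balanced two-class patch dataset fed to the classifier.

    ``patches`` holds ``out_size`` x ``out_size`` intensity windows,
    ``labels`` is 1 for lung parenchyma (LP) and 0 for non-lung-parenchyma
    (NLP), and ``addresses`` records each patch's source grid cell
    ``(slice, i, j)``.
    """

    patches: np.ndarray
    labels: np.ndarray
    addresses: np.ndarray

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.addresses = np.asarray(self.addresses, dtype=np.int64)
        if len(self.patches) != len(self.labels) or len(self.labels) != len(self.addresses):
            raise ShapeError("patches, labels and addresses must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def counts(self) -> Tuple[int, int]:
        """(n_lp, n_nlp)"""
        n_lp = int(np.sum(self.labels == 1))
        return n_lp, len(self.labels) - n_lp

    def save(self, path, manifest: Optional[dict] = None) -> None:
        import json

        kwargs = dict(patches=self.patches, labels=self.labels, addresses=self.addresses)
        if manifest is not None:
            kwargs["manifest"] = np.frombuffer(
                json.dumps(manifest).encode(), dtype=np.uint8
            )
        np.savez_compressed(path, **kwargs)

    @classmethod
    def load(cls, path) -> "LabeledPatchSet":
        with np.load(path) as data:
            return cls(data["patches"], data["labels"], data["addresses"])


def balance_addresses(
    lp_addresses: np.ndarray,
    candidate_addresses: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Sample NLP addresses to match the LP count exactly.

    Uniform sampling without replacement over ``candidate_addresses``
    (all non-LP grid cells), seeded for reproducibility.  Raises
    :class:`BalanceError` when there are fewer candidates than positives.
    """
    lp_addresses = np.asarray(lp_addresses)
    candidate_addresses = np.asarray(candidate_addresses)
    n_lp = len(lp_addresses)
    if len(candidate_addresses) < n_lp:
        raise BalanceError(
            f"need {n_lp} negative patches but only "
            f"{len(candidate_addresses)} candidates are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidate_addresses), size=n_lp, replace=False)
    return candidate_addresses[np.sort(idx)]


def build_labeled_dataset(
    volume: CTVolume | np.ndarray,
    lp_mask: np.ndarray,
    seed: int = 0,
    out_size: int = 32,
    patch_size: int = 8,
) -> LabeledPatchSet:
    """Expand LP cells and an equal random sample of NLP cells into patches.

    ``lp_mask`` is the boolean patch-address mask surviving
    :func:`extract_lung_components`.  Class balance is exact: ``|LP| ==
    |NLP|``.  An empty ``lp_mask`` yields an empty dataset with a warning.
    """
    lp_mask = np.asarray(lp_mask, dtype=bool)
    lp_addr = np.argwhere(lp_mask)
    if len(lp_addr) == 0:
        warnings.warn("build_labeled_dataset: no LP addresses; empty dataset",
                      stacklevel=2)
        empty = np.empty((0, out_size, out_size), dtype=np.float32)
        return LabeledPatchSet(empty, np.empty(0, dtype=np.int8),
                               np.empty((0, 3), dtype=np.int64))
    nlp_candidates = np.argwhere(~lp_mask)
    nlp_addr = balance_addresses(lp_addr, nlp_candidates, seed=seed)

    def _extract(addresses: np.ndarray) -> np.ndarray:
        return np.stack(
            [expand_patch(volume, tuple(a), out_size, patch_size) for a in addresses]
        )

    patches = np.concatenate([_extract(lp_addr), _extract(nlp_addr)])
    labels = np.concatenate(
        [np.ones(len(lp_addr), dtype=np.int8), np.zeros(len(nlp_addr), dtype=np.int8)]
    )
    addresses = np.concatenate([lp_addr, nlp_addr])
    return LabeledPatchSet(patches, labels, addresses)


class WeakPatchLabeler:
    """Estimator-style wrapper around the full weak-label pipeline.

    ``fit`` runs gridding, dual clustering, verification, intersection and
    component extraction on a volume, exposing every intermediate as a
    fitted attribute; ``transform`` materialises the balanced
    :class:`LabeledPatchSet`.

    Parameters
    ----------
    patch_size : int
        Grid cell size in pixels (8 by default).
    out_size : int
        Side of the expanded patches fed to the classifier (32).
    connectivity : {6, 26}
        3-D adjacency for component extraction over patch addresses.
    min_size_frac, max_components
        Lung-component retention rule.
    random_state : int
        Seed for clustering and negative sampling.
    """

    def __init__(
        self,
        patch_size: int = 8,
        out_size: int = 32,
        connectivity: int = 6,
        min_size_frac: float = 0.01,
        max_components: int = 2,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.out_size = out_size
        self.connectivity = connectivity
        self.min_size_frac = min_size_frac
        self.max_components = max_components
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "patch_size": self.patch_size,
            "out_size": self.out_size,
            "connectivity": self.connectivity,
            "min_size_frac": self.min_size_frac,
            "max_components": self.max_components,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "WeakPatchLabeler":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: CTVolume | np.ndarray, y=None) -> "WeakPatchLabeler":
        self.grid_, self.records_ = split_into_patches(X, self.patch_size)
        self.kept_mean_ = run_single_clustering(self.records_, "mean", self.random_state)
        self.kept_min_ = run_single_clustering(self.records_, "min", self.random_state)
        self.intersection_ = intersect_volumes(self.kept_mean_, self.kept_min_)
        self.lp_mask_ = extract_lung_components(
            self.intersection_,
            connectivity=self.connectivity,
            min_size_frac=self.min_size_frac,
            max_components=self.max_components,
        )
        return self

    def transform(self, X: CTVolume | np.ndarray) -> LabeledPatchSet:
        if not hasattr(self, "lp_mask_"):
            raise RuntimeError("WeakPatchLabeler must be fitted before transform")
        return build_labeled_dataset(
            X, self.lp_mask_, seed=self.random_state,
            out_size=self.out_size, patch_size=self.patch_size,
        )

    def fit_transform(self, X: CTVolume | np.ndarray, y=None) -> LabeledPatchSet:
        return self.fit(X).transform(X)
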