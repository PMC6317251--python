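"""Synthetic thoracic CT phantoms with analytic ground truth.

The phantom emulates the axial-slice anatomy the weak-label pipeline relies
on: low-attenuation background air, a high-attenuation elliptical body,
two low-attenuation lung fields inside the body, a scanner bed separated
from the body by an air gap, and optional high-attenuation lesions placed
inside the lung fields or on their border (effusion-like rims).

The scanner bed matters: under mean-intensity patch clustering the air gap
between body and bed clusters together with the lung fields, which is
exactly the artifact the dual clustering + intersection step exists to
remove.  Ground truth is analytic — the parenchyma mask is the rasterized
lung-ellipse interiors minus lesion voxels — so every downstream stage can
be scored without manual annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError
from .volume import CTVolume, LabeledVolume

__all__ = ["Ellipse", "Lesion", "PhantomSpec", "generate_phantom", "default_spec"]

#: default tissue intensities in HU
TISSUE_HU: Dict[str, float] = {
    "air": -1000.0,
    "parenchyma": -850.0,
    "body": 40.0,
    "bed": 100.0,
    "lesion": 30.0,
}


@dataclass(frozen=True)
class Ellipse:
    """An axis-aligned ellipse: centre ``(row, col)`` and semi-axes in pixels."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        cr, ccen = self.center
        a, b = self.semi_axes
        return ((rr - cr) / a) ** 2 + ((cc - ccen) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class Lesion:
    """A circular high-attenuation lesion on every slice of a range.

    ``center`` is ``(row, col)``; the lesion spans slices
    ``[slice_start, slice_stop)`` (the whole stack when both are None),
    giving a cylindrical region — adequate for a 2.5-D phantom.
    """

    center: Tuple[float, float]
    radius: float
    intensity: float = TISSUE_HU["lesion"]
    slice_start: Optional[int] = None
    slice_stop: Optional[int] = None

    def disk(self, shape: Tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass
class PhantomSpec:
    """Full geometric and radiometric description of a phantom volume."""

    n_slices: int = 20
    slice_shape: Tuple[int, int] = (512, 512)
    body: Ellipse = None  # type: ignore[assignment]
    lungs: Tuple[Ellipse, Ellipse] = None  # type: ignore[assignment]
    bed: Tuple[int, int, int, int] = None  # (row0, row1, col0, col1)
    lesions: List[Lesion] = field(default_factory=list)
    tissue_hu: Dict[str, float] = field(default_factory=lambda: dict(TISSUE_HU))
    noise_sigma: float = 20.0
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices <= 0:
            raise GeometryError("n_slices must be positive")
        if self.body is None or self.lungs is None:
            raise GeometryError("body and lung ellipses are required")

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "n_slices": self.n_slices,
            "slice_shape": list(self.slice_shape),
            "body": {"center": list(self.body.center),
                     "semi_axes": list(self.body.semi_axes)},
            "lungs": [{"center": list(l.center), "semi_axes": list(l.semi_axes)}
                      for l in self.lungs],
            "bed": list(self.bed) if self.bed is not None else None,
            "lesions": [{"center": list(l.center), "radius": l.radius,
                         "intensity": l.intensity,
                         "slice_start": l.slice_start, "slice_stop": l.slice_stop}
                        for l in self.lesions],
            "tissue_hu": dict(self.tissue_hu),
            "noise_sigma": self.noise_sigma,
            "spacing": list(self.spacing),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            n_slices=d["n_slices"],
            slice_shape=tuple(d["slice_shape"]),
            body=Ellipse(tuple(d["body"]["center"]), tuple(d["body"]["semi_axes"])),
            lungs=tuple(Ellipse(tuple(l["center"]), tuple(l["semi_axes"]))
                        for l in d["lungs"]),
            bed=tuple(d["bed"]) if d.get("bed") is not None else None,
            lesions=[Lesion(tuple(l["center"]), l["radius"], l["intensity"],
                            l.get("slice_start"), l.get("slice_stop"))
                     for l in d.get("lesions", [])],
            tissue_hu=dict(d.get("tissue_hu", TISSUE_HU)),
            noise_sigma=d.get("noise_sigma", 20.0),
            spacing=tuple(d.get("spacing", (1.0, 1.0, 1.0))),
            seed=d.get("seed", 0),
        )


def default_spec(
    n_slices: int = 20,
    slice_shape: Tuple[int, int] = (512, 512),
    lesions: Sequence[Lesion] = (),
    noise_sigma: float = 20.0,
    seed: int = 0,
) -> PhantomSpec:
    """A standard two-lung phantom scaled to ``slice_shape``.

    Geometry is expressed as fractions of the slice so the same anatomy is
    produced at any resolution: the body fills ~70% of the field of view,
    each lung ~45% x 22% of it, and a thin bed slab sits below the body
    with an air gap of a few rows.
    """
    nr, nc = slice_shape
    # chest wall deliberately thick (>= ~2 patch widths between lung and body
    # boundary) so that patches of pure body tissue exist along every ray —
    # the anatomy the cross-shaped verification relies on
    body = Ellipse(center=(0.46 * nr, 0.50 * nc), semi_axes=(0.36 * nr, 0.42 * nc))
    lungs = (
        Ellipse(center=(0.46 * nr, 0.32 * nc), semi_axes=(0.18 * nr, 0.10 * nc)),
        Ellipse(center=(0.46 * nr, 0.68 * nc), semi_axes=(0.18 * nr, 0.10 * nc)),
    )
    bed_row0 = int(0.86 * nr)
    bed = (bed_row0, bed_row0 + max(2, nr // 50), int(0.15 * nc), int(0.85 * nc))
    return PhantomSpec(
        n_slices=n_slices,
        slice_shape=slice_shape,
        body=body,
        lungs=lungs,
        bed=bed,
        lesions=list(lesions),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _validate_geometry(spec: PhantomSpec, body_mask: np.ndarray,
                       lung_masks: Sequence[np.ndarray]) -> None:
    from scipy.ndimage import binary_dilation

    for k, lm in enumerate(lung_masks):
        if not np.all(body_mask[lm]):
            raise GeometryError(f"lung ellipse {k} is not strictly inside the body")
    if spec.bed is not None:
        r0, r1, c0, c1 = spec.bed
        bed_mask = np.zeros(spec.slice_shape, dtype=bool)
        bed_mask[r0:r1, c0:c1] = True
        # >=1 background row between bed and body
        if np.any(binary_dilation(bed_mask, iterations=1) & body_mask):
            raise GeometryError("bed must be separated from the body by an air gap")


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Rasterize a phantom spec into a volume plus ground-truth masks.

    Deterministic given ``spec.seed``.  Gaussian noise of ``noise_sigma`` HU
    is added independently to every voxel of every tissue.
    """
    shape2d = spec.slice_shape
    hu = spec.tissue_hu
    body_mask = spec.body.mask(shape2d)
    lung_masks = [lung.mask(shape2d) for lung in spec.lungs]
    _validate_geometry(spec, body_mask, lung_masks)

    template = np.full(shape2d, hu["air"], dtype=np.float32)
    template[body_mask] = hu["body"]
    lung_all = np.zeros(shape2d, dtype=bool)
    for lm in lung_masks:
        lung_all |= lm
    template[lung_all] = hu["parenchyma"]
    if spec.bed is not None:
        r0, r1, c0, c1 = spec.bed
        template[r0:r1, c0:c1] = hu["bed"]

    n = spec.n_slices
    voxels = np.repeat(template[None], n, axis=0)
    gt_parenchyma = np.repeat(lung_all[None], n, axis=0).copy()
    gt_lesions = np.zeros_like(gt_parenchyma)

    for lesion in spec.lesions:
        disk = lesion.disk(shape2d)
        s0 = 0 if lesion.slice_start is None else lesion.slice_start
        s1 = n if lesion.slice_stop is None else lesion.slice_stop
        voxels[s0:s1, disk] = lesion.intensity
        gt_lesions[s0:s1] |= disk[None]
    gt_parenchyma &= ~gt_lesions
    # lesions only count as lesions where they sit on lung tissue or its rim;
    # clip to the lung fields so gt_lesions stays meaningful for border lesions
    gt_lesions &= np.repeat(lung_all[None], n, axis=0)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sigma, voxels.shape).astype(np.float32)

    volume = CTVolume(voxels, spacing=spec.spacing)
    return LabeledVolume(volume, gt_parenchyma, gt_lesions)
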