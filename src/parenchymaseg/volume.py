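"""CT volume container and file I/O.

Volumes are stored as 3-D arrays indexed ``(slice, row, col)`` with
intensities on the Hounsfield-unit scale (air ~ -1000 HU, water 0 HU,
soft tissue ~ +40 HU).  Supported on-disk formats:

* NIfTI (``.nii`` / ``.nii.gz``) via :mod:`nibabel` — the array is stored
  in the package's ``(slice, row, col)`` axis order with voxel spacing
  ``(dz, dy, dx)`` recorded in the header zooms, so round-trips are exact.
* A directory of per-slice ``.npy`` 2-D arrays (sorted by file name), or a
  single 3-D ``.npy`` file.
* DICOM series directories (read-only); ``RescaleSlope``/``RescaleIntercept``
  are applied so intensities come back in HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import ShapeError, VolumeIOError

__all__ = ["CTVolume", "LabeledVolume", "read_volume", "write_volume", "write_mask", "read_mask"]


@dataclass
class CTVolume:
    """A stack of CT slices with voxel spacing metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, rows, cols)
        Intensities in HU-like units.  Any integer or float dtype.
    spacing : tuple of float
        Voxel spacing ``(dz, dy, dx)`` in millimetres.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ShapeError(
                f"volume must be 3-D (slice, row, col), got shape {self.voxels.shape}"
            )
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must be (dz, dy, dx)")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> Tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]


@dataclass
class LabeledVolume:
    """A CT volume paired with its ground-truth masks.

    ``gt_parenchyma`` marks functional lung tissue; ``gt_lesions`` marks
    high-attenuation pathology.  The two masks are disjoint by construction
    (lesion voxels are carved out of the parenchyma).
    """

    volume: CTVolume
    gt_parenchyma: np.ndarray
    gt_lesions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gt_parenchyma = np.asarray(self.gt_parenchyma, dtype=bool)
        if self.gt_lesions is None:
            self.gt_lesions = np.zeros_like(self.gt_parenchyma)
        self.gt_lesions = np.asarray(self.gt_lesions, dtype=bool)
        shape = self.volume.voxels.shape
        if self.gt_parenchyma.shape != shape or self.gt_lesions.shape != shape:
            raise ShapeError("ground-truth masks must match the volume shape")
        if np.any(self.gt_parenchyma & self.gt_lesions):
            raise ValueError("gt_parenchyma and gt_lesions must be disjoint")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npy"):
        return "npy"
    if path.is_dir():
        if any(p.suffix == ".npy" for p in path.iterdir()):
            return "npy-stack"
        return "dicom-dir"
    raise VolumeIOError(f"cannot infer volume format for {path}")


def read_volume(path, format: Optional[str] = None) -> CTVolume:
    """Read a CT volume from disk.

    Parameters
    ----------
    path : str or Path
        File or directory to read.
    format : {"nifti", "npy", "npy-stack", "dicom-dir"}, optional
        Explicit format; inferred from the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "npy":
        arr = np.load(path)
        if arr.ndim != 3:
            raise ShapeError(f"{path}: expected 3-D array, got shape {arr.shape}")
        return CTVolume(arr)
    if fmt == "npy-stack":
        return _read_npy_stack(path)
    if fmt == "dicom-dir":
        return _read_dicom_dir(path)
    raise VolumeIOError(f"unrecognized format {fmt!r}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"unreadable NIfTI file {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ShapeError(f"{path}: expected 3-D NIfTI, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(arr, spacing=tuple(float(z) for z in zooms))


def _read_npy_stack(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.suffix == ".npy")
    if not files:
        raise VolumeIOError(f"no .npy slices in {path}")
    slices = [np.load(f) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ShapeError(f"{path}: non-uniform slice shapes {sorted(shapes)}")
    if slices[0].ndim != 2:
        raise ShapeError(f"{path}: slices must be 2-D, got shape {slices[0].shape}")
    return CTVolume(np.stack(slices, axis=0))


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    datasets = []
    for f in sorted(path.iterdir()):
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files quietly
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise VolumeIOError(f"no readable DICOM slices in {path}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ShapeError(f"{path}: non-uniform DICOM slice shapes {sorted(shapes)}")
    ds0 = datasets[0]
    dy, dx = (float(v) for v in getattr(ds0, "PixelSpacing", (1.0, 1.0)))
    dz = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(np.stack(slices, axis=0), spacing=(dz, dy, dx))


def write_volume(volume: CTVolume, path, format: Optional[str] = None) -> None:
    """Write a CT volume to NIfTI or a single 3-D ``.npy`` file."""
    path = Path(path)
    fmt = format or ("nifti" if path.name.lower().endswith((".nii", ".nii.gz")) else "npy")
    _write_array(volume.voxels, volume.spacing, path, fmt)


def _write_array(arr: np.ndarray, spacing, path: Path, fmt: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(tuple(spacing))
        try:
            nib.save(img, str(path))
        except Exception as exc:
            raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    elif fmt == "npy":
        try:
            np.save(path, arr)
        except OSError as exc:
            raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    else:
        raise VolumeIOError(f"unrecognized format {fmt!r}")


def write_mask(mask: np.ndarray, path, format: Optional[str] = None,
               spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    """Write a binary segmentation mask (as uint8) to NIfTI or ``.npy``.

    Raises
    ------
    ValueError
        If the mask contains values other than 0 and 1.
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary, found values {vals[:10]}")
    path = Path(path)
    fmt = format or ("nifti" if path.name.lower().endswith((".nii", ".nii.gz")) else "npy")
    _write_array(mask.astype(np.uint8), tuple(spacing), path, fmt)


def read_mask(path, format: Optional[str] = None) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`."""
    vol = read_volume(path, format=format)
    return np.asarray(vol.voxels, dtype=bool)
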