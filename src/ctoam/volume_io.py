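"""Volumetric and tabular I/O for the density-mapping pipeline.

The in-memory container is :class:`CtVolume`: a 3-D array of attenuation
values in Hounsfield units (HU) plus physical voxel spacing, origin and
anatomical axis labels.  All internal coordinates are 0-based voxel indices;
physical positions (mm) are derived as ``origin + index * spacing``.

Supported on-disk formats: NIfTI (.nii / .nii.gz) for volumes, CSV for result
tables, PNG for 2-D maps.  Reading a DICOM series requires ``pydicom``, which
is an optional dependency; without it :func:`read_volume` raises a clear
error.  The HU rescale arithmetic used for DICOM stored values is exposed as
:func:`rescale_to_hu` regardless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

#: Default anatomical meaning of the three array axes, in index order.
#: Axis 0 runs proximal -> distal, axis 1 dorsal -> plantar (along the
#: trochlear ridges), axis 2 medial -> lateral.
DEFAULT_AXIS_LABELS = ("proximodistal", "dorsoplantar", "mediolateral")


@dataclass
class CtVolume:
    """A CT volume in Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels
        3-D float array of attenuation values (HU), indexed ``[i, j, k]``.
    spacing_mm
        Physical voxel size per axis (mm), same order as the array axes.
    origin_mm
        Physical position of voxel ``(0, 0, 0)``.
    axis_labels
        Anatomical orientation tag per axis.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError(f"every dimension must be >= 2, got {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be three positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must all be finite")
        self.axis_labels = tuple(self.axis_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axis_index(self, label: str) -> int:
        """Index of the array axis carrying the given anatomical label."""
        try:
            return self.axis_labels.index(label)
        except ValueError:
            raise ValueError(
                f"volume has no axis labelled {label!r}; labels are {self.axis_labels}"
            ) from None

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions (mm) of voxel indices, shape (..., 3)."""
        idx = np.asarray(indices, dtype=np.float64)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)


def rescale_to_hu(stored: np.ndarray | float, slope: float, intercept: float):
    """Convert stored integer values to HU: ``slope * value + intercept``.

    This is the linear rescale defined by the DICOM RescaleSlope /
    RescaleIntercept tags (e.g. slope 1, intercept -1024, stored 1024 -> 0 HU).
    """
    return slope * np.asarray(stored, dtype=np.float64) + intercept


def write_volume(volume: CtVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI.  HU values and spacing round-trip losslessly."""
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, os.fspath(path))


def read_volume(
    path: str | os.PathLike,
    format: str = "nifti",
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS,
) -> CtVolume:
    """Read a CT volume in HU.

    Parameters
    ----------
    path
        A NIfTI file, or a directory holding a DICOM series.
    format
        ``"nifti"`` or ``"dicom_series"``.
    axis_labels
        Anatomical labels to attach (neither format carries them natively).
    """
    if format == "nifti":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
        img = nib.load(os.fspath(p))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
            raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
        spacing = tuple(float(abs(rot[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        return CtVolume(data, spacing, origin, axis_labels)
    if format == "dicom_series":
        return _read_dicom_series(path, axis_labels)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_series'")


def _read_dicom_series(path, axis_labels):
    p = Path(path)
    if not p.is_dir():
        raise FileNotFoundError(f"DICOM series must be a directory: {p}")
    files = sorted(f for f in p.iterdir() if f.is_file())
    if not files:
        raise ValueError(f"empty directory, no DICOM slices found in {p}")
    try:
        import pydicom  # noqa: F401
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise NotImplementedError(
            "reading DICOM series requires the optional dependency 'pydicom', "
            "which is not installed; convert the series to NIfTI instead"
        ) from exc
    raise NotImplementedError("DICOM series assembly is not implemented in this build")


def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | os.PathLike,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records as CSV with a header row.

    Zero rows with an explicit ``columns`` schema produce a header-only file.
    Numeric fields round-trip at full precision (pandas ``repr`` formatting).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            keys = set(rows[0].keys())
            for r in rows[1:]:
                if set(r.keys()) != keys:
                    raise ValueError("all records must share one schema")
        df = pd.DataFrame(rows, columns=columns if columns is not None else None)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(os.fspath(path), index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path))


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D map as PNG.

    ``image`` may be an (H, W) scalar map (rescaled to 8-bit grey over its
    finite range) or an (H, W, 3) uint8 RGB array (written as-is).
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 3:
        Image.fromarray(arr.astype(np.uint8), mode="RGB").save(os.fspath(path))
        return
    if arr.ndim != 2:
        raise ValueError(f"expected (H, W) or (H, W, 3) array, got shape {arr.shape}")
    finite = np.isfinite(arr)
    out = np.zeros(arr.shape, dtype=np.uint8)
    if finite.any():
        lo, hi = arr[finite].min(), arr[finite].max()
        span = hi - lo if hi > lo else 1.0
        out[finite] = np.clip(255 * (arr[finite] - lo) / span, 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="L").save(os.fspath(path))
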