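"""Volume I/O, lung-window normalization, and isotropic resampling.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``; ``spacing`` and ``origin`` follow the same
  order, in millimetres;
* voxel indices are 0-based; the physical position of voxel ``(k, j, i)`` is
  ``origin + index * spacing``;
* intensity volumes are resampled trilinearly, masks nearest-neighbour.

CT intensities are either raw Hounsfield units or, after
:func:`window_normalize`, unitless values in [0, 1] on the standard lung
window (width 1600 HU, level -600 HU).  Normalized values are kept as real
numbers — there is no 8-bit re-quantization, which would round away the
subtle contrast of small nodules.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
import pydicom
from scipy import ndimage


class FormatError(ValueError):
    """Raised for structurally invalid input volumes (e.g. a gappy DICOM series)."""


@dataclass
class CTVolume:
    """A 3D scalar field with voxel spacing and provenance metadata.

    Parameters
    ----------
    data:
        3D array ordered ``(z, y, x)``.  Hounsfield units, or [0, 1] when
        ``normalized`` is true.
    spacing:
        Voxel size ``(z, y, x)`` in mm; strictly positive.
    origin:
        Physical position of voxel (0, 0, 0) in mm.
    normalized:
        Whether :func:`window_normalize` has been applied.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.normalized:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"normalized volume has values outside [0, 1]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_mm(self, idx) -> np.ndarray:
        """Physical (z, y, x) position in mm of a voxel index (array-friendly)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, pos) -> np.ndarray:
        """Fractional voxel index of a physical position in mm."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


def load_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Returns an HU-valued :class:`CTVolume` with spacing taken from the file
    headers and the ``normalized`` flag unset.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        For a 2D image, or a DICOM series with inconsistent slice spacing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        return _load_dicom_series(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got {data.ndim}D: {path}")
    # nibabel stores (x, y, z); flip to the package's (z, y, x) order.
    data = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return CTVolume(data=data.astype(np.float64), spacing=spacing, origin=origin,
                    normalized=False, meta={"source": path})


def _load_dicom_series(directory: str) -> CTVolume:
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") or hasattr(ds, "SliceLocation"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM slices found in {directory}")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.SliceLocation)

    slices.sort(key=zpos)
    zs = np.array([zpos(s) for s in slices])
    if len(slices) < 2:
        raise FormatError("a DICOM series needs at least 2 slices")
    gaps = np.diff(zs)
    if np.any(gaps <= 0):
        raise FormatError("duplicate or unordered slice positions in series")
    if (gaps.max() - gaps.min()) > 0.01 * abs(gaps.mean()) + 1e-3:
        bad = [os.path.basename(slices[i + 1].filename)
               for i in np.nonzero(np.abs(gaps - gaps.mean()) > 0.01 * abs(gaps.mean()) + 1e-3)[0]]
        raise FormatError(f"inconsistent slice spacing in DICOM series near: {bad}")
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
    data = np.stack([s.pixel_array.astype(np.float64) * slope + intercept for s in slices])
    py, px = (float(v) for v in slices[0].PixelSpacing)
    spacing = (float(gaps.mean()), py, px)
    origin = (zs[0], float(slices[0].ImagePositionPatient[1]) if hasattr(slices[0], "ImagePositionPatient") else 0.0,
              float(slices[0].ImagePositionPatient[0]) if hasattr(slices[0], "ImagePositionPatient") else 0.0)
    return CTVolume(data=data, spacing=spacing, origin=origin, normalized=False,
                    meta={"source": directory, "n_slices": len(slices)})


def save_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume (or a mask cast to int16/uint8) as NIfTI."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    # back to nibabel's (x, y, z)
    arr = np.transpose(data, (2, 1, 0))
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    affine[:3, 3] = [vol.origin[2], vol.origin[1], vol.origin[0]]
    nib.save(nib.Nifti1Image(arr, affine), os.fspath(path))


def window_normalize(vol: CTVolume, width: float = 1600.0, level: float = -600.0) -> CTVolume:
    """Map HU values onto [0, 1] with a display window.

    The window spans ``[level - width/2, level + width/2]`` (the radiological
    convention); values are clipped at both ends.  With the default lung
    window, -1400 HU maps to 0, -600 HU to 0.5 and +200 HU to 1.
    """
    if vol.normalized:
        raise ValueError("volume is already normalized")
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    floor = level - width / 2.0
    out = np.clip((vol.data - floor) / width, 0.0, 1.0)
    return replace(vol, data=out, normalized=True)


def denormalize(vol: CTVolume, width: float = 1600.0, level: float = -600.0) -> CTVolume:
    """Inverse of :func:`window_normalize` (HU export for normalized volumes)."""
    if not vol.normalized:
        raise ValueError("volume is not normalized")
    floor = level - width / 2.0
    return replace(vol, data=vol.data * width + floor, normalized=False)


def resample_isotropic(vol: CTVolume, target: float = 1.0, *, is_mask: bool = False) -> CTVolume:
    """Resample to uniform *target* spacing (mm).

    Intensities are interpolated trilinearly; masks (``is_mask=True``)
    nearest-neighbour so that labels stay integral.  The physical extent of
    each axis is preserved to within one voxel.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    factors = tuple(s / target for s in vol.spacing)
    if np.allclose(factors, 1.0):
        return replace(vol, spacing=(target,) * 3)
    order = 0 if is_mask else 1
    out = ndimage.zoom(vol.data.astype(float) if not is_mask else vol.data,
                       factors, order=order, mode="nearest", grid_mode=True)
    if vol.normalized and not is_mask:
        out = np.clip(out, 0.0, 1.0)
    if is_mask and vol.data.dtype == bool:
        out = out.astype(bool)
    return replace(vol, data=out, spacing=(target,) * 3)
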