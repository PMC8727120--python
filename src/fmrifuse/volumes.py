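"""Volumetric containers and I/O for 4D BOLD series and 3D scalar maps.

Axis convention is (X, Y, Z, T) with 0-based voxel indices throughout.
NIfTI-1/-2 files are read and written with nibabel; the repetition time is
taken from the header (``pixdim[4]``) but can be overridden because scanner
headers are frequently wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume4D",
    "Volume3D",
    "BrainMask",
    "read_volume4d",
    "write_volume4d",
    "write_volume3d",
    "read_volume3d",
    "drop_initial_volumes",
    "auto_mask",
    "normalize_map_by_mask_mean",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Volume4D:
    """A single subject's BOLD series on an X*Y*Z voxel grid over T frames."""

    data: np.ndarray
    tr_seconds: float
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError(f"Volume4D needs 4 dimensions, got shape {data.shape}")
        if data.shape[3] < 2:
            raise ValueError(f"Volume4D needs T >= 2 frames, got T={data.shape[3]}")
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume4D data must be finite")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class Volume3D:
    """A scalar brain map (ALFF, mALFF, ReHo, mReHo or an intermediate)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"Volume3D needs 3 dimensions, got shape {data.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")


@dataclass(frozen=True)
class BrainMask:
    """Boolean voxel mask defining "whole brain" for normalization and maps."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"BrainMask needs 3 dimensions, got shape {data.shape}")
        if not data.any():
            raise ValueError("BrainMask must contain at least one true voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _spacing_from_header(img: nib.spatialimages.SpatialImage) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()
    sp = tuple(float(z) for z in zooms[:3])
    if any(s <= 0 for s in sp):
        sp = (1.0, 1.0, 1.0)
    return sp  # type: ignore[return-value]


def read_volume4d(path: str | Path, tr_seconds: float | None = None) -> Volume4D:
    """Read a 4D NIfTI file.

    Parameters
    ----------
    path
        NIfTI-1/-2 file (``.nii`` or ``.nii.gz``) with 4 dimensions.
    tr_seconds
        Override for the repetition time; when ``None`` it is taken from the
        header's ``pixdim[4]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D volume, got {data.ndim}D in {path}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_seconds <= 0:
        raise ValueError(
            f"non-positive TR ({tr_seconds}) in header of {path}; pass tr_seconds explicitly"
        )
    return Volume4D(data=np.asarray(data, dtype=np.float64), tr_seconds=tr_seconds,
                    spacing_mm=_spacing_from_header(img))


def write_volume4d(v: Volume4D, path: str | Path) -> None:
    affine = np.diag([*v.spacing_mm, 1.0])
    img = nib.Nifti1Image(v.data.astype(np.float64), affine)
    img.header.set_zooms((*v.spacing_mm, v.tr_seconds))
    nib.save(img, str(path))


def write_volume3d(m: Volume3D, path: str | Path) -> None:
    affine = np.diag([*m.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(m.data.astype(np.float64), affine), str(path))


def read_volume3d(path: str | Path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return Volume3D(data=np.asarray(data, dtype=np.float64),
                    spacing_mm=_spacing_from_header(img))


def drop_initial_volumes(v: Volume4D, n: int) -> Volume4D:
    """Discard the first ``n`` frames (the unstable initial signal)."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n >= v.n_frames:
        raise ValueError(f"cannot drop {n} of {v.n_frames} frames: nothing would remain")
    if n == 0:
        return v
    return Volume4D(data=v.data[..., n:], tr_seconds=v.tr_seconds, spacing_mm=v.spacing_mm)


def auto_mask(v: Volume4D, fraction: float = 0.1) -> BrainMask:
    """Heuristic brain mask: temporal mean above ``fraction`` of the robust max.

    The robust max is the 98th percentile of the temporal-mean image, which
    ignores isolated bright voxels.
    """
    mean_img = v.data.mean(axis=3)
    robust_max = np.percentile(mean_img, 98)
    mask = mean_img > fraction * robust_max
    if not mask.any():
        raise ValueError("auto_mask found no voxels above threshold")
    return BrainMask(data=mask)


def normalize_map_by_mask_mean(m: Volume3D, mask: BrainMask) -> Volume3D:
    """Divide a map by its in-mask mean so the whole-brain mean becomes 1."""
    if m.data.shape != mask.data.shape:
        raise ValueError(f"map shape {m.data.shape} != mask shape {mask.data.shape}")
    mean = float(m.data[mask.data].mean())
    scale = np.abs(m.data[mask.data]).max() if mask.n_voxels else 0.0
    if mean == 0.0 or (scale > 0 and abs(mean) < 1e-12 * scale):
        raise ValueError(f"in-mask mean is zero or near zero ({mean!r}); cannot divide by it")
    return Volume3D(data=m.data / mean, spacing_mm=m.spacing_mm)


def fwhm_to_sigma(fwhm_mm: float, spacing_mm: tuple[float, float, float]) -> tuple[float, ...]:
    """Per-axis Gaussian sigma in voxel units for an isotropic FWHM in mm."""
    return tuple(fwhm_mm / _FWHM_PER_SIGMA / s for s in spacing_mm)


def gaussian_smooth(m: Volume3D, fwhm_mm: float) -> Volume3D:
    """Gaussian-smooth a map with an isotropic kernel given as FWHM in mm.

    Reflect padding at the boundary; ``fwhm_mm == 0`` returns the input
    unchanged. The kernel is normalized, so constant maps are preserved.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return m
    sigma = fwhm_to_sigma(fwhm_mm, m.spacing_mm)
    smoothed = ndimage.gaussian_filter(m.data, sigma=sigma, mode="reflect")
    return Volume3D(data=smoothed, spacing_mm=m.spacing_mm)
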