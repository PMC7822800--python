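"""Voxel volume containers and lossless MHD/NIfTI round-trip I/O.

Conventions
-----------
Arrays are indexed ``[z, y, x]`` (axial slice first, matching how SimpleITK
exposes image buffers).  ``spacing`` and ``origin`` are given in world order
``(x, y, z)`` and millimetres.  ``origin`` is the *corner* of the volume:
the world position of the centre of voxel ``(i, j, k)`` is
``origin + (index + 0.5) * spacing``.  File formats that store a voxel-centre
origin (ITK convention) are converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["ScalarVolume", "LabelVolume", "read_volume", "write_volume"]


def _check_grid(values: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got ndim={values.ndim}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have three components (x, y, z)")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    if not all(np.isfinite(spacing)) or not all(np.isfinite(origin)):
        raise ValueError("spacing and origin must be finite")
    return spacing, origin


@dataclass
class ScalarVolume:
    """A 3-D grid of non-negative physical scalars (dose, fluence, density, ...).

    ``values`` has shape ``(nz, ny, nx)``; units depend on the role the volume
    plays (mGy for dose, g/cm^3 for density, cm^2/g for coefficient maps).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing, self.origin = _check_grid(self.values, self.spacing, self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("scalar volume contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_grid(self, other: "ScalarVolume | LabelVolume") -> bool:
        return (
            self.values.shape == other_shape(other)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(values, self.spacing, self.origin)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (x, y, z) of voxel centres, each shaped (nz, ny, nx)."""
        nz, ny, nx = self.values.shape
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        zs = oz + (np.arange(nz) + 0.5) * sz
        ys = oy + (np.arange(ny) + 0.5) * sy
        xs = ox + (np.arange(nx) + 0.5) * sx
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        return X, Y, Z


@dataclass
class LabelVolume:
    """A 3-D integer tissue-label grid on the same world-grid convention."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("label volume must hold integers")
            arr = arr.astype(np.int32)
        self.labels = arr
        self.spacing, self.origin = _check_grid(self.labels, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def with_labels(self, labels: np.ndarray) -> "LabelVolume":
        return LabelVolume(labels, self.spacing, self.origin)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (x, y, z) of voxel centres, each shaped (nz, ny, nx)."""
        nz, ny, nx = self.labels.shape
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        zs = oz + (np.arange(nz) + 0.5) * sz
        ys = oy + (np.arange(ny) + 0.5) * sy
        xs = ox + (np.arange(nx) + 0.5) * sx
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        return X, Y, Z

    def same_grid(self, other) -> bool:
        return (
            self.labels.shape == other_shape(other)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def other_shape(vol) -> tuple[int, int, int]:
    return vol.values.shape if hasattr(vol, "values") else vol.labels.shape


_SUPPORTED = (".mhd", ".nii", ".nii.gz")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise ValueError(
            f"unsupported volume format '{path.suffix}'; supported: {_SUPPORTED}"
        )


def write_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume to MHD/RAW or NIfTI; scalars as float32, labels as int16."""
    path = Path(path)
    _check_ext(path)
    if isinstance(vol, LabelVolume):
        arr = vol.labels.astype(np.int16)
    else:
        arr = vol.values.astype(np.float32)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(vol.spacing)
    # ITK stores the centre of voxel (0,0,0); our origin is the grid corner.
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing)))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> ScalarVolume | LabelVolume:
    """Read MHD/RAW or NIfTI; integer pixel types load as :class:`LabelVolume`."""
    path = Path(path)
    _check_ext(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    spacing = img.GetSpacing()
    origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    if np.issubdtype(arr.dtype, np.integer):
        return LabelVolume(arr.astype(np.int32), spacing, origin)
    return ScalarVolume(arr.astype(np.float64), spacing, origin)
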