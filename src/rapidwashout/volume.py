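"""In-memory volume containers and world-geometry helpers.

All volumes live in a single right-handed RAS world (mm units): +x right,
+y anterior, +z superior.  DICOM geometry (LPS) and NIfTI affines are
converted into this convention at the I/O boundary so that every downstream
module (registration, subtraction, volumetry) can do geometry math without
per-format sign juggling.

Voxel indexing is 0-based with axis order (i, j, k); the world position of a
voxel is ``origin + orientation @ (spacing * index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "RgbVolume", "GeometryError", "to_sitk", "from_sitk"]

#: RAS <-> LPS flip (negate x and y).
_RAS_LPS = np.diag([-1.0, -1.0, 1.0])

_ORTHO_TOL = 1e-6


class GeometryError(ValueError):
    """Raised when volume geometry is invalid or inconsistent."""


def _check_orientation(orientation: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (3, 3):
        raise GeometryError(f"orientation must be 3x3, got {orientation.shape}")
    if not np.allclose(orientation.T @ orientation, np.eye(3), atol=tol):
        raise GeometryError("orientation matrix is not orthonormal")
    return orientation


@dataclass
class Volume:
    """A 3-D scalar image with world geometry.

    Parameters
    ----------
    data
        Scalar grid indexed ``[i, j, k]``; arbitrary intensity units.
    spacing
        Voxel edge lengths in mm per axis, strictly positive.
    origin
        World (RAS, mm) position of voxel ``(0, 0, 0)``.
    orientation
        3x3 direction-cosine matrix; column ``a`` is the world direction of
        image axis ``a``.  Orthonormal within 1e-6.
    meta
        Optional acquisition metadata (series time, modality, patient ID...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise GeometryError("data must be a non-empty 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = _check_orientation(self.orientation)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> world (RAS mm) affine."""
        A = np.eye(4)
        A[:3, :3] = self.orientation @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.atleast_2d(np.asarray(index, dtype=float))
        return (self.affine[:3, :3] @ index.T).T + np.asarray(self.origin)

    def same_grid_as(self, other: "Volume", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.orientation, other.orientation, atol=tol)
        )

    def with_data(self, data: np.ndarray, **meta: Any) -> "Volume":
        """Copy of this volume's geometry carrying new voxel data."""
        return Volume(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            orientation=self.orientation.copy(),
            meta={**self.meta, **meta},
        )


@dataclass
class RgbVolume:
    """A 3-D RGB image: last axis holds (R, G, B) as uint8 in [0, 255]."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise GeometryError("RGB data must have shape (nx, ny, nz, 3)")
        if self.data.min() < 0 or self.data.max() > 255:
            raise GeometryError("RGB channel values must lie in [0, 255]")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = _check_orientation(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]


# -- SimpleITK interop -------------------------------------------------------


def to_sitk(vol: Volume, dtype=None) -> sitk.Image:
    """Convert a Volume (RAS world) into a SimpleITK image (LPS world)."""
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple((_RAS_LPS @ np.asarray(vol.origin)).tolist()))
    img.SetDirection(tuple((_RAS_LPS @ vol.orientation).flatten(order="C").tolist()))
    return img


def from_sitk(img: sitk.Image, meta: dict[str, Any] | None = None) -> Volume:
    """Convert a SimpleITK image (LPS world) into a Volume (RAS world)."""
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    return Volume(
        data=data,
        spacing=tuple(img.GetSpacing()),
        origin=tuple((_RAS_LPS @ np.asarray(img.GetOrigin())).tolist()),
        orientation=_RAS_LPS @ direction,
        meta=dict(meta or {}),
    )
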