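"""Core in-memory containers for the TSC pipeline.

All volumes live on regular 3-D grids in physical LPS space (left, posterior,
superior — the convention of DICOM and SimpleITK). A :class:`GridMeta` fixes
the mapping between 0-based voxel indices and physical millimetre
coordinates; voxel (0, 0, 0) is centred at ``origin`` and axis ``i`` advances
by ``spacing[i]`` along the ``i``-th column of ``direction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "GridMeta",
    "ScalarVolume",
    "LabelVolume",
    "to_sitk",
    "from_sitk",
]


@dataclass(frozen=True)
class GridMeta:
    """Geometry of a regular 3-D voxel grid in LPS physical space (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    space: str = "LPS"

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError(f"expected 3-D grid, got shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        d = self.direction_matrix
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index → LPS-mm affine (voxel centres)."""
        a = np.eye(4)
        a[:3, :3] = self.direction_matrix * np.asarray(self.spacing)
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to LPS mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        m = self.direction_matrix * np.asarray(self.spacing)
        return idx @ m.T + np.asarray(self.origin)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        m = np.linalg.inv(self.direction_matrix * np.asarray(self.spacing))
        return (pts - np.asarray(self.origin)) @ m.T

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of every voxel centre, one array per axis."""
        idx = np.indices(self.shape, dtype=float)
        pts = self.index_to_physical(np.moveaxis(idx, 0, -1))
        return pts[..., 0], pts[..., 1], pts[..., 2]

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def matches(self, other: "GridMeta", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


def _require_same_grid(a: "GridMeta", b: "GridMeta", what: str) -> None:
    if not a.matches(b):
        raise ValueError(
            f"{what}: grids differ "
            f"(shape {a.shape} vs {b.shape}, spacing {a.spacing} vs {b.spacing}, "
            f"origin {a.origin} vs {b.origin})"
        )


@dataclass
class ScalarVolume:
    """3-D scalar field (signal, dose in Gy, or concentration in mM)."""

    data: np.ndarray
    meta: GridMeta
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarVolume requires 3-D data, got {self.data.ndim}-D")
        if tuple(self.data.shape) != tuple(self.meta.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.meta.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.meta.spacing

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.meta, self.units)

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ScalarVolume":
        return ScalarVolume(data, self.meta, self.units if units is None else units)


@dataclass
class LabelVolume:
    """Integer compartment/ROI map on a :class:`GridMeta` grid."""

    data: np.ndarray
    meta: GridMeta
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"LabelVolume requires integer dtype, got {self.data.dtype}")
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume requires 3-D data, got {self.data.ndim}-D")
        if tuple(self.data.shape) != tuple(self.meta.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.meta.shape}"
            )

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.data == label)) * self.meta.voxel_volume_mm3

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.meta, dict(self.names))


def to_sitk(vol: ScalarVolume | LabelVolume) -> sitk.Image:
    """Convert to a SimpleITK image (LPS, axis order preserved).

    Our arrays are indexed ``[i, j, k]`` with axis 0 the first physical axis;
    SimpleITK's buffer is z-fastest, so the array is transposed on the way in.
    """
    arr = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.meta.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.meta.origin))
    img.SetDirection(tuple(float(d) for d in vol.meta.direction))
    return img


def from_sitk(img: sitk.Image, units: str = "", names: dict[int, str] | None = None):
    """Convert a SimpleITK image back to a Scalar/LabelVolume (by dtype)."""
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    meta = GridMeta(
        shape=tuple(int(n) for n in img.GetSize()),
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
        direction=tuple(float(d) for d in img.GetDirection()),
    )
    if np.issubdtype(arr.dtype, np.integer):
        return LabelVolume(arr, meta, names or {})
    return ScalarVolume(arr.astype(float), meta, units)


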