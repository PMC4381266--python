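"""Voxel rasters, structure masks, dose grids and CT-number conversion.

World coordinates are in centimetres throughout. A :class:`VoxelGrid` stores
one scalar per voxel, either Hounsfield units (``value_kind="HU"``) or
relative water-equivalent density (``value_kind="density"``, water = 1).
Voxel ``(i, j, k)`` (0-based) occupies the half-open box
``[origin + i*spacing, origin + (i+1)*spacing)`` along each axis; the array
axis order is ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HULookupTable",
    "default_hu_table",
    "hu_to_density",
    "VoxelGrid",
    "StructureMask",
    "DoseGrid",
]


@dataclass(frozen=True)
class HULookupTable:
    """Piecewise-linear CT-number to relative-density conversion curve.

    Breakpoints must be strictly increasing in HU, densities non-negative,
    and the curve must map 0 HU to density 1.0 (water by definition). The
    interpolation clamps outside the breakpoint range.
    """

    hu: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=np.float64)
        density = np.asarray(self.density, dtype=np.float64)
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "density", density)
        if hu.ndim != 1 or hu.shape != density.shape or hu.size < 2:
            raise ValueError("HU table needs matching 1-D breakpoint arrays (>= 2 points)")
        if not (np.all(np.isfinite(hu)) and np.all(np.isfinite(density))):
            raise ValueError("HU table breakpoints must be finite")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(density < 0):
            raise ValueError("densities must be non-negative")
        if abs(float(np.interp(0.0, hu, density)) - 1.0) > 1e-12:
            raise ValueError("HU table must map 0 HU to density 1.0 (water)")

    def __call__(self, hu):
        hu = np.asarray(hu, dtype=np.float64)
        if not np.all(np.isfinite(hu)):
            raise ValueError("non-finite HU value")
        return np.interp(hu, self.hu, self.density)


def default_hu_table() -> HULookupTable:
    """4-point stand-in for a clinic-calibrated HU-to-density curve."""
    return HULookupTable(
        hu=np.array([-1000.0, 0.0, 100.0, 1500.0]),
        density=np.array([0.001, 1.0, 1.05, 1.6]),
    )


def hu_to_density(hu, table: HULookupTable):
    """Convert HU to relative water-equivalent density (clamped interpolation)."""
    return table(hu)


@dataclass
class VoxelGrid:
    """Regular 3-D raster with world-coordinate geometry (cm)."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    value_kind: str = "density"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if self.value_kind not in ("HU", "density"):
            raise ValueError("value_kind must be 'HU' or 'density'")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def upper(self) -> np.ndarray:
        """World coordinates of the corner opposite ``origin``."""
        return self.origin + self.spacing * np.asarray(self.dims, dtype=np.float64)

    def densities(self, table: HULookupTable | None = None) -> np.ndarray:
        """Relative water-equivalent densities, converting from HU if needed."""
        if self.value_kind == "density":
            return self.values
        if table is None:
            table = default_hu_table()
        return table(self.values)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array, index order C-contiguous."""
        nx, ny, nz = self.dims
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing[0]
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing[1]
        cz = self.origin[2] + (np.arange(nz) + 0.5) * self.spacing[2]
        out = np.empty((nx, ny, nz, 3), dtype=np.float64)
        out[..., 0] = cx[:, None, None]
        out[..., 1] = cy[None, :, None]
        out[..., 2] = cz[None, None, :]
        return out.reshape(-1, 3)

    def index_to_world(self, i, j, k) -> np.ndarray:
        """World coordinates of voxel center (i, j, k)."""
        idx = np.asarray([i, j, k], dtype=np.float64)
        return self.origin + (idx + 0.5) * self.spacing

    def world_to_index(self, point) -> tuple[int, int, int]:
        """Voxel index containing a world point (no bounds check)."""
        p = np.asarray(point, dtype=np.float64)
        idx = np.floor((p - self.origin) / self.spacing).astype(int)
        return tuple(idx)

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=np.float64)
        return bool(np.all(p >= self.origin) and np.all(p < self.upper))

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
        )


@dataclass
class StructureMask:
    """Boolean per-voxel mask aligned to an anatomy grid."""

    name: str
    mask: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> np.ndarray:
        """World-coordinate centroid of the masked voxel centers."""
        if self.voxel_count == 0:
            raise ValueError(f"structure '{self.name}' is empty")
        idx = np.argwhere(self.mask).astype(np.float64)
        return self.grid.origin + (idx.mean(axis=0) + 0.5) * self.grid.spacing


@dataclass
class DoseGrid:
    """Per-voxel dose-like quantity aligned to an anatomy grid.

    ``units`` is one of ``"Gy"`` (proton absorbed dose), ``"Sv"`` (equivalent
    dose), ``"mSv/Gy"`` (neutron H/D) or ``"%"`` (percent of prescription).
    """

    grid: VoxelGrid
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError("dose values must match the anatomy grid dims")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.units not in ("Gy", "Sv", "mSv/Gy", "%"):
            raise ValueError(f"unknown dose units {self.units!r}")

    def same_geometry(self, other: "DoseGrid") -> bool:
        return self.grid.same_geometry(other.grid)
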