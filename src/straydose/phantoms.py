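"""Deterministic phantom factory.

Two study geometries are generated programmatically so the whole pipeline
is testable without any patient data:

* a box-shaped water phantom (30 x 15 x 15 cm^3) containing a spherical
  target 5 cm in diameter at a depth of 7.5 cm, beam along +z;
* a thorax-like heterogeneous phantom (elliptical soft-tissue body, two
  low-density lungs, a spine-like bone column, a mediastinal spherical
  target, a thyroid-like structure in the neck ~15 cm superior of the
  target, and an anterior breast-like bulge so surface obliquity is
  exercised), beam anterior-posterior along +y.

All generation is deterministic given the spec (and seed, when the optional
density noise is enabled; it is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import StructureMask, VoxelGrid
from .proton import BeamPlan

__all__ = [
    "PhantomSpec",
    "make_water_box",
    "make_thorax",
    "default_water_box_plan",
    "default_thorax_plan",
    "write_fixture",
]

LUNG_DENSITY = 0.26
BONE_DENSITY = 1.4
THYROID_DENSITY = 1.05
AIR = 0.001

#: Geometric distance (cm) from the virtual proton source to the isocenter.
SOURCE_AXIS_DISTANCE = 233.0
#: Collimator plane distance (cm) downstream of the proton source; this
#: leaves the plane of final collimation 33 cm upstream of the isocenter,
#: where the virtual neutron source sits.
COLLIMATOR_DISTANCE = 200.0


@dataclass
class PhantomSpec:
    """Declarative description of a generated phantom."""

    kind: str = "water_box_sphere"
    spacing: float = 0.25
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("water_box_sphere", "thorax"):
            raise ValueError("kind must be 'water_box_sphere' or 'thorax'")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _maybe_add_noise(values: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = np.clip(values + rng.normal(0.0, spec.noise_sd, values.shape), 0.0, None)
    return values


def make_water_box(
    spacing: float = 0.25, noise_sd: float = 0.0, seed: int = 0
) -> tuple[VoxelGrid, StructureMask]:
    """Water box 30x15x15 cm^3 with a 5-cm spherical target at 7.5 cm depth.

    The beam axis is +z; the isocenter (target center) is the world origin,
    so the entrance face sits at z = -7.5 cm.  The surrounding world is air
    (handled by the ray tracer's outside density).
    """
    spec = PhantomSpec(kind="water_box_sphere", spacing=spacing, noise_sd=noise_sd, seed=seed)
    if spacing > 2.5:
        raise ValueError("spacing larger than the target radius (2.5 cm)")
    nxy = int(round(15.0 / spacing))
    nz = int(round(30.0 / spacing))
    origin = np.array([-7.5, -7.5, -7.5])
    values = np.ones((nxy, nxy, nz), dtype=np.float64)
    values = _maybe_add_noise(values, spec)
    grid = VoxelGrid(origin=origin, spacing=[spacing] * 3, values=values, value_kind="density")

    cx = origin[0] + (np.arange(nxy) + 0.5) * spacing
    cz = origin[2] + (np.arange(nz) + 0.5) * spacing
    X = cx[:, None, None]
    Y = cx[None, :, None]
    Z = cz[None, None, :]
    target = X * X + Y * Y + Z * Z <= 2.5**2
    return grid, StructureMask(name="target", mask=target, grid=grid)


def default_water_box_plan(prescription: float = 36.0) -> BeamPlan:
    """Single-field geometry for the water-box phantom (beam along +z)."""
    return BeamPlan(
        source=[0.0, 0.0, -SOURCE_AXIS_DISTANCE],
        axis=[0.0, 0.0, 1.0],
        collimator_plane_z=COLLIMATOR_DISTANCE,
        isocenter=[0.0, 0.0, 0.0],
        prescription=prescription,
        energy=140.0,
    )


def make_thorax(
    spacing: float = 0.4, noise_sd: float = 0.0, seed: int = 0
) -> tuple[VoxelGrid, dict[str, StructureMask]]:
    """Thorax-like heterogeneous phantom; beam anterior-posterior along +y.

    Returns the density grid and the structure masks ``body``, ``lungs``,
    ``spine``, ``target`` and ``thyroid``.  The isocenter (target center) is
    the world origin; +z is superior, -y anterior.
    """
    spec = PhantomSpec(kind="thorax", spacing=spacing, noise_sd=noise_sd, seed=seed)
    sp = spacing
    nx = int(round(36.0 / sp))
    ny = int(round(28.0 / sp))
    nz = int(round(32.0 / sp))
    origin = np.array([-18.0, -15.2, -12.0])
    cx = origin[0] + (np.arange(nx) + 0.5) * sp
    cy = origin[1] + (np.arange(ny) + 0.5) * sp
    cz = origin[2] + (np.arange(nz) + 0.5) * sp
    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]

    torso = ((X / 16.0) ** 2 + ((Y + 0.5) / 10.5) ** 2 <= 1.0) & (Z <= 12.0)
    neck = (X**2 + (Y + 3.0) ** 2 <= 5.0**2) & (Z > 12.0) & (Z <= 18.0)
    bulge = np.zeros_like(torso)
    for sx in (-6.0, 6.0):
        bulge |= (X - sx) ** 2 + (Y + 10.5) ** 2 + (Z - 2.0) ** 2 <= 4.5**2
    bulge &= Z <= 12.0
    body = torso | neck | bulge

    lungs = np.zeros_like(body)
    for sx in (-8.5, 8.5):
        lungs |= ((X - sx) / 5.5) ** 2 + (Y / 7.0) ** 2 + ((Z - 1.0) / 8.5) ** 2 <= 1.0
    lungs &= body

    spine = (X**2 + (Y - 7.5) ** 2 <= 2.1**2) & (Z <= 12.0) & body
    target = X**2 + Y**2 + Z**2 <= 3.0**2
    thyroid = (
        (X / 2.2) ** 2 + ((Y + 4.0) / 1.3) ** 2 + ((Z - 15.0) / 1.4) ** 2 <= 1.0
    ) & body

    lungs &= ~(target | spine)
    spine &= ~target

    values = np.full((nx, ny, nz), AIR, dtype=np.float64)
    values[body] = 1.0
    values[lungs] = LUNG_DENSITY
    values[spine] = BONE_DENSITY
    values[thyroid] = THYROID_DENSITY
    values[target] = 1.0
    values = _maybe_add_noise(values, spec)
    grid = VoxelGrid(origin=origin, spacing=[sp] * 3, values=values, value_kind="density")

    masks = {
        "body": StructureMask("body", body, grid),
        "lungs": StructureMask("lungs", lungs, grid),
        "spine": StructureMask("spine", spine, grid),
        "target": StructureMask("target", target, grid),
        "thyroid": StructureMask("thyroid", thyroid, grid),
    }
    return grid, masks


def default_thorax_plan(prescription: float = 36.0) -> BeamPlan:
    """Single anterior-posterior field for the thorax phantom (beam along +y)."""
    return BeamPlan(
        source=[0.0, -SOURCE_AXIS_DISTANCE, 0.0],
        axis=[0.0, 1.0, 0.0],
        collimator_plane_z=COLLIMATOR_DISTANCE,
        isocenter=[0.0, 0.0, 0.0],
        prescription=prescription,
        energy=160.0,
        range_shifter=1.5,
    )


def write_fixture(grid: VoxelGrid, masks, outdir, fmt: str = "nii") -> dict:
    """Write a phantom (density raster + label volume + manifest) to disk."""
    from . import io as _io

    return _io.write_phantom(grid, masks, outdir, fmt=fmt)
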