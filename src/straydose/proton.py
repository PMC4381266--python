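"""Passive-scattering surrogate proton dose engine.

A scanned-beam optimizer is deliberately not modelled.  Instead the plan is
constructed the way a passive-scattering delivery conforms to a target:

* the aperture is the planning target volume (PTV) projected to beam's eye
  view (BEV) on the collimator plane, with divergence from the virtual
  proton source;
* the range-modulation width is the maximal difference between the
  radiological depths of the proximal and distal PTV edges;
* the artificial volume PTV_PS collects every voxel inside the aperture
  whose radiological depth lies within the modulation band ending at the
  distal PTV edge on its ray;
* absorbed dose is a closed-form spread-out-Bragg-peak (SOBP) depth profile
  per ray (flat across the modulation band, entrance plateau upstream,
  rapid distal falloff) times an error-function lateral penumbra anchored
  to the aperture edge, normalized to the prescription at the isocenter.

All shape parameters are exposed in :class:`SOBPParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erfc

from .grid import DoseGrid, StructureMask, VoxelGrid
from .raytrace import AIR_DENSITY, beam_basis, radiological_pathlengths

__all__ = [
    "ApertureMask",
    "BeamPlan",
    "SOBPParams",
    "project_aperture",
    "modulation_width",
    "build_ptv_ps",
    "proton_dose_grid",
]


@dataclass
class ApertureMask:
    """Boolean open/blocked raster on the collimator plane.

    ``origin`` is the (u, v) world coordinate (cm, in the beam's lateral
    basis) of the corner of pixel (0, 0); ``spacing`` is the pixel size.
    """

    open_region: np.ndarray
    spacing: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        self.open_region = np.asarray(self.open_region, dtype=bool)
        if self.open_region.ndim != 2:
            raise ValueError("aperture mask must be 2-D")
        if self.spacing <= 0:
            raise ValueError("aperture pixel spacing must be positive")

    @property
    def open_pixel_count(self) -> int:
        return int(self.open_region.sum())

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv = self.open_region.shape
        u = self.origin[0] + (np.arange(nu) + 0.5) * self.spacing
        v = self.origin[1] + (np.arange(nv) + 0.5) * self.spacing
        return u, v

    def max_open_radius(self) -> float:
        """Largest distance of an open pixel center from the beam axis."""
        if self.open_pixel_count == 0:
            raise ValueError("aperture has no open pixels")
        u, v = self.pixel_centers()
        iu, iv = np.nonzero(self.open_region)
        return float(np.sqrt(u[iu] ** 2 + v[iv] ** 2).max())

    def signed_distance(self) -> np.ndarray:
        """Signed distance (cm) to the aperture edge; negative inside."""
        open_ = self.open_region
        sampling = (self.spacing, self.spacing)
        d_out = ndimage.distance_transform_edt(~open_, sampling=sampling)
        d_in = ndimage.distance_transform_edt(open_, sampling=sampling)
        return np.where(open_, -d_in, d_out)


@dataclass
class BeamPlan:
    """Source/collimator geometry, aperture, energy/modulation and prescription."""

    source: np.ndarray
    axis: np.ndarray
    collimator_plane_z: float
    isocenter: np.ndarray
    prescription: float
    energy: float | None = None
    modulation_width: float | None = None
    range_shifter: float = 0.0
    aperture: ApertureMask | None = None

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=np.float64).reshape(3)
        self.isocenter = np.asarray(self.isocenter, dtype=np.float64).reshape(3)
        _, _, self.axis = beam_basis(self.axis)
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.collimator_plane_z <= 0:
            raise ValueError("collimator plane must be downstream of the source")
        if self.modulation_width is not None and self.modulation_width < 0:
            raise ValueError("modulation width must be non-negative")
        if self.range_shifter < 0:
            raise ValueError("range shifter thickness must be non-negative")

    @property
    def isocenter_z(self) -> float:
        """Axial distance from source to isocenter."""
        rel = self.isocenter - self.source
        return float(rel @ self.axis)


@dataclass
class SOBPParams:
    """Shape parameters of the surrogate SOBP dose model (all cm unless noted)."""

    entrance_plateau: float = 0.75  # fraction of plateau dose at zero depth
    distal_falloff: float = 0.6  # cos^2 falloff length beyond the distal edge
    sigma_penumbra: float = 0.4  # lateral penumbra sigma at the isocenter plane
    aperture_margin: float = 0.8  # 50%-isodose offset outside the aperture edge
    lateral_cutoff: float = 3.0  # dose forced to 0 beyond this aperture distance


def _beam_frame_arrays(plan: BeamPlan, grid: VoxelGrid):
    """Per-voxel beam-frame coordinates (x, y lateral; z axial) of voxel centers."""
    u, v, axis = beam_basis(plan.axis)
    rel = grid.voxel_centers() - plan.source
    x = rel @ u
    y = rel @ v
    z = rel @ axis
    return x, y, z, u, v, axis


def _collimator_coords(plan: BeamPlan, x, y, z):
    """Divergently project lateral voxel coordinates onto the collimator plane."""
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(z > 1e-9, plan.collimator_plane_z / np.maximum(z, 1e-9), np.nan)
    return x * scale, y * scale


def _half_chords(plan: BeamPlan, grid: VoxelGrid, table) -> np.ndarray:
    """Half water-equivalent thickness of each voxel along the beam axis."""
    geom = 0.5 * float(np.abs(plan.axis) @ grid.spacing)
    return geom * grid.densities(table).ravel()


def project_aperture(
    ptv: StructureMask,
    plan: BeamPlan,
    pixel: float = 0.1,
    pad: float = 6.0,
) -> ApertureMask:
    """Project the PTV boundary to BEV on the collimator plane (no margin).

    A collimator pixel is open iff its center lies inside the union of the
    divergently projected PTV voxel footprints (each voxel's eight corners
    projected, bounding box taken per voxel — exact for beams aligned with
    a grid axis).
    """
    if ptv.voxel_count == 0:
        raise ValueError("empty PTV")
    grid = ptv.grid
    u, v, axis = beam_basis(plan.axis)
    idx = np.argwhere(ptv.mask).astype(np.float64)

    corners = np.array(
        [[a, b, c] for a in (0.0, 1.0) for b in (0.0, 1.0) for c in (0.0, 1.0)]
    )
    umin = np.full(idx.shape[0], np.inf)
    umax = np.full(idx.shape[0], -np.inf)
    vmin = np.full(idx.shape[0], np.inf)
    vmax = np.full(idx.shape[0], -np.inf)
    for corner in corners:
        world = grid.origin + (idx + corner) * grid.spacing
        rel = world - plan.source
        zc = rel @ axis
        if np.any(zc <= 0):
            raise ValueError("PTV extends to or behind the proton source plane")
        scale = plan.collimator_plane_z / zc
        uc = (rel @ u) * scale
        vc = (rel @ v) * scale
        np.minimum(umin, uc, out=umin)
        np.maximum(umax, uc, out=umax)
        np.minimum(vmin, vc, out=vmin)
        np.maximum(vmax, vc, out=vmax)

    u0 = float(umin.min()) - pad
    v0 = float(vmin.min()) - pad
    nu = int(np.ceil((float(umax.max()) + pad - u0) / pixel))
    nv = int(np.ceil((float(vmax.max()) + pad - v0) / pixel))
    open_ = np.zeros((nu, nv), dtype=bool)
    # pixel center c_i = u0 + (i + 0.5) * pixel lies in [umin, umax]
    iu0 = np.ceil((umin - u0) / pixel - 0.5).astype(int).clip(0, nu - 1)
    iu1 = np.floor((umax - u0) / pixel - 0.5).astype(int).clip(-1, nu - 1)
    iv0 = np.ceil((vmin - v0) / pixel - 0.5).astype(int).clip(0, nv - 1)
    iv1 = np.floor((vmax - v0) / pixel - 0.5).astype(int).clip(-1, nv - 1)
    for a0, a1, b0, b1 in zip(iu0, iu1, iv0, iv1):
        if a1 >= a0 and b1 >= b0:
            open_[a0 : a1 + 1, b0 : b1 + 1] = True
    return ApertureMask(open_region=open_, spacing=pixel, origin=(u0, v0))


def _pixel_indices(aperture: ApertureMask, ucoll, vcoll):
    iu = np.floor((ucoll - aperture.origin[0]) / aperture.spacing).astype(int)
    iv = np.floor((vcoll - aperture.origin[1]) / aperture.spacing).astype(int)
    nu, nv = aperture.open_region.shape
    inside = (iu >= 0) & (iu < nu) & (iv >= 0) & (iv < nv)
    return iu, iv, inside


def _ptv_depth_maps(
    ptv: StructureMask, anatomy: VoxelGrid, table, plan: BeamPlan, outside_density
):
    """Per-aperture-pixel distal/proximal radiological PTV edge depths.

    Returns (distal_center, distal_edge, proximal_edge, defined) rasters on
    the aperture grid, nearest-neighbour filled where no PTV voxel projects.
    ``distal_center`` is the deepest PTV voxel-center depth on the ray;
    ``*_edge`` include the half water-equivalent voxel chord.
    """
    if plan.aperture is None:
        raise ValueError("plan.aperture must be set (see project_aperture)")
    flat = ptv.mask.ravel()
    if not flat.any():
        raise ValueError("empty PTV")
    x, y, z, *_ = _beam_frame_arrays(plan, anatomy)
    centers = anatomy.voxel_centers()[flat]
    depths = radiological_pathlengths(anatomy, table, plan.source, centers, outside_density)
    hc = _half_chords(plan, anatomy, table)[flat]
    ucoll, vcoll = _collimator_coords(plan, x[flat], y[flat], z[flat])
    iu, iv, inside = _pixel_indices(plan.aperture, ucoll, vcoll)
    if not inside.all():
        raise ValueError("PTV projects outside the aperture raster")

    shape = plan.aperture.open_region.shape
    lin = iu * shape[1] + iv
    distal_c = np.full(shape[0] * shape[1], -np.inf)
    distal_e = np.full(shape[0] * shape[1], -np.inf)
    proximal_e = np.full(shape[0] * shape[1], np.inf)
    np.maximum.at(distal_c, lin, depths)
    np.maximum.at(distal_e, lin, depths + hc)
    np.minimum.at(proximal_e, lin, depths - hc)
    distal_c = distal_c.reshape(shape)
    distal_e = distal_e.reshape(shape)
    proximal_e = proximal_e.reshape(shape)
    defined = np.isfinite(distal_c)

    # nearest-defined-pixel fill for rays that miss every PTV voxel center
    _, (fi, fj) = ndimage.distance_transform_edt(~defined, return_indices=True)
    return distal_c[fi, fj], distal_e[fi, fj], proximal_e[fi, fj], defined


def modulation_width(
    ptv: StructureMask,
    anatomy: VoxelGrid,
    table,
    plan: BeamPlan,
    per_ray: bool = False,
    outside_density: float = AIR_DENSITY,
) -> float:
    """Range-modulation width (cm water-equivalent) of the PTV.

    Default is the global envelope reading — deepest distal edge minus
    shallowest proximal edge over all BEV rays intersecting the PTV; with
    ``per_ray=True`` it is the maximum single-ray distal-minus-proximal
    difference instead.
    """
    distal_c, distal_e, proximal_e, defined = _ptv_depth_maps(
        ptv, anatomy, table, plan, outside_density
    )
    if not defined.any():
        raise ValueError("no BEV ray intersects the PTV")
    if per_ray:
        return float((distal_e[defined] - proximal_e[defined]).max())
    return float(distal_e[defined].max() - proximal_e[defined].min())


def build_ptv_ps(
    ptv: StructureMask,
    anatomy: VoxelGrid,
    table,
    plan: BeamPlan,
    outside_density: float = AIR_DENSITY,
) -> StructureMask:
    """The artificial passive-scattering target volume.

    A voxel belongs to PTV_PS iff its BEV ray falls in the open aperture and
    its distal water-equivalent edge (center depth + half chord) lies in the
    half-open band ``(distal_edge - M, distal_edge]`` on its ray, where
    ``distal_edge`` is the distal PTV edge depth and ``M`` the modulation
    width.  The degenerate ``M = 0`` band collapses to the distal-edge
    shell.  In homogeneous media PTV is a subset of PTV_PS.
    """
    if plan.aperture is None:
        raise ValueError("plan.aperture must be set (see project_aperture)")
    if not anatomy.same_geometry(ptv.grid):
        raise ValueError("PTV mask and anatomy grid geometries differ")
    M = plan.modulation_width
    if M is None:
        M = modulation_width(ptv, anatomy, table, plan, outside_density=outside_density)

    distal_c, distal_e, _, _ = _ptv_depth_maps(ptv, anatomy, table, plan, outside_density)

    x, y, z, *_ = _beam_frame_arrays(plan, anatomy)
    forward = z > 1e-6
    ucoll, vcoll = _collimator_coords(plan, x, y, z)
    iu, iv, inside = _pixel_indices(plan.aperture, ucoll, vcoll)
    candidate = forward & inside
    candidate[candidate] &= plan.aperture.open_region[
        iu[candidate], iv[candidate]
    ]

    member = np.zeros(z.shape[0], dtype=bool)
    if candidate.any():
        centers = ptv.grid.voxel_centers()[candidate]
        depths = radiological_pathlengths(
            anatomy, table, plan.source, centers, outside_density
        )
        hc = _half_chords(plan, anatomy, table)[candidate]
        edge = distal_e[iu[candidate], iv[candidate]]
        eps = 1e-9 * max(1.0, float(np.abs(edge).max()))
        dist_edge = depths + hc
        lower_strict = dist_edge > edge - M + eps
        upper = dist_edge <= edge + eps
        degenerate = M <= eps
        if degenerate:
            member[candidate] = (dist_edge >= edge - eps) & upper
        else:
            member[candidate] = lower_strict & upper
    out = member.reshape(ptv.grid.dims)
    return StructureMask(name="ptv_ps", mask=out, grid=ptv.grid)


def _sobp_depth_dose(depth, rng, mod, params: SOBPParams):
    """Closed-form SOBP depth profile: plateau ramp, flat top, cos^2 falloff."""
    depth = np.asarray(depth, dtype=np.float64)
    rng = np.asarray(rng, dtype=np.float64)
    prox = rng - mod
    s = np.ones_like(depth)
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp = params.entrance_plateau + (1.0 - params.entrance_plateau) * np.where(
            prox > 1e-9, depth / np.maximum(prox, 1e-9), 1.0
        )
    s = np.where(depth < prox, ramp, s)
    f = params.distal_falloff
    beyond = depth > rng
    if f > 0:
        frac = np.clip((depth - rng) / f, 0.0, 1.0)
        s = np.where(beyond, np.cos(0.5 * np.pi * frac) ** 2, s)
    s = np.where(depth >= rng + f, 0.0, s)
    return np.clip(s, 0.0, 1.0)


def proton_dose_grid(
    plan: BeamPlan,
    anatomy: VoxelGrid,
    table,
    ptv_ps: StructureMask,
    params: SOBPParams | None = None,
    outside_density: float = AIR_DENSITY,
    return_diagnostics: bool = False,
):
    """Deterministic surrogate proton absorbed-dose grid (Gy).

    Per voxel: ``prescription * SOBP(depth; ray range, modulation) *
    P(lateral)``, where the per-ray range is the distal PTV_PS radiological
    edge on the voxel's BEV ray (conformal distal coverage) and ``P`` is an
    error-function penumbra anchored ``aperture_margin`` outside the
    projected aperture edge, with sigma diverging linearly with axial
    distance.  Dose is forced to zero for rays beyond ``lateral_cutoff`` of
    the aperture edge at collimator scale.
    """
    if params is None:
        params = SOBPParams()
    if plan.aperture is None:
        raise ValueError("plan.aperture must be set")
    if ptv_ps.voxel_count == 0:
        raise ValueError("PTV_PS is empty")
    if not anatomy.contains(plan.isocenter):
        raise ValueError("isocenter lies outside the anatomy grid")
    M = plan.modulation_width
    if M is None:
        raise ValueError("plan.modulation_width must be set for dose calculation")

    distal_c, distal_e, _, _ = _ptv_depth_maps(
        ptv_ps, anatomy, table, plan, outside_density
    )

    x, y, z, *_ = _beam_frame_arrays(plan, anatomy)
    z_iso = plan.isocenter_z
    ucoll, vcoll = _collimator_coords(plan, x, y, z)

    # signed distance to aperture edge at collimator scale, bilinear sample
    sdist = plan.aperture.signed_distance()
    pu = (ucoll - plan.aperture.origin[0]) / plan.aperture.spacing - 0.5
    pv = (vcoll - plan.aperture.origin[1]) / plan.aperture.spacing - 0.5
    nu, nv = plan.aperture.open_region.shape
    forward = z > 1e-6
    pu_c = np.clip(np.where(forward, pu, 0.0), 0, nu - 1)
    pv_c = np.clip(np.where(forward, pv, 0.0), 0, nv - 1)
    s_coll = ndimage.map_coordinates(sdist, [pu_c, pv_c], order=1, mode="nearest")
    # beyond the raster: add the clipped Euclidean excess (still "far outside")
    du = np.where(forward, np.abs(pu - pu_c), 0.0) * plan.aperture.spacing
    dv = np.where(forward, np.abs(pv - pv_c), 0.0) * plan.aperture.spacing
    s_coll = s_coll + np.sqrt(du * du + dv * dv)

    active = forward & (s_coll < params.lateral_cutoff)
    values = np.zeros(z.shape[0], dtype=np.float64)
    rng_flat = np.zeros(z.shape[0], dtype=np.float64)
    if active.any():
        centers = anatomy.voxel_centers()[active]
        depth = radiological_pathlengths(
            anatomy, table, plan.source, centers, outside_density
        )
        iu, iv, inside = _pixel_indices(plan.aperture, ucoll[active], vcoll[active])
        iu = np.clip(iu, 0, nu - 1)
        iv = np.clip(iv, 0, nv - 1)
        rng = distal_e[iu, iv]
        sobp = _sobp_depth_dose(depth, rng, M, params)

        zeta = z[active] / z_iso  # divergence scale relative to the isocenter plane
        s_here = s_coll[active] * (z[active] / plan.collimator_plane_z)
        sigma = params.sigma_penumbra * zeta
        arg = (s_here - params.aperture_margin * zeta) / (sigma * np.sqrt(2.0))
        pen = 0.5 * erfc(arg)
        values[active] = plan.prescription * sobp * pen
        rng_flat[active] = rng

    dose = DoseGrid(
        grid=anatomy, values=values.reshape(anatomy.dims), units="Gy"
    )
    if return_diagnostics:
        diag = {
            "range_map": distal_e,
            "distal_center_map": distal_c,
            "signed_distance_coll": s_coll.reshape(anatomy.dims),
            "modulation_width": M,
        }
        return dose, diag
    return dose
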