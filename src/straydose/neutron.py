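"""Evaluation of the analytical neutron H/D model over points and grids.

The pointwise model for the neutron equivalent dose per prescribed proton
dose at a beam-frame point ``(x, y, z)`` with geometric source distance
``d`` and water-equivalent pathlength ``d'`` is::

    H/D = f * (H/D)_iso * (d / d_iso)^(-p)
          * sum_i C_i exp[-alpha_i (d' - d'_iso)]
                  exp[-(x^2 + y^2) d_iso^2 / (2 sigma_i^2 z^2)]

with ``f`` the field-size correction factor.  The lateral Gaussian uses the
axial distance ``z`` in its denominator, so each component's lateral width
grows linearly with distance from the virtual source plane.

Points at or behind the source plane (``z <= z_min``, default 1 mm) are
outside the model's forward half-space: the pointwise evaluator refuses
them, the grid evaluator assigns zero dose and logs how many voxels were
affected.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import least_squares

from .grid import DoseGrid
from .raytrace import AIR_DENSITY, BeamFramePoint, beam_basis, radiological_pathlengths
from .source_model import NeutronComponentParams, NeutronSourceModel

__all__ = [
    "DEFAULT_Z_MIN",
    "hd_at_point",
    "hd_grid",
    "neutron_equivalent_dose",
    "fit_hd_parameters",
]

logger = logging.getLogger(__name__)

DEFAULT_Z_MIN = 0.1  # cm beyond the virtual source plane

_EXP_CLIP = 700.0  # |exponent| bound; exp(-700) underflows to 0, exp(700) stays finite


def _require_dprime_iso(model: NeutronSourceModel) -> float:
    if model.dprime_iso is None:
        raise ValueError(
            "model.dprime_iso is unset; trace source->isocenter first "
            "(see NeutronSourceModel.with_dprime_iso)"
        )
    return model.dprime_iso


def _eval_hd(model: NeutronSourceModel, x, y, z, d, dprime):
    """Vectorized closed-form evaluation; callers guarantee z > 0 and d > 0."""
    dprime_iso = _require_dprime_iso(model)
    r2 = x * x + y * y
    base = model.field_size_factor * model.hd_iso * (d / model.d_iso) ** (-model.p)
    mix = 0.0
    for comp in model.components:
        expo = -comp.alpha * (dprime - dprime_iso) - r2 * (model.d_iso * model.d_iso) / (
            2.0 * comp.sigma * comp.sigma * z * z
        )
        term = np.exp(np.clip(expo, -_EXP_CLIP, _EXP_CLIP))
        mix = mix + comp.C * np.where(expo <= -_EXP_CLIP, 0.0, term)
    return base * mix


def hd_at_point(
    model: NeutronSourceModel, pt: BeamFramePoint, z_min: float = DEFAULT_Z_MIN
) -> float:
    """Neutron H/D (mSv/Gy) at a single beam-frame point."""
    if pt.z <= z_min:
        raise ValueError(f"point at z={pt.z:.4g} cm is at or behind the source plane")
    if pt.d == 0:
        raise ValueError("point coincides with the virtual source (d = 0)")
    return float(
        _eval_hd(
            model,
            np.float64(pt.x),
            np.float64(pt.y),
            np.float64(pt.z),
            np.float64(pt.d),
            np.float64(pt.dprime),
        )
    )


def hd_grid(
    model: NeutronSourceModel,
    anatomy,
    table=None,
    source=None,
    axis=None,
    *,
    z_min: float = DEFAULT_Z_MIN,
    outside_density: float = AIR_DENSITY,
) -> DoseGrid:
    """Neutron H/D map (mSv/Gy) over every voxel center of ``anatomy``.

    ``d'`` is ray traced from the virtual ``source`` to each voxel center
    through the anatomy.  If the model's ``dprime_iso`` is unset it is
    computed here by tracing from the source to the point on the beam axis
    at distance ``d_iso`` (the isocenter), using the same anatomy.
    """
    if source is None or axis is None:
        raise ValueError("hd_grid requires the virtual source position and beam axis")
    source = np.asarray(source, dtype=np.float64).reshape(3)
    u, v, axis = beam_basis(axis)

    if model.dprime_iso is None:
        iso_world = source + model.d_iso * axis
        dp_iso = radiological_pathlengths(
            anatomy, table, source, iso_world[None, :], outside_density
        )[0]
        model = model.with_dprime_iso(float(dp_iso))

    centers = anatomy.voxel_centers()
    rel = centers - source
    x = rel[:, 0] * u[0] + rel[:, 1] * u[1] + rel[:, 2] * u[2]
    y = rel[:, 0] * v[0] + rel[:, 1] * v[1] + rel[:, 2] * v[2]
    z = rel[:, 0] * axis[0] + rel[:, 1] * axis[1] + rel[:, 2] * axis[2]
    d = np.sqrt(x * x + y * y + z * z)

    valid = (z > z_min) & (d > 0)
    n_skipped = int(valid.size - valid.sum())
    if n_skipped:
        logger.warning(
            "%d voxels at or behind the virtual source plane (z <= %.3g cm) set to zero",
            n_skipped,
            z_min,
        )

    values = np.zeros(centers.shape[0], dtype=np.float64)
    if valid.any():
        dprime = radiological_pathlengths(
            anatomy, table, source, centers[valid], outside_density
        )
        values[valid] = _eval_hd(model, x[valid], y[valid], z[valid], d[valid], dprime)
    return DoseGrid(grid=anatomy, values=values.reshape(anatomy.dims), units="mSv/Gy")


def neutron_equivalent_dose(hdgrid: DoseGrid, prescription: float) -> DoseGrid:
    """Convert an H/D map (mSv/Gy) to neutron equivalent dose (Sv)."""
    if hdgrid.units != "mSv/Gy":
        raise ValueError("expected an H/D grid in mSv/Gy")
    if prescription < 0:
        raise ValueError("prescription must be non-negative")
    return DoseGrid(
        grid=hdgrid.grid, values=hdgrid.values * (prescription / 1000.0), units="Sv"
    )


def fit_hd_parameters(
    x,
    y,
    z,
    dprime,
    hd,
    init: NeutronSourceModel,
    *,
    fit_p: bool = True,
    xtol: float = 1e-14,
    ftol: float = 1e-14,
) -> NeutronSourceModel:
    """Least-squares refit of ``(p, C_i, alpha_i, sigma_i)`` from sampled H/D.

    ``hd_iso``, ``d_iso``, ``dprime_iso`` and the field-size factor are held
    fixed at the values of ``init``, which also provides the starting point.
    Residuals are relative (``model/data - 1``), so samples spanning orders
    of magnitude contribute evenly.  Recovery to high accuracy requires an
    identifiable sampling design: well-separated attenuation coefficients
    and lateral widths, and pathlengths that vary independently of the
    geometric distance (a heterogeneous medium).
    """
    x, y, z = (np.asarray(a, dtype=np.float64).ravel() for a in (x, y, z))
    dprime = np.asarray(dprime, dtype=np.float64).ravel()
    hd = np.asarray(hd, dtype=np.float64).ravel()
    if np.any(hd <= 0):
        raise ValueError("H/D samples must be positive for a relative-residual fit")
    d = np.sqrt(x * x + y * y + z * z)
    dprime_iso = _require_dprime_iso(init)

    def unpack(theta):
        p = theta[0] if fit_p else init.p
        comps = tuple(
            NeutronComponentParams(
                label=c.label,
                C=float(theta[1 + i]),
                alpha=float(theta[5 + i]),
                sigma=float(theta[9 + i]),
            )
            for i, c in enumerate(init.components)
        )
        return NeutronSourceModel(
            hd_iso=init.hd_iso,
            p=float(p),
            d_iso=init.d_iso,
            dprime_iso=dprime_iso,
            field_size_factor=init.field_size_factor,
            components=comps,
        )

    def residuals(theta):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # the optimizer may explore C sums far from 1
            model = unpack(theta)
        return _eval_hd(model, x, y, z, d, dprime) / hd - 1.0

    theta0 = np.concatenate(
        (
            [init.p],
            [c.C for c in init.components],
            [c.alpha for c in init.components],
            [c.sigma for c in init.components],
        )
    )
    lower = np.concatenate(([0.0], np.zeros(4), np.zeros(4), np.full(4, 1e-3)))
    upper = np.concatenate(([10.0], np.full(4, 10.0), np.full(4, 10.0), np.full(4, 1e4)))
    result = least_squares(
        residuals, theta0, bounds=(lower, upper), x_scale="jac", xtol=xtol, ftol=ftol
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        fitted = unpack(result.x)
    return fitted
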