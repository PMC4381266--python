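"""Combined equivalent dose, organ statistics, DVHs, isodose extraction and
the end-to-end pipeline.

Proton absorbed dose is converted to equivalent dose with a mean radiation
weighting factor of 1 (Gy -> Sv one-to-one) and summed voxelwise with the
neutron equivalent dose.  All percentage outputs are relative to the
prescription at the isocenter, not the maximum dose.  The structure-dose
"+-" convention is the population standard deviation over structure voxels
(configurable to the sample SD).
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from . import io as _io
from .grid import DoseGrid, StructureMask, default_hu_table
from .neutron import hd_grid, neutron_equivalent_dose
from .phantoms import (
    default_thorax_plan,
    default_water_box_plan,
    make_thorax,
    make_water_box,
)
from .proton import build_ptv_ps, modulation_width, project_aperture, proton_dose_grid
from .source_model import default_model, field_size_correction, load_model

__all__ = [
    "StructureDoseReport",
    "combine_equivalent_dose",
    "structure_stats",
    "percent_of_prescription",
    "cumulative_dvh",
    "isodose_bands",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class StructureDoseReport:
    """Equivalent-dose volume statistics for one structure."""

    name: str
    mean_sv: float
    sd_sv: float
    min_sv: float
    max_sv: float
    mean_percent: float
    voxel_count: int
    dvh_dose_percent: np.ndarray
    dvh_volume_percent: np.ndarray


def combine_equivalent_dose(proton: DoseGrid, neutron: DoseGrid) -> DoseGrid:
    """Voxelwise total equivalent dose: proton Gy x (w_R = 1 Sv/Gy) + neutron Sv."""
    if not proton.same_geometry(neutron):
        raise ValueError("proton and neutron grids have different geometries")
    if proton.units not in ("Gy", "Sv") or neutron.units not in ("Gy", "Sv"):
        raise ValueError("combine expects absorbed/equivalent dose grids (Gy or Sv)")
    return DoseGrid(grid=proton.grid, values=proton.values + neutron.values, units="Sv")


def cumulative_dvh(
    dose_percent: np.ndarray, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: fraction of voxels (%) receiving at least each dose level."""
    dose_percent = np.asarray(dose_percent, dtype=np.float64).ravel()
    top = max(float(dose_percent.max()), bin_width)
    levels = np.arange(0.0, top + bin_width, bin_width)
    volume = np.array(
        [100.0 * np.mean(dose_percent >= level) for level in levels]
    )
    volume[0] = 100.0
    return levels, volume


def structure_stats(
    dose: DoseGrid,
    mask: StructureMask,
    prescription: float,
    sd_convention: str = "population",
    dvh_bin: float = 1.0,
) -> StructureDoseReport:
    """Mean/SD/min/max equivalent dose over a structure plus its DVH.

    ``prescription`` is in Gy; with a proton weighting factor of 1 the
    prescribed target equivalent dose is numerically equal in Sv, and the
    percent column is 100 * mean / prescription.
    """
    if dose.units not in ("Gy", "Sv"):
        raise ValueError("structure statistics expect a Gy or Sv dose grid")
    if not dose.grid.same_geometry(mask.grid):
        raise ValueError("dose and mask geometries differ")
    if mask.voxel_count == 0:
        raise ValueError(f"structure '{mask.name}' has no voxels")
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    vals = dose.values[mask.mask]
    ddof = 0 if sd_convention == "population" else 1
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    pct = 100.0 * vals / prescription
    levels, volume = cumulative_dvh(pct, dvh_bin)
    return StructureDoseReport(
        name=mask.name,
        mean_sv=float(vals.mean()),
        sd_sv=sd,
        min_sv=float(vals.min()),
        max_sv=float(vals.max()),
        mean_percent=float(pct.mean()),
        voxel_count=int(vals.size),
        dvh_dose_percent=levels,
        dvh_volume_percent=volume,
    )


def percent_of_prescription(dose: DoseGrid, prescription: float) -> DoseGrid:
    """Rescale a dose grid to percent of the prescribed target equivalent dose."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    return DoseGrid(
        grid=dose.grid, values=100.0 * dose.values / prescription, units="%"
    )


def isodose_bands(
    dose_pct: DoseGrid, levels, slice_axis: int = 2
) -> dict[float, list[tuple[int, np.ndarray]]]:
    """Marching-squares isodose contours per slice.

    Returns, per requested level (% of prescription), a list of
    ``(slice_index, polyline)`` pairs where each polyline is an (N, 2) array
    of world coordinates (cm) in the two in-plane axes.  Levels outside the
    data range simply yield no contours.
    """
    levels = sorted(float(lv) for lv in levels)
    axes = [a for a in range(3) if a != slice_axis]
    origin = dose_pct.grid.origin
    spacing = dose_pct.grid.spacing
    out: dict[float, list[tuple[int, np.ndarray]]] = {lv: [] for lv in levels}
    n_slices = dose_pct.grid.dims[slice_axis]
    for k in range(n_slices):
        plane = np.take(dose_pct.values, k, axis=slice_axis)
        for lv in levels:
            if not (plane.min() < lv < plane.max()):
                continue
            for contour in measure.find_contours(plane, lv):
                world = np.empty_like(contour)
                world[:, 0] = origin[axes[0]] + (contour[:, 0] + 0.5) * spacing[axes[0]]
                world[:, 1] = origin[axes[1]] + (contour[:, 1] + 0.5) * spacing[axes[1]]
                out[lv].append((k, world))
    return out


def _load_pipeline_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(Path(config), "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(config, output_dir, seed: int = 0, log_level: str = "INFO") -> dict:
    """Phantom -> PTV_PS -> proton dose -> neutron dose -> combine -> reports.

    ``config`` is a dict or TOML path with optional sections ``[phantom]``
    (kind, spacing, noise_sd), ``[plan]`` (prescription, aperture_pixel,
    modulation: "auto" | cm), ``[neutron]`` (model: "default" | path,
    total_field_radius) and ``[output]`` (isodose_levels, format).  Writes
    dose rasters, per-structure statistics (CSV + JSON), DVHs, and a JSON
    run manifest with parameters and per-stage wall times.
    """
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))
    cfg = _load_pipeline_config(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    table = default_hu_table()
    fmt = cfg.get("output", {}).get("format", "nii")

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    try:
        t = stage("phantom")
        ph = cfg.get("phantom", {})
        kind = ph.get("kind", "water_box")
        noise_sd = float(ph.get("noise_sd", 0.0))
        if kind in ("water_box", "water_box_sphere"):
            spacing = float(ph.get("spacing", 0.25))
            anatomy, target = make_water_box(spacing, noise_sd=noise_sd, seed=seed)
            masks = {"target": target}
            plan_factory = default_water_box_plan
        elif kind == "thorax":
            spacing = float(ph.get("spacing", 0.4))
            anatomy, masks = make_thorax(spacing, noise_sd=noise_sd, seed=seed)
            target = masks["target"]
            plan_factory = default_thorax_plan
        else:
            raise ValueError(f"unknown phantom kind {kind!r}")
        timings["phantom"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'phantom' failed: {exc}") from exc

    try:
        t = stage("plan")
        plan_cfg = cfg.get("plan", {})
        prescription = float(plan_cfg.get("prescription", 36.0))
        plan = plan_factory(prescription)
        plan.aperture = project_aperture(
            target, plan, pixel=float(plan_cfg.get("aperture_pixel", 0.1))
        )
        modulation = plan_cfg.get("modulation", "auto")
        if modulation == "auto":
            plan.modulation_width = modulation_width(target, anatomy, table, plan)
        else:
            plan.modulation_width = float(modulation)
        ptv_ps = build_ptv_ps(target, anatomy, table, plan)
        timings["plan"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'plan' failed: {exc}") from exc

    try:
        t = stage("proton_dose")
        proton = proton_dose_grid(plan, anatomy, table, ptv_ps)
        timings["proton_dose"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'proton_dose' failed: {exc}") from exc

    try:
        t = stage("neutron_dose")
        neutron_cfg = cfg.get("neutron", {})
        model_src = neutron_cfg.get("model", "default")
        model = default_model() if model_src == "default" else load_model(model_src)
        if "hd_iso" in neutron_cfg:
            from dataclasses import replace

            model = replace(model, hd_iso=float(neutron_cfg["hd_iso"]))
        total_radius = float(neutron_cfg.get("total_field_radius", 0.0))
        if total_radius > 0:
            factor = _field_factor_from_aperture(plan.aperture, total_radius)
            model = model.with_field_size_factor(factor)
        neutron_source = plan.source + plan.collimator_plane_z * plan.axis
        hd = hd_grid(model, anatomy, table, source=neutron_source, axis=plan.axis)
        neutron_sv = neutron_equivalent_dose(hd, prescription)
        timings["neutron_dose"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'neutron_dose' failed: {exc}") from exc

    try:
        t = stage("combine_report")
        combined = combine_equivalent_dose(proton, neutron_sv)
        combined_pct = percent_of_prescription(combined, prescription)
        neutron_pct = percent_of_prescription(neutron_sv, prescription)

        reports = {}
        rows = []
        for name, mask in masks.items():
            rep_total = structure_stats(combined, mask, prescription)
            rep_neutron = structure_stats(neutron_sv, mask, prescription)
            reports[name] = {"total": rep_total, "neutron": rep_neutron}
            rows.append(
                {
                    "structure": name,
                    "voxels": rep_total.voxel_count,
                    "total_mean_sv": rep_total.mean_sv,
                    "total_sd_sv": rep_total.sd_sv,
                    "total_mean_pct": rep_total.mean_percent,
                    "neutron_mean_sv": rep_neutron.mean_sv,
                    "neutron_sd_sv": rep_neutron.sd_sv,
                    "neutron_mean_pct": rep_neutron.mean_percent,
                    "min_sv": rep_total.min_sv,
                    "max_sv": rep_total.max_sv,
                }
            )
        stats_df = pd.DataFrame(rows)

        levels = cfg.get("output", {}).get("isodose_levels", [0.3, 0.5, 1.0, 50.0, 95.0])
        bands = isodose_bands(combined_pct, levels)
        timings["combine_report"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'combine_report' failed: {exc}") from exc

    try:
        t = stage("write_outputs")
        _io.write_volume(anatomy, outdir / f"anatomy.{fmt}")
        _io.write_dose(proton, outdir / f"proton_dose_gy.{fmt}")
        _io.write_dose(hd, outdir / f"neutron_hd_msv_per_gy.{fmt}")
        _io.write_dose(neutron_sv, outdir / f"neutron_equivalent_sv.{fmt}")
        _io.write_dose(
            combined,
            outdir / f"combined_equivalent_sv.{fmt}",
            sidecar={
                "prescription_gy": prescription,
                "model": {
                    "hd_iso": model.hd_iso,
                    "p": model.p,
                    "d_iso": model.d_iso,
                    "dprime_iso": model.dprime_iso,
                    "field_size_factor": model.field_size_factor,
                    "components": [asdict(c) for c in model.components],
                },
                "source": list(plan.source),
                "axis": list(plan.axis),
            },
        )
        stats_df.to_csv(outdir / "structure_stats.csv", index=False)
        dvh_frames = []
        for name, pair in reports.items():
            rep = pair["total"]
            dvh_frames.append(
                pd.DataFrame(
                    {
                        "structure": name,
                        "dose_pct": rep.dvh_dose_percent,
                        "volume_pct": rep.dvh_volume_percent,
                    }
                )
            )
        pd.concat(dvh_frames).to_csv(outdir / "dvh.csv", index=False)
        band_rows = []
        for lv, contours in bands.items():
            for k, poly in contours:
                for a, b in poly:
                    band_rows.append({"level_pct": lv, "slice": k, "u_cm": a, "v_cm": b})
        pd.DataFrame(band_rows).to_csv(outdir / "isodose_contours.csv", index=False)
        timings["write_outputs"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'write_outputs' failed: {exc}") from exc

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "prescription_gy": prescription,
        "modulation_width_cm": plan.modulation_width,
        "field_size_factor": model.field_size_factor,
        "dprime_iso_cm": model.dprime_iso,
        "stage_wall_time_s": timings,
        "structures": {
            name: {
                "total_mean_sv": pair["total"].mean_sv,
                "total_sd_sv": pair["total"].sd_sv,
                "total_mean_pct": pair["total"].mean_percent,
                "neutron_mean_sv": pair["neutron"].mean_sv,
                "neutron_sd_sv": pair["neutron"].sd_sv,
                "neutron_mean_pct": pair["neutron"].mean_percent,
                "voxels": pair["total"].voxel_count,
            }
            for name, pair in reports.items()
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _field_factor_from_aperture(aperture, total_radius: float) -> float:
    """Blocked-to-total ratio with a circular total-field footprint."""
    u, v = aperture.pixel_centers()
    U, V = np.meshgrid(u, v, indexing="ij")
    radius = max(total_radius, aperture.max_open_radius())
    total = U * U + V * V <= radius * radius
    # the disc must be fully contained in the raster for correct pixel counting
    half_u = (u[-1] - u[0]) / 2 + (u[1] - u[0])
    if radius > min(abs(u[0]), abs(u[-1]), abs(v[0]), abs(v[-1])) + half_u:
        # extend virtually: count missing disc area as blocked pixels
        pix_area = aperture.spacing**2
        disc_area = np.pi * radius**2
        open_area = aperture.open_pixel_count * pix_area
        return float(max(0.0, min(1.0, (disc_area - open_area) / disc_area)))
    return field_size_correction(aperture.open_region & total, total)
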