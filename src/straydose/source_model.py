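"""The analytical four-component neutron source model and its scalar inputs.

Out-of-field neutron equivalent dose per prescribed proton dose (H/D) is
parameterized by a plan-level isocenter value ``hd_iso`` (mSv/Gy), a
power-law divergence exponent ``p``, the geometric and water-equivalent
source-to-isocenter distances, and four neutron components
(intranuclear-cascade, evaporation, epithermal, thermal), each with a
relative weight ``C``, a water attenuation coefficient ``alpha`` (1/cm) and
a lateral Gaussian width ``sigma`` (cm at the isocenter plane).

``hd_iso`` can be supplied directly or computed from a proton energy-bin
spectrum: the spectrum-weighted value is ``(1/n_max) * sum_j hd_iso_j n_j``
with ``n_max`` the proton count of the maximum-energy bin.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "COMPONENT_LABELS",
    "ModelConsistencyWarning",
    "NeutronComponentParams",
    "NeutronSourceModel",
    "EnergyBinSpectrum",
    "weighted_hd_iso",
    "field_size_correction",
    "load_model",
    "default_model",
]

COMPONENT_LABELS = ("intranuclear-cascade", "evaporation", "epithermal", "thermal")


class ModelConsistencyWarning(UserWarning):
    """The model parameters are valid but internally inconsistent."""


@dataclass(frozen=True)
class NeutronComponentParams:
    """One neutron component of the source model."""

    label: str
    C: float
    alpha: float
    sigma: float

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise ValueError(
                f"unknown component label {self.label!r}; expected one of {COMPONENT_LABELS}"
            )
        for name in ("C", "alpha", "sigma"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"component {self.label}: {name} must be finite")
        if self.C < 0:
            raise ValueError(f"component {self.label}: C must be >= 0")
        if self.alpha < 0:
            raise ValueError(f"component {self.label}: alpha must be >= 0")
        if self.sigma <= 0:
            raise ValueError(f"component {self.label}: sigma must be > 0")


@dataclass(frozen=True)
class NeutronSourceModel:
    """Validated parameter set of the analytical H/D model.

    ``dprime_iso`` may be ``None``, meaning "compute per plan by ray tracing
    from the virtual source to the isocenter through the anatomy"; it must
    be resolved before pointwise evaluation.
    """

    hd_iso: float
    p: float
    d_iso: float
    components: tuple[NeutronComponentParams, ...]
    dprime_iso: float | None = None
    field_size_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.hd_iso) and self.hd_iso > 0):
            raise ValueError("hd_iso must be positive and finite")
        if not (np.isfinite(self.d_iso) and self.d_iso > 0):
            raise ValueError("d_iso must be positive and finite")
        if not (np.isfinite(self.p) and self.p >= 0):
            raise ValueError("p must be non-negative and finite")
        if self.dprime_iso is not None and not (
            np.isfinite(self.dprime_iso) and self.dprime_iso >= 0
        ):
            raise ValueError("dprime_iso must be non-negative and finite (or None)")
        if not (0.0 <= self.field_size_factor <= 1.0):
            raise ValueError("field_size_factor must lie in [0, 1]")
        labels = [c.label for c in self.components]
        for label in COMPONENT_LABELS:
            if labels.count(label) > 1:
                raise ValueError(f"duplicate component {label!r}")
            if label not in labels:
                raise ValueError(f"missing component {label!r}")
        if len(self.components) != 4:
            raise ValueError("exactly four components required")
        ordered = tuple(sorted(self.components, key=lambda c: COMPONENT_LABELS.index(c.label)))
        object.__setattr__(self, "components", ordered)
        csum = self.component_sum
        if abs(csum - 1.0) > 1e-3:
            warnings.warn(
                f"component weights sum to {csum:.6g}, not 1: at the isocenter the model "
                "evaluates to hd_iso * sum(C_i), making hd_iso inconsistent with its own "
                "value there",
                ModelConsistencyWarning,
                stacklevel=2,
            )

    @property
    def component_sum(self) -> float:
        return float(sum(c.C for c in self.components))

    def with_dprime_iso(self, dprime_iso: float) -> "NeutronSourceModel":
        return replace(self, dprime_iso=float(dprime_iso))

    def with_field_size_factor(self, factor: float) -> "NeutronSourceModel":
        return replace(self, field_size_factor=float(factor))


@dataclass(frozen=True)
class EnergyBinSpectrum:
    """Proton energy-bin spectrum with per-bin isocenter H/D values.

    ``energy`` (MeV) strictly increasing, ``n`` proton counts (>= 0, arbitrary
    common scale), ``hd_iso_j`` (mSv/Gy) per bin.
    """

    energy: np.ndarray
    n: np.ndarray
    hd_iso_j: np.ndarray

    def __post_init__(self) -> None:
        for name in ("energy", "n", "hd_iso_j"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.energy.ndim != 1 or self.energy.size < 1:
            raise ValueError("spectrum needs at least one energy bin")
        if self.n.shape != self.energy.shape or self.hd_iso_j.shape != self.energy.shape:
            raise ValueError("spectrum arrays must have matching shapes")
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("bin energies must be strictly increasing")
        if np.any(self.n < 0):
            raise ValueError("proton counts must be non-negative")
        if not (
            np.all(np.isfinite(self.energy))
            and np.all(np.isfinite(self.n))
            and np.all(np.isfinite(self.hd_iso_j))
        ):
            raise ValueError("spectrum values must be finite")


def weighted_hd_iso(spectrum: EnergyBinSpectrum, convention: str = "max_energy") -> float:
    """Spectrum-weighted isocenter H/D in mSv/Gy.

    ``(1/n_max) * sum_j hd_iso_j * n_j`` where ``n_max`` is the proton count
    of the maximum-energy bin (``convention="max_energy"``, the default) or
    the largest bin count (``convention="max_count"``).
    """
    if convention == "max_energy":
        n_max = float(spectrum.n[-1])
    elif convention == "max_count":
        n_max = float(spectrum.n.max())
    else:
        raise ValueError("convention must be 'max_energy' or 'max_count'")
    if n_max <= 0:
        raise ValueError("normalizing bin has zero proton count")
    return float(np.sum(spectrum.hd_iso_j * spectrum.n) / n_max)


def field_size_correction(aperture_open, total_field_region) -> float:
    """Blocked-to-total area ratio of the proton field on the collimator.

    Both arguments are boolean masks on the same collimator-plane raster.
    Returns 1 for a fully blocked aperture (the closed-collimator calibration
    condition) and 0 for a fully open one; applied multiplicatively to
    ``hd_iso``.
    """
    aperture_open = np.asarray(aperture_open, dtype=bool)
    total = np.asarray(total_field_region, dtype=bool)
    if aperture_open.shape != total.shape:
        raise ValueError("aperture and total-field masks must share a raster")
    total_area = int(total.sum())
    if total_area == 0:
        raise ValueError("total field region is empty")
    if np.any(aperture_open & ~total):
        raise ValueError("aperture open region must lie within the total field")
    blocked = int((total & ~aperture_open).sum())
    return blocked / total_area


def _model_from_dict(cfg: dict, nmax_convention: str = "max_energy") -> NeutronSourceModel:
    model_cfg = dict(cfg.get("model", {}))
    comp_cfg = cfg.get("components", {})
    components = []
    for label in COMPONENT_LABELS:
        if label not in comp_cfg:
            raise ValueError(f"config missing component {label!r}")
        c = comp_cfg[label]
        components.append(
            NeutronComponentParams(
                label=label,
                C=float(c["C"]),
                alpha=float(c["alpha"]),
                sigma=float(c["sigma"]),
            )
        )
    extra = set(comp_cfg) - set(COMPONENT_LABELS)
    if extra:
        raise ValueError(f"unknown component labels in config: {sorted(extra)}")

    hd_iso = model_cfg.get("hd_iso")
    spec_cfg = cfg.get("spectrum")
    if hd_iso is None:
        if spec_cfg is None:
            raise ValueError("config must supply either model.hd_iso or a [spectrum] table")
        bins = spec_cfg["bins"] if isinstance(spec_cfg, dict) else spec_cfg
        arr = np.asarray(
            [[b["energy"], b["n"], b["hd_iso_j"]] for b in bins], dtype=np.float64
        )
        spectrum = EnergyBinSpectrum(arr[:, 0], arr[:, 1], arr[:, 2])
        hd_iso = weighted_hd_iso(spectrum, convention=nmax_convention)

    return NeutronSourceModel(
        hd_iso=float(hd_iso),
        p=float(model_cfg["p"]),
        d_iso=float(model_cfg["d_iso"]),
        dprime_iso=(
            float(model_cfg["dprime_iso"]) if "dprime_iso" in model_cfg else None
        ),
        field_size_factor=float(model_cfg.get("field_size_factor", 1.0)),
        components=tuple(components),
    )


def load_model(source, nmax_convention: str = "max_energy") -> NeutronSourceModel:
    """Load and validate a neutron source model from TOML (path) or a dict."""
    if isinstance(source, dict):
        return _model_from_dict(source, nmax_convention)
    with open(Path(source), "rb") as fh:
        return _model_from_dict(tomllib.load(fh), nmax_convention)


def default_model() -> NeutronSourceModel:
    """The packaged illustrative (non-clinical) parameter set."""
    data = resources.files("straydose").joinpath("data/default_model.toml").read_bytes()
    return _model_from_dict(tomllib.loads(data.decode()))
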