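import numpy as np
import pytest

import straydose as sd
from straydose.grid import default_hu_table


@pytest.fixture(scope="session")
def table():
    return default_hu_table()


@pytest.fixture(scope="session")
def toy_grid():
    """Small heterogeneous density grid (8 cm cube, 1 cm voxels), seeded."""
    rng = np.random.default_rng(7)
    return sd.VoxelGrid(
        origin=[0.0, 0.0, 0.0],
        spacing=[1.0, 1.0, 1.0],
        values=rng.uniform(0.2, 1.5, (8, 8, 8)),
    )


@pytest.fixture(scope="session")
def simple_model():
    """Single active component with hand-checkable parameters."""
    comps = tuple(
        sd.NeutronComponentParams(label, C, alpha, sigma)
        for label, C, alpha, sigma in [
            ("intranuclear-cascade", 1.0, 0.1, 10.0),
            ("evaporation", 0.0, 0.1, 10.0),
            ("epithermal", 0.0, 0.1, 10.0),
            ("thermal", 0.0, 0.1, 10.0),
        ]
    )
    return sd.NeutronSourceModel(
        hd_iso=3.68, p=1.0, d_iso=33.0, dprime_iso=10.0, components=comps
    )


@pytest.fixture(scope="session")
def packaged_model():
    return sd.default_model()


def sampled_pathlength(grid, p0, p1, outside=0.001, step=0.001):
    """Independent fine-step midpoint-sampling oracle for radiological pathlength."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step)), 1)
    t = (np.arange(n) + 0.5) / n
    pts = p0 + t[:, None] * (p1 - p0)
    idx = np.floor((pts - grid.origin) / grid.spacing).astype(int)
    dims = np.asarray(grid.dims)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    dens = np.full(n, outside)
    ii = idx[inside]
    dens[inside] = grid.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(dens.sum() * length / n)


@pytest.fixture(scope="session")
def water_box_coarse(table):
    """Water-box plan chain at 0.5 cm spacing, shared across proton tests."""
    grid, target = sd.make_water_box(0.5)
    plan = sd.default_water_box_plan(36.0)
    plan.aperture = sd.project_aperture(target, plan)
    plan.modulation_width = sd.modulation_width(target, grid, table, plan)
    ptv_ps = sd.build_ptv_ps(target, grid, table, plan)
    dose, diag = sd.proton_dose_grid(
        plan, grid, table, ptv_ps, return_diagnostics=True
    )
    return {
        "grid": grid,
        "target": target,
        "plan": plan,
        "ptv_ps": ptv_ps,
        "dose": dose,
        "diag": diag,
    }
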