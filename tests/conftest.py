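import numpy as np
import pytest

from orgscreen import synthgen
from orgscreen.quantify import ScreenTable

BC_PANEL = ["GD2", "NCAM1", "L1CAM", "EGFR", "EPCAM", "HER2"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A compact 3-organoid scene with mild noise, shared across tests."""
    spec = synthgen.random_scene(
        3,
        shape_voxels=(48, 192, 192),
        n_channels=2,
        intensity_range=(8000.0, 16000.0),
        seed=7,
    )
    spec.gaussian_sd = 0.03 * 12000.0
    stack, labels = synthgen.generate_stack(spec)
    return spec, stack, labels


def make_bc_table(n_per_line: int = 60, seed: int = 0, lognormal_sigma: float = 0.3):
    """Nine tumor lines + two healthy breast-like lines over the 6-probe panel."""
    rng = np.random.default_rng(seed)
    line_effects = {}
    for i in range(9):
        line_effects[f"T{i + 1}"] = {
            p: float(rng.uniform(200.0, 3000.0)) for p in BC_PANEL
        }
    for h in ("healthy1", "healthy2"):
        line_effects[h] = {p: float(rng.uniform(150.0, 400.0)) for p in BC_PANEL}
    df = synthgen.generate_screen_table(
        organoids_per_line=n_per_line,
        probe_panel=BC_PANEL,
        line_effects=line_effects,
        healthy_lines=["healthy1", "healthy2"],
        day_effects={"d1": 1.0, "d2": 1.3, "d3": 0.8},
        lognormal_sigma=lognormal_sigma,
        seed=seed + 1,
    )
    return ScreenTable.from_dataframe(df)


@pytest.fixture
def bc_table():
    return make_bc_table()
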