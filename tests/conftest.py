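import numpy as np
import pytest

from heliscreen.design import naive_design, pr21_design
from heliscreen.quantify import ScreenSample
from heliscreen.synth import SimulationConfig, default_planted, default_wells, simulate_screen


@pytest.fixture(scope="session")
def pr21():
    return pr21_design()


@pytest.fixture(scope="session")
def naive14():
    return naive_design()


@pytest.fixture(scope="session")
def small_screen():
    """A small but complete simulated trimerizer screen with ground truth."""
    rng = np.random.default_rng(123)
    design = naive_design()
    planted = default_planted(design, rng, n_trimerizers=5, n_binary=5)
    config = SimulationConfig(
        design=design,
        planted=planted,
        library_size=2000,
        depth=50_000,
        seed=123,
        wells=default_wells(),
    )
    table, wells, truth = simulate_screen(config, rng)
    return table, wells, truth


def make_samples():
    """A minimal trimerizer well layout used by hand-built count tables:
    one top-conc target+presenter well, two target-only replicates, one
    blank+presenter counter well, one blank well."""
    return [
        ScreenSample("num", "target", "TGT", 1.0, "PRS", 10.0, 1),
        ScreenSample("den1", "target", "TGT", 1.0, None, None, 1),
        ScreenSample("den2", "target", "TGT", 1.0, None, None, 2),
        ScreenSample("ctr", "blank", None, None, "PRS", 10.0, 1),
        ScreenSample("blank", "blank", None, None, None, None, 1),
    ]
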