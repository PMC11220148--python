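import numpy as np
import pytest

from mattforce.pressure import GRID_SHAPE, PressureGrid, PressureRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20240702)


@pytest.fixture
def random_recording(rng):
    """30 frames at 1 Hz of random non-negative pressures."""
    frames = rng.uniform(0.0, 40.0, (30,) + GRID_SHAPE)
    return PressureRecording(frames, np.arange(30.0), units="mmHg")


@pytest.fixture
def simple_grid():
    """A grid loaded in a small central patch, in Newtons."""
    values = np.zeros(GRID_SHAPE)
    values[10:14, 20:28] = 5.0
    values[11, 22] = 9.0
    return PressureGrid(values, units="N")


@pytest.fixture
def supine_case():
    """Noise-free supine synthetic scenario with surface and ground truth."""
    from mattforce.synth import make_pressure, make_scenario, make_surface

    scenario, _ = make_scenario(11, preset="supine", noise="none")
    cloud, normal_at = make_surface(scenario)
    grid, truth = make_pressure(scenario)
    return scenario, cloud, grid, truth
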