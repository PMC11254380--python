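import numpy as np
import pytest

from dropcyte import (
    AssayConstants,
    BUILTIN_PANELS,
    MeasurementMeta,
    SimConfig,
    default_calibration,
    make_time_grid,
    simulate_measurement,
)


@pytest.fixture(scope="session")
def constants():
    return AssayConstants()


@pytest.fixture(scope="session")
def grid(constants):
    return make_time_grid(constants.frame_interval_min, constants.duration_min)


@pytest.fixture(scope="session")
def panel1():
    return BUILTIN_PANELS["panel1"]


@pytest.fixture(scope="session")
def calibration(panel1):
    return default_calibration(panel1)


@pytest.fixture(scope="session")
def meta():
    return MeasurementMeta(stimulant="LPS", stim_duration_hr=1, panel_id="panel1")


@pytest.fixture(scope="session")
def small_dataset(meta):
    """A small simulated measurement at the default study conditions."""
    config = SimConfig(n_droplets=600, seed=11)
    traces, truth = simulate_measurement(config, meta)
    return config, traces, truth


def make_trace(droplet_id, relocation, has_cell=True, measurement_id="m0"):
    from dropcyte import DropletTrace

    return DropletTrace(
        droplet_id=droplet_id,
        measurement_id=measurement_id,
        has_cell=has_cell,
        relocation={ch: np.asarray(v, dtype=float) for ch, v in relocation.items()},
    )
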