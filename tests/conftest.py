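import numpy as np
import pytest

from scorploc import (
    StimulusPosition,
    default_grid,
    generate_dataset,
    make_default_array,
)
from scorploc.wave_sim import NoiseModel, WaveParams


@pytest.fixture(scope="session")
def array():
    return make_default_array()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noiseless_ds(array, grid):
    """Full 320-trial dataset at the default wood speed, no noise."""
    return generate_dataset(
        array, grid, 10, WaveParams(126.0), NoiseModel.noiseless(), seed=1
    )


@pytest.fixture(scope="session")
def jitter5_ds(array, grid):
    """320 trials with 5 µs Gaussian jitter and no systematic bias."""
    return generate_dataset(
        array,
        grid,
        10,
        WaveParams(126.0),
        NoiseModel(jitter_sigma=5.0, sensor_bias=np.zeros(8)),
        seed=11,
    )


@pytest.fixture(scope="session")
def balanced_angle_ds(array, grid):
    """Rotationally balanced dataset: all angles, symmetric jitter, zero bias."""
    return generate_dataset(
        array,
        grid,
        3,
        WaveParams(126.0),
        NoiseModel(jitter_sigma=20.0, sensor_bias=np.zeros(8)),
        seed=7,
    )


@pytest.fixture(scope="session")
def four_patterns(array):
    """Four clean single-trial patterns at distinct cardinal angles."""
    out = []
    for a in (0.0, 90.0, 180.0, 270.0):
        ds = generate_dataset(
            array,
            [StimulusPosition(a, 400.0)],
            1,
            WaveParams(126.0),
            NoiseModel.noiseless(),
            seed=0,
        )
        out.append(ds.trials[0])
    return out
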