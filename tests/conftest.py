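"""Shared fixtures: default kinetics and a small rendered imaging stack."""

import numpy as np
import pytest

from globtx.synthetic import (
    ImageSpec,
    PopulationSpec,
    generate_population,
    population_to_render_cells,
    render_timelapse,
)
from globtx.twostate import GlobalWaveform, SimConfig, TwoStateParams


@pytest.fixture(scope="session")
def params():
    return TwoStateParams()


@pytest.fixture(scope="session")
def sine_wave():
    return GlobalWaveform(kind="sine", amplitude=0.7, period_hr=12.0, phase=0.0)


@pytest.fixture(scope="session")
def flat_wave():
    return GlobalWaveform(kind="constant", amplitude=0.0)


@pytest.fixture(scope="session")
def sim48():
    return SimConfig(duration_hr=48.0, dt_sample_min=10.0)


@pytest.fixture(scope="session")
def rendered_stack():
    """Small noisy time-lapse with ground truth (SNR 10, separated spots)."""
    rng = np.random.default_rng(7)
    pop = generate_population(
        PopulationSpec(n_cells=6, cv_static=0.2, n_reporters=5, seed=7, dt_sample_min=60.0)
    )
    spec = ImageSpec(
        frame_shape=(256, 256), read_noise_sd=20.0, spot_amplitude_scale=200.0, z_slices=1
    )
    cells = population_to_render_cells(pop, spec, rng, max_cells=5)
    stack = render_timelapse(cells, spec, seed=11, n_frames=10)
    return stack
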