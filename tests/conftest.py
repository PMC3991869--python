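import numpy as np
import pytest
from hypothesis import settings

import vestigait as vg

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_params():
    return vg.default_params("control", "normal")


@pytest.fixture(scope="session")
def quiet_config():
    """No noise, no stride-to-stride variability."""
    return vg.SimulationConfig(noise_sd=0.0, stride_time_cv=0.0,
                               amplitude_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def quiet_leg(control_params, quiet_config):
    """30 noise-free control strides plus the generator's event schedule."""
    return vg.simulate_leg(control_params, 30, quiet_config,
                           return_truth=True)


@pytest.fixture(scope="session")
def quiet_analysis(quiet_leg):
    series, _ = quiet_leg
    return vg.analyze_series(series, corridor_length=88.8)


@pytest.fixture(scope="session")
def noisy_walk():
    """Full control corridor walk at the study's noise/variability levels."""
    recording = vg.simulate_walk(vg.SimulationConfig(seed=7))
    analyses = vg.analyze_recording(recording)
    return recording, analyses


def make_series(gx, gy, gz, dt=0.02, leg="left"):
    gx, gy, gz = (np.asarray(c, dtype=float) for c in (gx, gy, gz))
    t = np.arange(len(gz)) * dt
    return vg.AngularVelocitySeries(t, gx, gy, gz, leg=leg, sensor_id="test")
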