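import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgdecode import (ArmPlantConfig, NarxConfig, generate_trial,
                       init_parameters, preprocess_trial, simulate_parallel)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_plant_cfg():
    """A 30 s plant configuration shared by tests that only need realism,
    not decoding accuracy."""
    return ArmPlantConfig(duration_s=30.0, seed=123)


@pytest.fixture(scope="session")
def short_trial(short_plant_cfg):
    return generate_trial(short_plant_cfg)


@pytest.fixture(scope="session")
def short_envelope(short_trial):
    return preprocess_trial(short_trial)


@pytest.fixture(scope="session")
def teacher():
    """A random but fixed teacher network with non-trivial dynamics, plus a
    realizable dataset generated by running it closed-loop on smooth
    envelope-like inputs."""
    config = NarxConfig()
    rng = np.random.default_rng(2024)
    n = 3600
    # smooth nonnegative inputs in [0, 1]: random walks low-passed by cumsum
    raw = rng.standard_normal((n, config.n_inputs))
    kernel = np.hanning(41)
    kernel /= kernel.sum()
    smooth = np.stack([np.convolve(raw[:, i], kernel, mode="same")
                       for i in range(config.n_inputs)], axis=1)
    envelopes = (smooth - smooth.min(axis=0)) / np.ptp(smooth, axis=0)
    params = init_parameters(config, seed=11)
    # scale weights up so the teacher is meaningfully nonlinear
    params.A *= 6.0
    params.B *= 4.0
    params.C *= 3.0
    initial = np.zeros((config.burn_in, config.n_outputs))
    angles = simulate_parallel(params, envelopes, initial)
    return params, envelopes, angles
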