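import warnings

import pytest

from footgait import GaitSimParams, PipelineConfig, analyze
from footgait.synthetic import simulate_walk


@pytest.fixture(scope="session")
def short_cfg():
    """Pipeline config matching the shortened standstill of test fixtures."""
    return PipelineConfig(static_window_s=5.0)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free 20-stride bout with a short standstill, plus ground truth."""
    params = GaitSimParams(
        n_strides=20, initial_still_s=6.0, final_still_s=4.0, seed=7
    ).noise_free()
    return simulate_walk(params)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise 20-stride bout (study noise/bias levels), plus truth."""
    params = GaitSimParams(n_strides=20, initial_still_s=6.0, final_still_s=4.0, seed=7)
    return simulate_walk(params)


@pytest.fixture(scope="session")
def clean_result(clean_sim, short_cfg):
    rec, _ = clean_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze(rec, config=short_cfg)


@pytest.fixture(scope="session")
def noisy_result(noisy_sim, short_cfg):
    rec, _ = noisy_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze(rec, config=short_cfg)
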