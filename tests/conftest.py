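import numpy as np
import pytest

from prepsacc.design import DesignConfig, build_run_schedule
from prepsacc.hrf import dual_gamma_hrf
from prepsacc.simulate import ScenarioParams, make_patterns, simulate_bold_run


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A shortened run (8 trials) for tests where speed matters more than
    the full 20-trial protocol."""
    return DesignConfig(n_trials_per_run=8, n_pro=4, n_anti=4)


@pytest.fixture(scope="session")
def hrf():
    return dual_gamma_hrf()


@pytest.fixture(scope="session")
def small_schedule(small_config):
    return build_run_schedule(np.random.default_rng(11), small_config)


@pytest.fixture
def noiseless_run(small_schedule, hrf):
    """A zero-noise, zero-drift simulated run with known amplitudes."""
    gen = np.random.default_rng(5)
    patterns = make_patterns("cortex_like", 4, gen)
    run = simulate_bold_run(
        small_schedule, patterns, hrf, noise_sd=0.0, drift_amplitude=0.0, rng=gen
    )
    return run, patterns
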