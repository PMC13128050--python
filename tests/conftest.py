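import warnings

import numpy as np
import pytest

from rampgait import CohortSpec, RunConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def mini_noiseless_cohort():
    """2+2 participants, all conditions, no noise: exact ground truth."""
    spec = CohortSpec(
        n_young=2, n_old=2, trials_per_condition=2,
        participant_sd=0.0, feature_noise_sd=0.0, noise_sd=0.0, seed=101,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def mini_noisy_cohort():
    """2+2 participants with the default noise tiers."""
    spec = CohortSpec(n_young=2, n_old=2, trials_per_condition=2, seed=202)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def mini_results(mini_noiseless_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(mini_noiseless_cohort.trials)
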