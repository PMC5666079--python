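import warnings

import pytest

from mtleo import GeneratorSpec, fit_allometry, generate_traits


@pytest.fixture(scope="session")
def noiseless_cohort():
    """72 species generated exactly under the log-linear model (no noise)."""
    cohort = generate_traits(GeneratorSpec(bmr_noise_sd=0.0, mls_noise_sd=0.0, seed=11))
    return cohort, fit_allometry(cohort.traits)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions: 72 species, paper-scale lifespan scatter."""
    cohort = generate_traits(GeneratorSpec(seed=7))
    return cohort, fit_allometry(cohort.traits)


@pytest.fixture()
def quiet_scan_warnings():
    """Silence boundary-optimum warnings for scans whose optimum is the edge."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
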