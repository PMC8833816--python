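import pytest
from hypothesis import settings

from ovatriage import default_params, generate_cohort, run_all_strategies

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort_1k():
    """Default-parameter synthetic cohort of 1,000 women."""
    return generate_cohort(default_params(n=1000, seed=20180430))


@pytest.fixture(scope="session")
def predictions_1k(cohort_1k):
    return run_all_strategies(cohort_1k)
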