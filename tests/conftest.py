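import warnings

import pytest
from hypothesis import settings

from hospclimate.harness import pipeline_cohort
from hospclimate.model import ModelConfig, build_model_inputs, fit
from hospclimate.synthetic import Scenario, generate

warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile("fixed", derandomize=True, max_examples=50)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_data():
    """200 hospitals, 60 counties, 6 climates (one singleton)."""
    return generate(Scenario(n_hospitals=200, n_counties=60, n_climates=6, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_data, tmp_path_factory):
    return pipeline_cohort(small_data, str(tmp_path_factory.mktemp("small")))


@pytest.fixture(scope="session")
def small_inputs(small_cohort):
    return build_model_inputs(small_cohort)


@pytest.fixture(scope="session")
def small_fit(small_inputs):
    """One shared fit of the small cohort (2 chains keep it quick)."""
    return fit(small_inputs, ModelConfig(chains=2, iterations=1500, seed=5))
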