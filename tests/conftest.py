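import warnings

import pytest

from chronopanel.simulate import GeneratorConfig, generate_dataset

warnings.filterwarnings("ignore", message=".*MLE may be on the boundary.*")
warnings.filterwarnings("ignore", message=".*Random effects covariance is singular.*")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort (with follow-up wave), shared read-only."""
    return generate_dataset(GeneratorConfig(), seed=12345, followup=True)


@pytest.fixture()
def small_config():
    cfg = GeneratorConfig()
    cfg.demographics.n_participants = 400
    cfg.followup.home_office_n = 60
    return cfg
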