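import pytest
from hypothesis import settings

from pointorigin.classify import preprocess_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from pointorigin.synthdata import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study conditions (501 rows)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def analysis_cohort(default_cohort):
    """The default cohort, preprocessed and classified."""
    analysis, _ = preprocess_cohort(default_cohort)
    return analysis
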