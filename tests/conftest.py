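import numpy as np
import pytest

from consites import synthetic as syn
from consites.pipeline import PipelineConfig, run_all
from consites.pwm import exact_pvalue_table


@pytest.fixture(scope="session")
def core_pwm():
    return syn.ctcf_pwm()


@pytest.fixture(scope="session")
def score_table(core_pwm):
    return exact_pvalue_table(core_pwm)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic pipeline run shared by pipeline/acceptance tests."""
    return run_all(PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
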