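import numpy as np
import pytest

from hmdnuc.pipeline import PipelineConfig, run_pipeline
from hmdnuc.simulate import SyntheticConfig, generate


SMALL_SYNTH = SyntheticConfig(seed=7, chrom_length=200_000, n_hmds=24)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(seed=7, synthetic=SMALL_SYNTH)


@pytest.fixture(scope="session")
def small_result(small_config):
    """Full pipeline on a reduced genome (0.8 Mb, 24 HMDs); fast."""
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_result):
    return small_result.dataset


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default synthetic dataset (5 Mb, 200 HMDs)."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
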