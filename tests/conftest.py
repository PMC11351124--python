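import numpy as np
import pytest

from sorfclass.model import train_feature_suite
from sorfclass.synthetic import SyntheticConfig, generate_dataset

#: seed for the full-size synthetic study shared by the heavier tests
STUDY_SEED = 7


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_pos=120, n_neg=120, seed=11)


@pytest.fixture(scope="session")
def small_records(small_config):
    """120+120 strongly-signaled records shared across model tests."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def study_records():
    """The full-size study conditions: 1,000+1,000 records, full signal."""
    return generate_dataset(SyntheticConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_suite(study_records):
    """All seven feature-configuration models trained on the study data."""
    pos, neg = study_records
    models, splits, summary = train_feature_suite(pos, neg, seed=STUDY_SEED)
    return models, splits, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
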