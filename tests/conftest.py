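import numpy as np
import pytest

from bwmkl.core_data import FeatureTable
from bwmkl.synthetic import default_schema, default_spec, generate


@pytest.fixture(scope="session")
def big_cohort():
    """One large draw from the default spec, shared across tests."""
    return generate(default_spec(n_samples=5000, seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-subject cohort for fast pipeline tests."""
    return generate(default_spec(n_samples=150, seed=7))


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture()
def tiny_table():
    """Hand-written 4x2 table with positive target."""
    return FeatureTable(
        sample_ids=["a", "b", "c", "d"],
        feature_names=["MH", "MW"],
        values=np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 15.0], [4.0, 5.0]]),
        target=np.array([100.0, 200.0, 150.0, 120.0]),
    )
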