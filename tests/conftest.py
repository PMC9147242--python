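import numpy as np
import pytest

from ascakit.io import DesignTable
from ascakit.synthetic import SyntheticConfig, generate_feature_dataset


def make_design(labels, factor="group", amounts=None, prefix="S"):
    """Quick one-factor design from a label sequence."""
    return DesignTable(
        sample_ids=[f"{prefix}{i + 1:02d}" for i in range(len(labels))],
        factors={factor: list(labels)},
        sample_amount=amounts,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def marker_dataset():
    """Two-group dataset with strong planted markers (shared across tests)."""
    config = SyntheticConfig(
        n_per_group=8,
        group_levels=("A", "B"),
        n_variables=120,
        n_markers=15,
        effect_size=3.0,
        n_internal_standards=2,
        drift_sd=0.2,
        seed=7,
    )
    return generate_feature_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted effect at all."""
    config = SyntheticConfig(
        n_per_group=5,
        group_levels=("A", "B"),
        n_variables=40,
        n_markers=0,
        effect_size=0.0,
        n_internal_standards=1,
        seed=11,
    )
    return generate_feature_dataset(config)
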