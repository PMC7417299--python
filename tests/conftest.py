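import numpy as np
import pytest

from pancnv.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def two_class_cohort():
    """100 samples x 100 features, 10 planted, strong effect."""
    spec = CohortSpec(
        n_per_class=(50, 50),
        n_features=100,
        n_informative_per_class=5,
        effect_strength=0.8,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def four_class_cohort():
    """240 samples x 120 features, 20 planted, near-separable."""
    spec = CohortSpec(
        n_per_class=(60, 60, 60, 60),
        n_features=120,
        n_informative_per_class=5,
        effect_strength=0.9,
        seed=3,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
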