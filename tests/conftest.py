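import numpy as np
import pytest

from phenomm.data import build_trait_dataset
from phenomm.simulate import generate_dataset, scenario


@pytest.fixture(scope="session")
def direct_effect_ds():
    """One simulated study with a genuine genotype effect (beta1 = 1.5)."""
    recs = generate_dataset(scenario("direct_effect", seed=3))
    return build_trait_dataset(recs, "fat_mass", "simline")


@pytest.fixture(scope="session")
def null_ds():
    """One batch-confounded null study (no genotype effect anywhere)."""
    recs = generate_dataset(scenario("null_confounded", seed=5))
    return build_trait_dataset(recs, "fat_mass", "simline")


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)
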