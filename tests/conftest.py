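import numpy as np
import pytest

import faflab as fl


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort exercised by several pipeline tests."""
    spec = fl.CohortSpec(n_per_genotype={"AA": 4, "AG": 4, "GG": 3},
                         trials_per_condition=12, seed=42)
    return fl.simulate_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free vocal traces for ground-truth recovery checks."""
    spec = fl.CohortSpec(
        n_per_genotype={"AA": 3, "AG": 2, "GG": 2}, trials_per_condition=5,
        effects=fl.EffectParams(following_fraction=0.0), seed=7)
    return fl.simulate_cohort(spec, vocal_jitter=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
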