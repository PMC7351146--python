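import numpy as np
import pytest

from pulseqc import SyntheticConfig, gen_labeled_corpus, reference_model


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


def clean_synth_config(**overrides):
    """Noise-free, jitter-free generator settings for oracle tests."""
    defaults = dict(
        period_jitter=0.0,
        morph_jitter=0.0,
        baseline_wander_amplitude=0.0,
        noise_sd=0.0,
        rng_seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_corpus():
    """The default seeded labeled corpus (n=1000, 58% normal)."""
    return gen_labeled_corpus(SyntheticConfig(rng_seed=0), 1000, normal_fraction=0.58)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
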