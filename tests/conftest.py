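import numpy as np
import pytest

from convosync.features import extract_corpus_features
from convosync.synthetic_data import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Six dyads x two tasks at reduced duration, default (planted) effects."""
    cfg = GeneratorConfig(n_mixed_dyads=3, n_nonautistic_dyads=3, duration_s=120.0, seed=42)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    records, _ = small_corpus
    return extract_corpus_features(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
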