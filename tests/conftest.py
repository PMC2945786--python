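import numpy as np
import pytest

from coflank.synthetic_data import CorpusConfig, PlantedPair, generate_corpus


@pytest.fixture(scope="session")
def small_null_corpus():
    """150 exons with GC-correlated flanks and no planted pairs."""
    corpus, _ = generate_corpus(CorpusConfig(n_exons=150, seed=101))
    return corpus


@pytest.fixture(scope="session")
def planted_corpus():
    """2,000 exons with TCCCT:GGAGG planted jointly in 30% of UpDp windows."""
    cfg = CorpusConfig(
        n_exons=2000,
        seed=7,
        planted=(PlantedPair("TCCCT", "GGAGG", "UpDp", 0.3, 0.02, 0.02),),
    )
    return generate_corpus(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n, gc=0.5):
    return "".join(
        rng.choice(list("ACGT"), p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for _ in range(n)
    )
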