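import numpy as np
import pytest

from errorthreshold.fluctuation import CultureSet
from errorthreshold.synthetic import load_reference_orf


@pytest.fixture(scope="session")
def orf():
    """Bundled synthetic 1773-bp reporter open reading frame."""
    seq = load_reference_orf()
    assert len(seq) == 1773
    return seq


@pytest.fixture
def rng():
    return np.random.default_rng(20110)


@pytest.fixture(scope="session")
def mle_fixtures():
    """Hand-picked culture sets spanning jackpots, sparse counts and
    diluted platings, for estimator-vs-oracle comparisons."""
    return [
        CultureSet(counts=(0, 0, 0, 1, 0, 2, 0, 0, 15), n_total=1e7, label="spec"),
        CultureSet(counts=(0, 0, 1, 0, 0, 0, 0, 0, 0), n_total=1e7, label="sparse"),
        CultureSet(counts=(3, 1, 0, 7, 2, 1, 0, 0, 4), n_total=1e7, label="moderate"),
        CultureSet(counts=(12, 3, 41, 2, 7, 5, 9, 1, 130), n_total=1e7, label="jackpot"),
        CultureSet(counts=(1, 1, 2, 0, 3, 1, 0, 2, 1, 0, 1, 2), n_total=5e6,
                   label="dozen"),
        CultureSet(counts=(0, 2, 0, 9, 1, 0, 0, 3, 0), n_total=1e7,
                   plating_fraction=0.2, label="diluted"),
    ]
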