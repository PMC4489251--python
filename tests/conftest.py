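import numpy as np
import pytest

from affixpat.esa import normalize_seq
from affixpat.oracle import oracle_search
from affixpat.query import default_pairing_matrix
from affixpat.search import search


@pytest.fixture
def default_matrix():
    return default_pairing_matrix()


def engine_keys(target_id, seq, q, matrix):
    """Engine match set as comparable tuples."""
    return {m.key() for m in search([(target_id, seq)], q, matrix)}


def oracle_keys(target_id, seq, q, matrix):
    """Brute-force match set as comparable tuples."""
    return {m.key() for m in oracle_search(target_id, normalize_seq(seq), q, matrix)}


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
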