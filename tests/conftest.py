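import pytest

from peafold import (
    BasePairProbabilityMatrix,
    PairScoringModel,
    base_pair_probabilities,
    enumerate_structures,
    random_sequence,
    uniform_model,
)


def make_bpp(length, entries):
    """Build a probability matrix from a {(i, j): p} dict."""
    return BasePairProbabilityMatrix(length, entries)


@pytest.fixture(scope="session")
def default_model():
    return PairScoringModel()


@pytest.fixture(scope="session")
def test_sequences():
    """20 seeded random sequences, lengths 10-14, uniform composition."""
    return [random_sequence(10 + i % 5, seed=300 + i) for i in range(20)]


@pytest.fixture(scope="session")
def ensemble_cache():
    """Memoized (P, enumeration) per (sequence, model) — the oracle data."""
    cache = {}

    def get(seq, model):
        key = (seq.residues, tuple(sorted(model.pair_weights.items())),
               model.min_hairpin)
        if key not in cache:
            cache[key] = (
                base_pair_probabilities(seq, model),
                enumerate_structures(seq, model),
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def both_models():
    return [PairScoringModel(), uniform_model()]
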