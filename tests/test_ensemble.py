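"""Ensemble model: partition values, pairing probabilities, sampling,
enumeration — each checked against an independent route."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peafold import (
    InvalidCompositionError,
    InvalidSequenceError,
    InvalidStructureError,
    PairScoringModel,
    RnaSequence,
    SecondaryStructure,
    SequenceTooLongError,
    base_pair_probabilities,
    enumerate_structures,
    inside_partition,
    random_sequence,
    sample_structures,
    structure_probability,
    uniform_model,
)


class TestSequenceAndStructureTypes:
    def test_t_is_folded_to_u_and_case_is_normalized(self):
        assert RnaSequence("s", "gaaat").residues == "GAAAU"

    def test_illegal_residue_reports_position(self):
        with pytest.raises(InvalidSequenceError, match="position 3"):
            RnaSequence("s", "GAXAC")

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidSequenceError):
            RnaSequence("s", "")

    @pytest.mark.parametrize(
        "pairs, message",
        [
            ({(1, 8), (2, 8)}, "more than once"),  # shared position
            ({(2, 9), (5, 12)}, "cross"),  # pseudoknot
            ({(1, 4)}, "fewer than"),  # hairpin too short
            ({(1, 15)}, "outside"),  # beyond length
        ],
    )
    def test_structure_invariants_are_enforced(self, pairs, message):
        with pytest.raises(InvalidStructureError, match=message):
            SecondaryStructure(12, frozenset(pairs))

    def test_hairpin_constraint_is_configurable(self):
        s = SecondaryStructure(5, {(1, 4)}, min_hairpin=2)
        assert s.pairs == frozenset({(1, 4)})

    def test_structure_equality_ignores_min_hairpin(self):
        a = SecondaryStructure(10, {(1, 10)}, min_hairpin=3)
        b = SecondaryStructure(10, {(1, 10)}, min_hairpin=0)
        assert a == b and hash(a) == hash(b)


class TestInsidePartition:
    def test_no_pairable_residues_gives_unit_partition(self):
        Z, _ = inside_partition(RnaSequence("s", "AAAA"))
        assert Z == 1.0

    def test_single_hairpin_partition_is_one_plus_gc_weight(self):
        # ensemble = {empty, {(1,5)}} with weights 1 and 3
        Z, _ = inside_partition(RnaSequence("s", "GAAAC"))
        assert Z == pytest.approx(4.0)

    def test_uniform_model_partition_counts_structures(self):
        seq = RnaSequence("s", "GGGAAACCC")
        model = uniform_model()
        Z, _ = inside_partition(seq, model)
        assert Z == pytest.approx(len(enumerate_structures(seq, model)), rel=1e-12)

    def test_partition_equals_enumeration_weight_sum(
        self, test_sequences, both_models
    ):
        for seq in test_sequences[:8]:
            for model in both_models:
                Z, _ = inside_partition(seq, model)
                probs = [p for _, p in enumerate_structures(seq, model)]
                assert sum(probs) == pytest.approx(1.0, abs=1e-9)
                # Z consistency: probability of the empty structure is 1/Z
                empty = SecondaryStructure(len(seq), min_hairpin=model.min_hairpin)
                assert structure_probability(seq, model, empty) == pytest.approx(
                    1.0 / Z, rel=1e-9
                )


class TestBasePairProbabilities:
    def test_unpairable_sequence_has_empty_matrix(self):
        P = base_pair_probabilities(RnaSequence("s", "AAAA"))
        assert dict(P.items()) == {}

    def test_two_structure_ensemble_marginal(self):
        P = base_pair_probabilities(RnaSequence("s", "GAAAC"))
        assert dict(P.items()) == {(1, 5): pytest.approx(0.75)}

    def test_matches_enumeration_marginals(self, test_sequences, both_models,
                                           ensemble_cache):
        for seq in test_sequences[:8]:
            for model in both_models:
                P, ens = ensemble_cache(seq, model)
                marginals = {}
                for theta, p in ens:
                    for pair in theta.pairs:
                        marginals[pair] = marginals.get(pair, 0.0) + p
                for pair in set(marginals) | set(P.entries):
                    assert P.get(*pair) == pytest.approx(
                        marginals.get(pair, 0.0), abs=1e-9
                    )

    def test_single_partner_bound(self, test_sequences, default_model):
        for seq in test_sequences:
            P = base_pair_probabilities(seq, default_model)
            for k in range(1, len(seq) + 1):
                involved = sum(p for (i, j), p in P.items() if k in (i, j))
                assert involved <= 1 + 1e-9


class TestSampling:
    def test_unpairable_sequence_yields_empty_structures(self):
        sample = sample_structures(RnaSequence("s", "AAAA"), n=5, seed=0)
        assert all(t.pairs == frozenset() for t in sample.structures)

    def test_two_outcome_frequency_matches_marginal(self):
        # pair (1,5) has probability 3/4; binomial check at 3 s.e.
        n = 10000
        sample = sample_structures(RnaSequence("s", "GAAAC"), n=n, seed=42)
        freq = sum(1 for t in sample.structures if t.pairs) / n
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(freq - 0.75) <= 3 * se

    def test_identical_seed_reproduces_identical_sample(self):
        seq = random_sequence(12, seed=7)
        a = sample_structures(seq, n=50, seed=9)
        b = sample_structures(seq, n=50, seed=9)
        assert a.structures == b.structures

    def test_smaller_sample_is_prefix_of_larger_with_same_seed(self):
        seq = random_sequence(12, seed=7)
        small = sample_structures(seq, n=40, seed=3)
        large = sample_structures(seq, n=200, seed=3)
        assert large.structures[:40] == small.structures

    def test_empirical_structure_frequencies_match_enumeration(
        self, ensemble_cache, default_model
    ):
        from scipy.stats import chisquare

        seq = random_sequence(12, seed=11)
        _, ens = ensemble_cache(seq, default_model)
        n = 50000
        sample = sample_structures(seq, default_model, n=n, seed=5)
        counts = {}
        for t in sample.structures:
            counts[t.pairs] = counts.get(t.pairs, 0) + 1
        observed, expected = [], []
        tail_obs = tail_exp = 0.0
        for theta, p in ens:
            if n * p >= 5:
                observed.append(counts.get(theta.pairs, 0))
                expected.append(n * p)
            else:
                tail_obs += counts.get(theta.pairs, 0)
                tail_exp += n * p
        if tail_exp > 0:
            observed.append(tail_obs)
            expected.append(tail_exp)
        stat = chisquare(observed, np.asarray(expected) * n / sum(expected))
        assert stat.pvalue > 0.01


class TestEnumeration:
    def test_unpairable_sequence_enumerates_only_empty(self):
        ens = enumerate_structures(RnaSequence("s", "AAAA"))
        assert len(ens) == 1 and ens[0][1] == pytest.approx(1.0)

    def test_two_structure_ensemble(self):
        ens = sorted(
            enumerate_structures(RnaSequence("s", "GAAAC")),
            key=lambda tp: len(tp[0].pairs),
        )
        assert ens[0][1] == pytest.approx(0.25)
        assert ens[1][0].pairs == frozenset({(1, 5)})
        assert ens[1][1] == pytest.approx(0.75)

    def test_structures_are_unique_and_normalized(self, test_sequences,
                                                  default_model):
        for seq in test_sequences[:5]:
            ens = enumerate_structures(seq, default_model)
            keys = [theta.pairs for theta, _ in ens]
            assert len(keys) == len(set(keys))
            assert sum(p for _, p in ens) == pytest.approx(1.0, abs=1e-9)

    def test_cap_guards_against_exponential_blowup(self):
        with pytest.raises(SequenceTooLongError):
            enumerate_structures(random_sequence(19, seed=0))
        enumerate_structures(random_sequence(19, seed=0), cap=19)  # override ok


class TestStructureProbability:
    def test_degenerate_ensemble(self):
        seq = RnaSequence("s", "AAAA")
        assert structure_probability(
            seq, sigma=SecondaryStructure(4)
        ) == pytest.approx(1.0)

    def test_agrees_with_enumeration(self, ensemble_cache, default_model):
        seq = random_sequence(12, seed=13)
        _, ens = ensemble_cache(seq, default_model)
        for theta, p in ens:
            assert structure_probability(seq, default_model, theta) == pytest.approx(
                p, rel=1e-9
            )

    def test_forbidden_pair_rejected(self):
        seq = RnaSequence("s", "AAAAAC")
        with pytest.raises(InvalidStructureError, match="forbidden"):
            structure_probability(seq, sigma=SecondaryStructure(6, {(1, 6)}))


class TestRandomSequence:
    def test_pure_composition(self):
        assert random_sequence(10, {"A": 1.0}, seed=1).residues == "A" * 10

    def test_determinism(self):
        assert random_sequence(30, seed=4) == random_sequence(30, seed=4)

    def test_uniform_composition_frequencies(self):
        n = 10000
        seq = random_sequence(n, seed=2)
        se = math.sqrt(0.25 * 0.75 / n)
        for base in "ACGU":
            freq = seq.residues.count(base) / n
            assert abs(freq - 0.25) <= 3 * se

    def test_invalid_composition_rejected(self):
        with pytest.raises(InvalidCompositionError):
            random_sequence(10, {"A": 0.6, "C": 0.6})
        with pytest.raises(InvalidCompositionError):
            random_sequence(10, {"A": 0.5, "X": 0.5})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6), length=st.integers(5, 11))
def test_partition_consistency_property(seed, length):
    """Inside-algorithm Z equals the enumeration weight-sum for any short
    random sequence (weights recovered via the empty-structure probability)."""
    seq = random_sequence(length, seed=seed)
    model = PairScoringModel()
    Z, _ = inside_partition(seq, model)
    ens = enumerate_structures(seq, model)
    # reweigh each enumerated structure directly from the model
    total_weight = 0.0
    for theta, _ in ens:
        w = 1.0
        for i, j in theta.pairs:
            w *= model.weight(seq.residues[i - 1], seq.residues[j - 1])
        total_weight += w
    assert total_weight == pytest.approx(Z, rel=1e-9)
    assert sum(p for _, p in ens) == pytest.approx(1.0, abs=1e-9)
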