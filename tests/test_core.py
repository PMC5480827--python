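"""Pair-count algebra, entropies, and the ESABO permutation statistic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esabo import (
    PairCounts,
    SUPPORTED_OPERATIONS,
    binarize_table,
    binary_entropy,
    boolean_combine,
    cooccurrence_zscore,
    cooccurrence_zscore_std,
    entropy_from_counts,
    entropy_from_ones_fraction,
    esabo_score,
    esabo_score_exact,
    jaccard_scores,
    pair_counts,
    shifted_pair_counts,
)

# the worked co-abundance example: 822 samples, marginals 112 and 132, overlap 22
WORKED = PairCounts(alpha=600, beta=110, gamma=90, delta=22)


def vectors_from_counts(c: PairCounts) -> tuple[np.ndarray, np.ndarray]:
    b_i = np.array([0] * c.alpha + [0] * c.beta + [1] * c.gamma + [1] * c.delta)
    b_j = np.array([0] * c.alpha + [1] * c.beta + [0] * c.gamma + [1] * c.delta)
    return b_i, b_j


binary_vec = st.lists(st.integers(0, 1), min_size=2, max_size=60)
pair_vecs = st.integers(2, 60).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
)


class TestBinarize:
    def test_counts_map_to_presence(self):
        table = pd.DataFrame({"t": [0, 1, 37, 0]})
        assert binarize_table(table).t.tolist() == [0, 1, 1, 0]

    def test_threshold_five(self):
        table = pd.DataFrame({"t": [0, 1, 37, 4]})
        assert binarize_table(table, threshold=5).t.tolist() == [0, 0, 1, 0]

    def test_all_zero_column_stays_zero(self):
        table = pd.DataFrame({"a": [0.0, 0.0], "b": [2.0, 0.0]})
        out = binarize_table(table)
        assert out.a.tolist() == [0, 0]

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            binarize_table(pd.DataFrame({"a": [1.0, -2.0]}))


class TestPairCounts:
    def test_worked_example_from_marginals(self):
        b_i, b_j = vectors_from_counts(WORKED)
        assert pair_counts(b_i, b_j).as_tuple() == (600, 110, 90, 22)

    def test_identical_vectors(self):
        v = np.array([1, 1, 0, 0, 1])
        assert pair_counts(v, v).as_tuple() == (2, 0, 0, 3)

    def test_complementary_vectors(self):
        v = np.array([1, 1, 0, 0, 0])
        assert pair_counts(v, 1 - v).as_tuple() == (0, 3, 2, 0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            pair_counts([0, 1], [0, 1, 1])


class TestBooleanCombine:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pair_vecs)
    def test_matches_python_operators(self, pair):
        b_i = np.array(pair[0])
        b_j = np.array(pair[1])
        expected = {
            "AND": b_i & b_j,
            "OR": b_i | b_j,
            "XOR": b_i ^ b_j,
            "NAND": 1 - (b_i & b_j),
            "NOR": 1 - (b_i | b_j),
            "EQL": 1 - (b_i ^ b_j),
            "GT": b_i & (1 - b_j),
            "GE": 1 - ((1 - b_i) & b_j),
            "LT": (1 - b_i) & b_j,
            "LE": 1 - (b_i & (1 - b_j)),
        }
        for op in SUPPORTED_OPERATIONS:
            assert np.array_equal(boolean_combine(b_i, b_j, op), expected[op]), op

    def test_worked_example_ones_counts(self):
        b_i, b_j = vectors_from_counts(WORKED)
        assert boolean_combine(b_i, b_j, "AND").sum() == 22  # delta
        assert boolean_combine(b_i, b_j, "OR").sum() == 222  # beta+gamma+delta

    def test_xor_with_self_vanishes(self):
        v = np.array([1, 0, 1, 1])
        assert boolean_combine(v, v, "XOR").sum() == 0

    def test_unknown_operation_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            boolean_combine([0, 1], [1, 1], "IMPLIES")


class TestShiftedPairCounts:
    def test_and_moves_gamma_to_alpha(self):
        assert shifted_pair_counts(WORKED, "AND").as_tuple() == (690, 110, 0, 22)

    def test_or_moves_beta_to_delta(self):
        assert shifted_pair_counts(WORKED, "OR").as_tuple() == (600, 0, 90, 132)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_total_count_conserved_for_every_operation(self, quad):
        counts = PairCounts(*quad)
        for op in SUPPORTED_OPERATIONS:
            assert shifted_pair_counts(counts, op).n_samples == counts.n_samples

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pair_vecs)
    def test_consistent_with_direct_tabulation(self, pair):
        b_i = np.array(pair[0])
        b_j = np.array(pair[1])
        counts = pair_counts(b_i, b_j)
        for op in SUPPORTED_OPERATIONS:
            direct = pair_counts(boolean_combine(b_i, b_j, op), b_j)
            assert shifted_pair_counts(counts, op) == direct, op

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pair_vecs)
    def test_ones_count_monotonicity(self, pair):
        b_i = np.array(pair[0])
        b_j = np.array(pair[1])
        ones = b_i.sum()
        assert boolean_combine(b_i, b_j, "AND").sum() <= ones
        assert boolean_combine(b_i, b_j, "OR").sum() >= ones


class TestEntropy:
    def test_degenerate_vectors_have_zero_entropy(self):
        assert binary_entropy(np.zeros(8, dtype=int)) == 0.0
        assert binary_entropy(np.ones(8, dtype=int)) == 0.0

    def test_balanced_vector_attains_ln2(self):
        assert binary_entropy(np.array([0, 1, 0, 1])) == pytest.approx(math.log(2))

    def test_worked_example_entropy_drop_under_and(self):
        # ones-fraction 112/822 before, 22/822 after AND: the vector simplifies
        before = entropy_from_ones_fraction(112 / 822)
        after = entropy_from_ones_fraction(22 / 822)
        assert before == pytest.approx(0.398, abs=5e-4)
        assert after == pytest.approx(0.123, abs=5e-4)
        assert after < before

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(0, 1))
    def test_bounds_and_symmetry(self, p):
        h = entropy_from_ones_fraction(p)
        assert 0.0 <= h <= math.log(2) + 1e-12
        assert h == pytest.approx(entropy_from_ones_fraction(1 - p))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(pair_vecs)
    def test_closed_form_matches_vector_route(self, pair):
        b_i = np.array(pair[0])
        b_j = np.array(pair[1])
        counts = pair_counts(b_i, b_j)
        for op in SUPPORTED_OPERATIONS:
            via_vector = binary_entropy(boolean_combine(b_i, b_j, op))
            via_counts = entropy_from_counts(shifted_pair_counts(counts, op))
            assert via_vector == pytest.approx(via_counts), op


def brute_force_and_null(b_i: np.ndarray, b_j: np.ndarray):
    """Oracle: entropy moments over ALL distinct placements of b_j's ones."""
    n = b_i.size
    k_j = int(b_j.sum())
    entropies = []
    for ones_at in itertools.combinations(range(n), k_j):
        perm = np.zeros(n, dtype=int)
        perm[list(ones_at)] = 1
        entropies.append(binary_entropy(b_i & perm))
    entropies = np.array(entropies)
    return entropies.mean(), entropies.std(ddof=0)


class TestEsaboScore:
    def test_exact_null_matches_enumeration_oracle(self):
        b_i = np.array([1, 1, 1, 0, 0])
        b_j = np.array([1, 1, 0, 0, 0])
        mean, std = brute_force_and_null(b_i, b_j)
        res = esabo_score_exact(b_i, b_j)
        assert res.null_mean == pytest.approx(mean)
        assert res.null_std == pytest.approx(std)
        observed = binary_entropy(b_i & b_j)
        assert res.z_score == pytest.approx((observed - mean) / std)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_null_matches_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        b_i = rng.integers(0, 2, 12)
        b_j = rng.integers(0, 2, 12)
        mean, std = brute_force_and_null(b_i, b_j)
        res = esabo_score_exact(b_i, b_j)
        assert res.null_mean == pytest.approx(mean)
        assert res.null_std == pytest.approx(std)

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(42)
        b_i = (rng.random(200) < 0.4).astype(int)
        b_j = (rng.random(200) < 0.6).astype(int)
        exact = esabo_score_exact(b_i, b_j)
        mc = esabo_score(b_i, b_j, "AND", n_shuffles=10_000, seed=7)
        se = math.sqrt((1 + exact.z_score**2 / 2) / 10_000)
        assert abs(mc.z_score - exact.z_score) < 3 * se

    def test_constant_partner_gives_undefined_flag(self):
        b_i = np.array([1, 0, 1, 0])
        ones = np.ones(4, dtype=int)
        res = esabo_score(b_i, ones, "AND", n_shuffles=50, seed=0)
        assert not res.is_defined
        assert math.isnan(res.z_score)
        assert not esabo_score_exact(b_i, ones).is_defined

    def test_zscore_is_entropy_base_invariant(self):
        # rescaling H by 1/ln 2 (nats -> bits) cancels in the z-score
        rng = np.random.default_rng(3)
        b_i = rng.integers(0, 2, 100)
        b_j = rng.integers(0, 2, 100)
        res = esabo_score(b_i, b_j, "AND", n_shuffles=500, seed=1)
        scale = 1 / math.log(2)
        z_bits = (scale * res.observed_entropy - scale * res.null_mean) / (
            scale * res.null_std
        )
        assert z_bits == pytest.approx(res.z_score)

    def test_independent_vectors_score_near_zero(self):
        rng = np.random.default_rng(8)
        zs = []
        for _ in range(60):
            b_i = rng.integers(0, 2, 150)
            b_j = rng.integers(0, 2, 150)
            res = esabo_score_exact(b_i, b_j)
            if res.is_defined:
                zs.append(res.z_score)
        assert abs(np.mean(zs)) < 0.2
        assert np.std(zs) < 2.0


class TestCooccurrenceZscore:
    def test_worked_example_as_printed(self):
        expectation, variance, z = cooccurrence_zscore(WORKED)
        assert expectation == pytest.approx(112 * 132 / 822)
        assert variance == pytest.approx(112 * 132 * 690 / 822**2)
        assert z == pytest.approx((22 - expectation) / variance)

    def test_std_variant_differs_by_sqrt(self):
        _, variance, z_var = cooccurrence_zscore(WORKED)
        _, _, z_std = cooccurrence_zscore_std(WORKED)
        assert z_std == pytest.approx(z_var * math.sqrt(variance))

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            cooccurrence_zscore(PairCounts(0, 0, 0, 0))


class TestJaccard:
    def test_worked_example(self):
        b_i, b_j = vectors_from_counts(WORKED)
        j11, j00 = jaccard_scores(b_i, b_j)
        assert j11 == pytest.approx(22 / 112)
        assert j00 == pytest.approx(600 / 690)

    def test_identical_vectors_score_one(self):
        v = np.array([1, 0, 0, 1])
        assert jaccard_scores(v, v) == (1.0, 1.0)

    def test_disjoint_supports_score_zero(self):
        j11, _ = jaccard_scores(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1]))
        assert j11 == 0.0

    def test_degenerate_marginals_flagged(self):
        j11, j00 = jaccard_scores(np.array([1, 1, 1]), np.array([1, 0, 1]))
        assert math.isnan(j00)
        assert j11 == pytest.approx(2 / 2)
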