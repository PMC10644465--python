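"""Optimal sampling scale and the resamplers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carbosite.rebalance import (
    attention_scores,
    attention_undersample,
    optimal_scale,
    random_undersample,
    smote_oversample,
)


def brute_force_scale(m: int, M: int) -> int:
    """Integer minimiser of s/m + M/s over [m, M] (ties -> smallest s)."""
    best, best_val = m, np.inf
    for s in range(m, M + 1):
        val = s / m + M / s
        if val < best_val:
            best, best_val = s, val
    return best


class TestOptimalScale:
    @pytest.mark.parametrize("m,M,expected", [(3, 1000, 55), (4, 4, 4), (1, 1, 1)])
    def test_known_values(self, m, M, expected):
        assert optimal_scale(m, M) == expected

    def test_equals_brute_force_minimiser(self, rng):
        # the rounded sqrt may differ from the integer argmin by at most 1
        # when both straddle sqrt(mM)
        for _ in range(200):
            m = int(rng.integers(1, 2000))
            M = int(rng.integers(m, 10001))
            s = optimal_scale(m, M)
            assert m <= s <= M
            assert abs(s - brute_force_scale(m, M)) <= 1

    def test_monotone_in_both_arguments(self):
        vals_m = [optimal_scale(m, 5000) for m in range(1, 200)]
        assert all(a <= b for a, b in zip(vals_m, vals_m[1:]))
        vals_M = [optimal_scale(50, M) for M in range(50, 4000, 13)]
        assert all(a <= b for a, b in zip(vals_M, vals_M[1:]))

    @pytest.mark.parametrize("m,M", [(0, 10), (-1, 10), (5, 0), (20, 10)])
    def test_invalid_inputs(self, m, M):
        with pytest.raises(ValueError):
            optimal_scale(m, M)


def hand_attention_diag(X):
    """Two-line independent oracle: cosine matrix then row softmax."""
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    C = Xn @ Xn.T
    E = np.exp(C - C.max(axis=1, keepdims=True))
    return np.diag(E / E.sum(axis=1, keepdims=True))


class TestAttentionScores:
    def test_identical_rows_give_uniform_attention(self):
        X = np.tile([0.3, 0.7], (5, 1))
        A = attention_scores(X, X).A
        np.testing.assert_allclose(A, 1 / 5)

    def test_unit_vector_toy_matches_hand_softmax(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        A = attention_scores(X, X)
        np.testing.assert_allclose(A.diag, hand_attention_diag(X), atol=1e-12)

    @given(st.integers(2, 10), st.integers(1, 6), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_rows_are_stochastic(self, n, d, seed):
        X = np.random.default_rng(seed).uniform(0.1, 1.0, size=(n, d))
        A = attention_scores(X, X).A
        assert A.min() >= 0 and A.max() <= 1
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_row_is_an_error(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="row 1"):
            attention_scores(X, X)


class TestAttentionUndersample:
    def test_s_equals_M_keeps_everything(self, rng):
        neg = rng.uniform(0.1, 1, size=(8, 3))
        pos = rng.uniform(0.1, 1, size=(2, 3))
        plan = attention_undersample(neg, pos, s=8)
        assert plan.final_keep == list(range(8))
        assert plan.n_synthesize == 6

    def test_positive_like_negative_is_dropped(self):
        # Three near-duplicate negatives plus one isolated negative that is
        # collinear with the lone positive; at s=2 the positive-like
        # negative must not survive. (Its self-attention is the largest
        # of the four, so in this geometry it already falls at stage 1.)
        neg = np.array([[1.0, 0.02], [1.0, 0.0], [0.98, 0.02], [0.05, 1.0]])
        pos = np.array([[0.05, 1.0]])
        plan = attention_undersample(neg, pos, s=2)
        assert 3 not in plan.final_keep
        # hand oracle for both stages' diagonals
        d1 = hand_attention_diag(neg)
        expect_s1 = sorted(np.argsort(d1, kind="stable")[:3])
        assert plan.stage1_keep == expect_s1
        pool = np.vstack([neg[plan.stage1_keep], pos])
        d2 = hand_attention_diag(pool)[: len(plan.stage1_keep)]
        expect = sorted(np.asarray(plan.stage1_keep)[np.argsort(-d2, kind="stable")][:2])
        assert plan.final_keep == list(expect)

    def test_contract_and_determinism(self, rng):
        neg = rng.uniform(0.1, 1, size=(30, 4))
        pos = rng.uniform(0.1, 1, size=(5, 4))
        p1 = attention_undersample(neg, pos, s=12)
        p2 = attention_undersample(neg, pos, s=12)
        assert p1.final_keep == p2.final_keep
        assert len(p1.final_keep) == 12
        assert set(p1.final_keep) <= set(p1.stage1_keep)
        assert len(p1.stage1_keep) == int(np.ceil((12 + 30) / 2))

    def test_permutation_equivariance(self, rng):
        neg = rng.uniform(0.1, 1, size=(20, 3))
        pos = rng.uniform(0.1, 1, size=(4, 3))
        perm = rng.permutation(20)
        base = attention_undersample(neg, pos, s=7).final_keep
        permuted = attention_undersample(neg[perm], pos, s=7).final_keep
        assert sorted(perm[permuted]) == sorted(base)

    def test_errors(self, rng):
        neg = rng.uniform(0.1, 1, size=(5, 3))
        pos = rng.uniform(0.1, 1, size=(2, 3))
        with pytest.raises(ValueError, match="s must be"):
            attention_undersample(neg, pos, s=6)
        with pytest.raises(ValueError, match="dimension mismatch"):
            attention_undersample(neg, rng.uniform(size=(2, 4)), s=3)

    def test_plan_json_roundtrip(self, tmp_path, rng):
        from carbosite.rebalance import RebalancePlan

        plan = attention_undersample(
            rng.uniform(0.1, 1, size=(10, 3)), rng.uniform(0.1, 1, size=(2, 3)), s=4
        )
        path = tmp_path / "plan.json"
        plan.to_json(path)
        assert RebalancePlan.from_json(path) == plan


class TestRandomUndersample:
    def test_full_and_reproducible(self, rng):
        neg = rng.uniform(size=(10, 2))
        assert list(random_undersample(neg, 10, seed=3)) == list(range(10))
        a = random_undersample(neg, 5, seed=7)
        b = random_undersample(neg, 5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_uniform_selection_frequency(self, rng):
        neg = rng.uniform(size=(10, 2))
        counts = np.zeros(10)
        for seed in range(1000):
            counts[random_undersample(neg, 5, seed=seed)] += 1
        freq = counts / 1000
        assert np.all(np.abs(freq - 0.5) < 0.05)  # binomial 3-sigma ~ 0.047

    def test_s_too_large(self, rng):
        with pytest.raises(ValueError):
            random_undersample(rng.uniform(size=(4, 2)), 5, seed=0)


class TestSmote:
    def test_zero_requested(self, rng):
        out = smote_oversample(rng.uniform(size=(6, 3)), 0, k_neighbors=2, seed=0)
        assert out.shape == (0, 3)

    def test_identical_points_reproduce_themselves(self):
        pos = np.tile([0.2, 0.8], (6, 1))
        out = smote_oversample(pos, 10, k_neighbors=2, seed=1)
        np.testing.assert_allclose(out, np.tile([0.2, 0.8], (10, 1)))

    def test_synthetics_stay_in_bounding_box(self, rng):
        pos = rng.uniform(0.2, 0.9, size=(15, 4))
        out = smote_oversample(pos, 200, k_neighbors=5, seed=2)
        assert out.shape == (200, 4)
        assert np.all(out >= pos.min(axis=0) - 1e-12)
        assert np.all(out <= pos.max(axis=0) + 1e-12)

    def test_too_few_positives(self, rng):
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_oversample(rng.uniform(size=(3, 2)), 5, k_neighbors=3, seed=0)
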