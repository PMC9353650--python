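"""Attention scoring, CDF construction, and inverse transform sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atsvit.sampling import (DegenerateScoresError, SamplerConfig,
                             TokenSampler, compute_attention,
                             inverse_transform_sample, output_tokens,
                             select_tokens, significance_scores)


class TestComputeAttention:
    def test_equal_scores_give_uniform_rows(self):
        A = compute_attention(np.array([[1.0], [1.0]]), np.array([[1.0], [1.0]]), d=1)
        np.testing.assert_allclose(A, [[0.5, 0.5], [0.5, 0.5]])

    def test_log_ratio_softmax(self):
        # logits row [0, ln 2] must give [1/3, 2/3]
        q = np.array([[1.0, 0.0], [0.0, 0.0]])
        k = np.array([[0.0, 0.0], [np.log(2.0) * np.sqrt(2), 0.0]])
        A = compute_attention(q, k)
        np.testing.assert_allclose(A[0], [1 / 3, 2 / 3], atol=1e-12)

    def test_rows_are_probability_vectors(self, rng):
        A = compute_attention(rng.standard_normal((4, 8)),
                              rng.standard_normal((4, 8)))
        assert np.all(A >= 0) and np.all(A <= 1)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            compute_attention(rng.random((3, 4)), rng.random((2, 4)))


class TestOutputTokens:
    def test_identity_attention_returns_values(self, rng):
        V = rng.random((4, 5))
        np.testing.assert_array_equal(output_tokens(np.eye(4), V), V)

    def test_hand_product(self):
        O = output_tokens(np.full((2, 2), 0.5), np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(O, [[1.0], [1.0]])

    def test_convexity_preserves_constant_rows(self, rng):
        A = compute_attention(rng.random((3, 2)), rng.random((3, 2)))
        V = np.full((3, 4), 7.0)
        np.testing.assert_allclose(output_tokens(A, V), V, atol=1e-12)

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError, match="columns"):
            output_tokens(np.eye(3), np.zeros((4, 2)))


class TestSignificanceScores:
    def test_symmetric_case_is_uniform(self):
        A = np.full((4, 4), 0.25)
        V = np.ones((4, 3))
        S, cdf = significance_scores(A, V)
        np.testing.assert_allclose(S, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(cdf, [1 / 3, 2 / 3, 1.0], atol=1e-12)

    def test_worked_example(self):
        # CLS row (0.1, 0.2, 0.3, 0.4), value norms (*, 1, 1, 2)
        A = np.zeros((4, 4))
        A[0] = [0.1, 0.2, 0.3, 0.4]
        V = np.zeros((4, 1))
        V[1:, 0] = [1.0, 1.0, 2.0]
        S, _ = significance_scores(A, V)
        np.testing.assert_allclose(S, [0.1538, 0.2308, 0.6154], atol=1e-4)

    def test_head_average_reduces_to_single_head(self, rng):
        A = compute_attention(rng.random((5, 3)), rng.random((5, 3)))
        V = rng.random((5, 3))
        S1, c1 = significance_scores(A, V)
        S2, c2 = significance_scores(A[None, :, :], V)  # one-head stack
        np.testing.assert_array_equal(S1, S2)
        np.testing.assert_array_equal(c1, c2)

    def test_degenerate_raises_or_uniform(self):
        A = np.zeros((3, 3))
        A[0, 0] = 1.0  # all CLS mass on itself
        V = np.ones((3, 2))
        with pytest.raises(DegenerateScoresError):
            significance_scores(A, V)
        S, _ = significance_scores(A, V, on_degenerate="uniform")
        np.testing.assert_allclose(S, [0.5, 0.5])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_scores_always_normalized(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 12))
        A = compute_attention(r.standard_normal((n, 4)), r.standard_normal((n, 4)))
        V = r.standard_normal((n, 4))
        S, cdf = significance_scores(A, V)
        assert np.all(S >= 0)
        assert S.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-6)


class TestInverseTransformSample:
    def test_generalized_inverse_convention(self):
        # u = 0.6 against CDF [0.2, 0.5, 1.0] selects the third patch
        cdf = np.array([0.2, 0.5, 1.0])

        class FixedRng:
            def uniform(self, lo, hi, size):
                return np.full(size, 0.6)

        idx = inverse_transform_sample(cdf, k=1, mode="stochastic", rng=FixedRng())
        np.testing.assert_array_equal(idx, [2])

    def test_budget_at_least_n_returns_all(self):
        cdf = np.array([0.2, 0.5, 1.0])
        for k in (3, 5, 100):
            np.testing.assert_array_equal(
                inverse_transform_sample(cdf, k, mode="deterministic"),
                [0, 1, 2])

    def test_concentrated_distribution_collapses(self):
        cdf = np.array([1.0, 1.0, 1.0, 1.0, 1.0])  # S = (1, 0, 0, 0, 0)
        rng = np.random.default_rng(0)
        idx = inverse_transform_sample(cdf, k=3, mode="stochastic", rng=rng)
        np.testing.assert_array_equal(idx, [0])

    def test_realized_count_never_exceeds_budget(self, rng):
        for _ in range(50):
            S = rng.dirichlet(np.ones(10))
            k = int(rng.integers(1, 9))
            idx = inverse_transform_sample(np.cumsum(S), k,
                                           mode="stochastic", rng=rng)
            assert 1 <= idx.size <= k
            assert np.all(np.diff(idx) > 0)  # distinct ascending

    def test_sampler_reproducible_given_seed(self, rng):
        A = compute_attention(rng.random((9, 4)), rng.random((9, 4)))
        V = rng.random((9, 4))
        s1 = TokenSampler(SamplerConfig(k=4, mode="stochastic", seed=7))
        s2 = TokenSampler(SamplerConfig(k=4, mode="stochastic", seed=7))
        for _ in range(5):
            np.testing.assert_array_equal(s1.sample(A, V), s2.sample(A, V))


class TestSelectTokens:
    def test_all_patches_is_identity(self, rng):
        O = rng.random((6, 3))
        np.testing.assert_array_equal(select_tokens(O, np.arange(5)), O)

    def test_gather_keeps_cls_first_and_ascending(self, rng):
        O = rng.random((5, 2))
        out = select_tokens(O, np.array([3, 1]))  # patch idx -> rows 4, 2
        np.testing.assert_array_equal(out, O[[0, 2, 4]])

    def test_shrinking_selection_never_reintroduces_rows(self, rng):
        O = rng.random((9, 3))
        first = select_tokens(O, np.array([1, 3, 5, 7]))
        second = select_tokens(first, np.array([0, 2]))  # of the survivors
        rows = {tuple(r) for r in second[1:]}
        assert rows <= {tuple(r) for r in first[1:]}

    def test_out_of_range_raises(self, rng):
        with pytest.raises(IndexError):
            select_tokens(rng.random((4, 2)), np.array([3]))
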