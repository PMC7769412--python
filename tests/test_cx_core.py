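"""Unit and property tests for the contextual-similarity mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxct.cx_core import (
    CXParams,
    FeatureSet,
    LossWeights,
    combined_loss,
    cosine_distances,
    cx_from_distances,
    cx_loss,
    global_similarity,
    l2_loss,
    perceptual_loss,
    sample_features,
)
from cxct.features import ExtractorConfig, FeatureExtractor

from oracles import cx_chain_oracle


class TestCosineDistances:
    def test_identical_single_vectors_give_zero_distance(self):
        d = cosine_distances(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]]))
        assert d.shape == (1, 1)
        assert d[0, 0] == 0.0

    def test_hand_computed_two_target_case(self):
        # mu_t = (0.5, 0.5); centered s = t1 = (0.5,-0.5), t2 = (-0.5,0.5)
        d = cosine_distances(np.array([[1.0, 0.0]]),
                             np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(d, [[0.0, 2.0]], atol=1e-4)

    def test_entries_within_cosine_range(self, rng):
        d = cosine_distances(rng.normal(size=(6, 3)), rng.normal(size=(5, 3)))
        assert np.all(d >= -1e-12) and np.all(d <= 2 + 1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="dimension mismatch"):
            cosine_distances(rng.normal(size=(3, 2)), rng.normal(size=(3, 4)))

    def test_matches_scalar_loop_oracle(self, rng):
        S, T = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        d_or, _, _ = cx_chain_oracle(S, T)
        np.testing.assert_allclose(cosine_distances(S, T), d_or, atol=1e-10)


class TestCXMatrix:
    def test_orthogonal_pair_is_near_identity(self):
        cx = cx_from_distances(np.array([[0.0, 2.0], [2.0, 0.0]]), CXParams())
        np.testing.assert_allclose(cx, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_constant_distances_give_uniform_rows(self, n):
        cx = cx_from_distances(np.full((n, n), 0.7), CXParams())
        np.testing.assert_allclose(cx, np.full((n, n), 1.0 / n), rtol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(50):
            d = rng.uniform(0, 2, size=rng.integers(1, 9, size=2))
            cx = cx_from_distances(d, CXParams())
            np.testing.assert_allclose(cx.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(cx >= 0) and np.all(cx <= 1 + 1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        from oracles import cx_matrix_oracle

        d = rng.uniform(0, 2, size=(6, 6))
        np.testing.assert_allclose(cx_from_distances(d, CXParams()),
                                   cx_matrix_oracle(d), atol=1e-10)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cx_from_distances(np.zeros((0, 3)), CXParams())


class TestGlobalSimilarity:
    def test_identity_matrix_gives_one(self):
        assert global_similarity(np.eye(7)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_uniform_matrix_gives_one_over_n(self, n):
        assert global_similarity(np.full((n, n), 1.0 / n)) == pytest.approx(1.0 / n)

    def test_hand_computed_column_maxima(self):
        cx = np.array([[0.7, 0.3], [0.4, 0.6]])
        assert global_similarity(cx) == pytest.approx(0.65)


class TestCXLoss:
    def test_self_loss_is_zero(self, rng):
        S = rng.normal(size=(16, 4))
        assert cx_loss(S, S) <= 1e-5

    def test_uniform_similarity_gives_log_n(self):
        # four mutually dissimilar features: CX uniform 1/4 -> loss = log 4
        loss = -np.log(global_similarity(np.full((4, 4), 0.25)))
        assert loss == pytest.approx(np.log(4), abs=1e-12)

    def test_loss_nonnegative_and_finite(self, rng):
        for _ in range(10):
            loss = cx_loss(rng.normal(size=(6, 3)), rng.normal(size=(5, 3)))
            assert 0 <= loss < np.inf

    def test_loss_decreases_toward_target(self, rng):
        """Interpolating the source toward the target monotonically helps."""
        S, T = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        losses = [cx_loss(S + a * (T - S), T) for a in (0.0, 0.5, 0.9, 1.0)]
        assert losses[-1] <= 1e-5
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_full_chain_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            ns, nt = rng.integers(1, 9, size=2)
            d_dim = rng.integers(1, 5)
            S, T = rng.normal(size=(ns, d_dim)), rng.normal(size=(nt, d_dim))
            d_or, cx_or, gs_or = cx_chain_oracle(S, T)
            d = cosine_distances(S, T)
            cx = cx_from_distances(d, CXParams())
            np.testing.assert_allclose(d, d_or, atol=1e-10)
            np.testing.assert_allclose(cx, cx_or, atol=1e-10)
            assert global_similarity(cx) == pytest.approx(gs_or, abs=1e-10)

    def test_scale_invariance_of_cx_matrix(self, rng):
        S, T = rng.normal(size=(6, 4)), rng.normal(size=(7, 4))
        base = cx_from_distances(cosine_distances(S, T), CXParams())
        scaled = cx_from_distances(cosine_distances(7.3 * S, 7.3 * T), CXParams())
        np.testing.assert_allclose(scaled, base, atol=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(2, 10), st.integers(2, 4), st.integers(0, 10_000))
def test_self_similarity_property(n, d, seed):
    """CX(S, S) = 1 whenever the feature directions are separated.

    The exact precondition is separation at the epsilon scale: each
    feature's zero self-distance must be isolated from its nearest
    other-feature distance relative to eps = 1e-5 (after normalising by
    the row minimum, a competitor at distance ~eps yields an affinity
    comparable to the self-match and the similarity genuinely drops
    below 1).  D >= 2 because in one dimension all centered features are
    collinear and cosine similarity cannot separate them at all.
    """
    from hypothesis import assume

    S = np.random.default_rng(seed).normal(size=(n, d))
    dmat = cosine_distances(S, S)
    off = dmat + 10.0 * np.eye(n)
    assume(off.min() > 1e-3)  # directions separated well above the eps scale
    cx = cx_from_distances(dmat, CXParams())
    assert global_similarity(cx) == pytest.approx(1.0, abs=1e-5)


class TestComparisonLosses:
    def test_l2_identical_is_zero_and_345_triangle(self):
        x = np.zeros((4, 4))
        y = x.copy()
        y[0, 0], y[0, 1] = 3.0, 4.0
        assert l2_loss(x, x) == pytest.approx(0.0, abs=1e-9)
        assert l2_loss(x, y) == pytest.approx(5.0)

    def test_l2_homogeneous_in_the_difference(self, rng):
        x, y = rng.normal(size=(5, 5)), rng.normal(size=(5, 5))
        base = l2_loss(x, y)
        assert l2_loss(x, x + 3.0 * (y - x)) == pytest.approx(3.0 * base, rel=1e-9)

    def test_l2_shape_mismatch(self):
        with pytest.raises(ValueError):
            l2_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_perceptual_identical_is_zero(self, rng):
        ext = FeatureExtractor(ExtractorConfig(seed=3))
        x = rng.normal(0, 300, (16, 16))
        assert perceptual_loss(x, x, "conv1_2", ext) == pytest.approx(0.0, abs=1e-6)

    def test_perceptual_with_identity_extractor_is_l1(self, rng):
        class IdentityExtractor:
            def hu_feature_maps(self, image, layers):
                from cxct._autodiff import as_tensor

                t = as_tensor(image)
                return {layer: t.reshape(1, *t.data.shape) for layer in layers}

        x, y = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        got = perceptual_loss(x, y, "any", IdentityExtractor())
        assert got == pytest.approx(np.abs(x - y).sum(), rel=1e-8)


class TestSampling:
    def test_full_sample_returns_set_unchanged(self, rng):
        fs = FeatureSet(rng.normal(size=(10, 3)))
        assert sample_features(fs, 10, seed=0) is fs

    def test_sampling_is_deterministic_and_duplicate_free(self, rng):
        fs = FeatureSet(rng.normal(size=(100, 3)))
        a = sample_features(fs, 10, seed=42)
        b = sample_features(fs, 10, seed=42)
        np.testing.assert_array_equal(a.vectors, b.vectors)
        assert a.n == 10
        # every sampled vector occurs in the original set, no index repeated
        rows = {tuple(v) for v in a.vectors}
        assert len(rows) == 10
        orig = {tuple(v) for v in fs.vectors}
        assert rows <= orig


@pytest.fixture(scope="module")
def ext():
    return FeatureExtractor(ExtractorConfig(seed=5))


class TestCombinedLoss:
    def test_identical_triple_gives_near_zero(self, ext, rng):
        img = rng.normal(0, 300, (32, 32))
        total = combined_loss(img, img, img, LossWeights(), CXParams(), ext)
        assert total <= 1e-4

    def test_lambda_zero_reduces_to_content_term(self, ext, rng):
        g, s, t = (rng.normal(0, 300, (32, 32)) for _ in range(3))
        w0 = LossWeights(lambda_weight=0.0)
        total = combined_loss(g, s, t, w0, CXParams(), ext)
        content_only = cx_loss(
            ext.hu_feature_sets(g.astype(np.float64), ["conv4_2"])["conv4_2"].data,
            ext.hu_feature_sets(s.astype(np.float64), ["conv4_2"])["conv4_2"].data,
            CXParams(),
        )
        assert total == pytest.approx(content_only, rel=1e-6)

    def test_total_is_content_plus_lambda_style_exactly(self, ext, rng):
        g, s, t = (rng.normal(0, 300, (32, 32)) for _ in range(3))
        total, content, style = combined_loss(
            g, s, t, LossWeights(lambda_weight=5.0), CXParams(), ext, return_terms=True)
        assert total == content + 5.0 * style

    def test_deterministic_across_invocations(self, ext, rng):
        g, s, t = (rng.normal(0, 300, (32, 32)) for _ in range(3))
        w = LossWeights(style_sample_n=100, sample_seed=9)
        a = combined_loss(g, s, t, w, CXParams(), ext)
        b = combined_loss(g, s, t, w, CXParams(), ext)
        assert a == b

    def test_missing_layer_is_reported_by_name(self, ext, rng):
        img = rng.normal(0, 300, (32, 32))
        with pytest.raises(ValueError, match="conv9_9"):
            combined_loss(img, img, img, LossWeights(content_layer="conv9_9"),
                          CXParams(), ext)
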