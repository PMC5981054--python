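import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist

from clinalign.embeddings import EmbeddingModel, cosine
from clinalign.errors import AlignmentError, ConfigError
from clinalign.harmonize import (
    AnchorSet,
    apply_transform,
    fit_procrustes,
    fuse_models,
    harmonize_multi,
    harmonize_pair,
    select_anchors,
)
from clinalign.synthdata import simulate_transformed_embedding


def random_rotation(m, seed):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((m, m)))
    return q * np.sign(np.diag(r))


class TestFitProcrustes:
    def test_identity_alignment(self, rng):
        X = rng.standard_normal((40, 8))
        t = fit_procrustes(X, X)
        assert t.k == pytest.approx(1.0, abs=1e-12)
        assert t.residual == pytest.approx(0.0, abs=1e-9)
        # assert on the action (Q may be ambiguous only in degenerate spectra)
        Xc = X - X.mean(axis=0)
        assert np.allclose(t.map_moving(X), Xc, atol=1e-9)

    def test_pure_translation_recovers_k_equal_one(self, rng):
        X = rng.standard_normal((40, 8))
        Y = X + rng.standard_normal(8)  # constant row shift
        t = fit_procrustes(X, Y)
        assert t.k == pytest.approx(1.0, abs=1e-9)
        assert t.residual == pytest.approx(0.0, abs=1e-8)

    def test_exact_recovery_of_rotation_and_scale(self, rng):
        # Y_c = (1/k0) X_c R with generic full-rank X: fit returns Q=R, k=k0
        n, m, k0 = 200, 25, 2.5
        R = random_rotation(m, seed=99)
        X = rng.standard_normal((n, m)) + 3.0
        Xc = X - X.mean(axis=0)
        Y = Xc @ R / k0 + rng.standard_normal(m)  # plus arbitrary translation
        t = fit_procrustes(X, Y)
        assert np.linalg.norm(t.Q - R) < 1e-8
        assert abs(t.k - k0) < 1e-8
        assert t.residual < 1e-6

    def test_agrees_with_scipy_orthogonal_procrustes(self, rng):
        X = rng.standard_normal((60, 10))
        Y = rng.standard_normal((60, 10))
        t = fit_procrustes(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        # scipy solves min ||Yc R - Xc||: R maps rows on the right, our Q = R^T
        R, _ = orthogonal_procrustes(Yc, Xc)
        assert np.allclose(t.Q, R.T, atol=1e-10)

    def test_orthogonality_always_holds(self, rng):
        for i in range(10):
            X = rng.standard_normal((30, 6))
            Y = rng.standard_normal((30, 6))
            t = fit_procrustes(X, Y)
            assert t.orthogonality_error() < 1e-8

    def test_shape_mismatch_and_degenerate_inputs(self, rng):
        with pytest.raises(AlignmentError):
            fit_procrustes(rng.standard_normal((5, 3)), rng.standard_normal((5, 4)))
        with pytest.raises(AlignmentError):
            fit_procrustes(rng.standard_normal((1, 3)), rng.standard_normal((1, 3)))
        X = rng.standard_normal((5, 3))
        Y = np.ones((5, 3))  # zero variance after centering
        with pytest.raises(AlignmentError):
            fit_procrustes(X, Y)

    def test_underdetermined_warns(self, rng):
        X = rng.standard_normal((4, 6))
        Y = rng.standard_normal((4, 6))
        with pytest.warns(UserWarning, match="under-determined"):
            fit_procrustes(X, Y)


class TestApplyTransform:
    def _model(self, rng, n=30, m=6):
        return EmbeddingModel(
            [f"c{i}" for i in range(n)], rng.standard_normal((n, m))
        )

    def test_identity_transform_is_noop(self, rng):
        from clinalign.harmonize import HarmonizationTransform

        model = self._model(rng)
        t = HarmonizationTransform(
            Q=np.eye(6), k=1.0, mu_X=np.zeros(6), mu_Y=np.zeros(6)
        )
        out = apply_transform(model, t, "moving")
        assert np.allclose(out.matrix, model.matrix)

    def test_moving_side_scales_pairwise_distances_by_k(self, rng):
        model = self._model(rng)
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 6))
        t = fit_procrustes(X, Y)
        out = apply_transform(model, t, "moving")
        assert np.allclose(pdist(out.matrix), t.k * pdist(model.matrix), rtol=1e-9)

    def test_reference_side_preserves_distances(self, rng):
        model = self._model(rng)
        t = fit_procrustes(rng.standard_normal((30, 6)), rng.standard_normal((30, 6)))
        out = apply_transform(model, t, "reference")
        assert np.allclose(pdist(out.matrix), pdist(model.matrix), rtol=1e-12)

    def test_difference_vector_cosines_invariant_on_moving_side(self, rng):
        model = self._model(rng)
        t = fit_procrustes(rng.standard_normal((30, 6)), rng.standard_normal((30, 6)))
        out = apply_transform(model, t, "moving")
        a, b, c, d = model.matrix[:4]
        a2, b2, c2, d2 = out.matrix[:4]
        assert cosine(a - b, c - d) == pytest.approx(
            cosine(a2 - b2, c2 - d2), abs=1e-9
        )

    def test_dim_mismatch_rejected(self, rng):
        model = self._model(rng, m=5)
        t = fit_procrustes(rng.standard_normal((30, 6)), rng.standard_normal((30, 6)))
        with pytest.raises(AlignmentError):
            apply_transform(model, t, "moving")


class TestSelectAnchors:
    def _models(self, rng):
        a = EmbeddingModel([f"c{i}" for i in range(10)] + ["onlyA"], rng.standard_normal((11, 4)))
        b = EmbeddingModel([f"c{i}" for i in range(10)] + ["onlyB"], rng.standard_normal((11, 4)))
        return a, b

    def test_disjoint_vocabularies_error(self, rng):
        a = EmbeddingModel(["x", "y"], rng.standard_normal((2, 4)))
        b = EmbeddingModel(["u", "v"], rng.standard_normal((2, 4)))
        with pytest.raises(AlignmentError):
            select_anchors(a, b, "random_fraction", 0.5)

    def test_random_fraction_count_and_reproducibility(self, rng):
        a, b = self._models(rng)
        s1 = select_anchors(a, b, "random_fraction", 0.4, seed=7)
        s2 = select_anchors(a, b, "random_fraction", 0.4, seed=7)
        assert len(s1) == 4  # ceil(0.4 * 10)
        assert s1.pairs == s2.pairs
        assert all(l == r for l, r in s1.pairs)

    def test_top_frequency_matches_exhaustive_sort(self, rng):
        a, b = self._models(rng)
        freqs = {f"c{i}": (i * 7) % 10 for i in range(10)}
        sel = select_anchors(
            a, b, "top_frequency_fraction", 0.3, corpus_frequencies=freqs
        )
        oracle = sorted(
            (f"c{i}" for i in range(10)), key=lambda c: (-freqs[c], c)
        )[:3]
        assert [l for l, _ in sel.pairs] == sorted(oracle)

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ConfigError):
            AnchorSet(pairs=[("a", "x"), ("a", "y")])


class TestHarmonizePair:
    def test_ground_truth_transform_recovered_from_simulated_model(self, rng):
        model = EmbeddingModel(
            [f"c{i}" for i in range(80)], rng.standard_normal((80, 12))
        )
        moved, true_t = simulate_transformed_embedding(
            model, k0=2.5, rotation_seed=5, noise_sd=0.0,
            translation=rng.standard_normal(12),
        )
        anchors = AnchorSet(pairs=[(c, c) for c in model.vocabulary])
        result = harmonize_pair(model, moved, anchors)
        assert result.residual < 1e-6
        assert abs(result.transform.k - 2.5) < 1e-8
        # anchor images coincide in the common space
        gap = np.max(
            np.linalg.norm(result.reference.matrix - result.moving.matrix, axis=1)
        )
        assert gap < 1e-6

    def test_degenerate_self_alignment_residual_zero(self, rng):
        model = EmbeddingModel([f"c{i}" for i in range(20)], rng.standard_normal((20, 5)))
        anchors = AnchorSet(pairs=[(c, c) for c in model.vocabulary])
        result = harmonize_pair(model, model, anchors)
        assert result.residual == pytest.approx(0.0, abs=1e-9)

    def test_same_corpus_different_seed_models_get_closer(self, trained_pair):
        m1, m2, _ = trained_pair
        common = sorted(set(m1.vocabulary) & set(m2.vocabulary))
        anchors = AnchorSet(pairs=[(c, c) for c in common])
        before = np.mean([cosine(m1.vector(c), m2.vector(c)) for c in common])
        result = harmonize_pair(m1, m2, anchors)
        after = np.mean(
            [
                cosine(result.reference.vector(c), result.moving.vector(c))
                for c in common
            ]
        )
        assert after > before

    def test_anchor_count_improves_heldout_residual_under_noise(self, rng):
        # median held-out anchor residual is non-increasing in anchor count
        model = EmbeddingModel(
            [f"c{i}" for i in range(150)], rng.standard_normal((150, 10))
        )
        counts = [15, 40, 100]
        medians = []
        for n_anchor in counts:
            residuals = []
            for rep in range(20):
                moved, _ = simulate_transformed_embedding(
                    model, k0=1.5, rotation_seed=rep, noise_sd=0.3
                )
                fit_idx = list(range(n_anchor))
                held_idx = list(range(100, 150))
                t = fit_procrustes(model.matrix[fit_idx], moved.matrix[fit_idx])
                mapped = t.map_moving(moved.matrix[held_idx])
                target = model.matrix[held_idx] - t.mu_X
                residuals.append(
                    float(np.mean(np.linalg.norm(mapped - target, axis=1)))
                )
            medians.append(float(np.median(residuals)))
        assert medians[0] >= medians[1] >= medians[2]


class TestHarmonizeMulti:
    def _three_models(self, rng):
        base = EmbeddingModel(
            [f"c{i}" for i in range(60)], rng.standard_normal((60, 8))
        )
        m1, _ = simulate_transformed_embedding(base, 1.5, rotation_seed=1)
        m2, _ = simulate_transformed_embedding(base, 0.7, rotation_seed=2)
        return base, m1, m2

    def test_three_sites_coincide_on_anchors(self, rng):
        base, m1, m2 = self._three_models(rng)
        anchors = {
            i: AnchorSet(pairs=[(c, c) for c in base.vocabulary]) for i in (1, 2)
        }
        out = harmonize_multi([base, m1, m2], anchors, reference_index=0)
        for j in (1, 2):
            gap = np.max(np.linalg.norm(out[0].matrix - out[j].matrix, axis=1))
            assert gap < 1e-6

    def test_two_models_match_harmonize_pair(self, rng):
        base, m1, _ = self._three_models(rng)
        anchors = AnchorSet(pairs=[(c, c) for c in base.vocabulary])
        pair = harmonize_pair(base, m1, anchors)
        multi = harmonize_multi([base, m1], {1: anchors}, reference_index=0)
        assert np.allclose(multi[0].matrix, pair.reference.matrix, atol=1e-9)
        assert np.allclose(multi[1].matrix, pair.moving.matrix, atol=1e-9)

    def test_reference_index_out_of_range(self, rng):
        base, m1, _ = self._three_models(rng)
        with pytest.raises(ConfigError):
            harmonize_multi([base, m1], {1: AnchorSet(pairs=[("c0", "c0")])}, 5)

    def test_missing_anchor_set_rejected(self, rng):
        base, m1, m2 = self._three_models(rng)
        with pytest.raises(ConfigError):
            harmonize_multi([base, m1, m2], {1: AnchorSet(pairs=[("c0", "c0")])}, 0)


class TestFuseModels:
    def test_anchor_weighted_average(self):
        a = EmbeddingModel(["x", "z"], np.array([[1.0, 0.0], [5.0, 5.0]]))
        b = EmbeddingModel(["x", "w"], np.array([[0.0, 1.0], [-5.0, 5.0]]))
        fused = fuse_models(a, b, AnchorSet(pairs=[("x", "x")]), weight_a=0.8)
        assert np.allclose(fused.vector("x"), [0.8, 0.2])

    def test_anchor_vector_on_segment_between_sites(self, rng):
        a = EmbeddingModel(["x", "y"], rng.standard_normal((2, 4)))
        b = EmbeddingModel(["x", "y"], rng.standard_normal((2, 4)))
        for w in (0.2, 0.5, 0.95):
            fused = fuse_models(a, b, AnchorSet(pairs=[("x", "x"), ("y", "y")]), w)
            v = fused.vector("x")
            # affine combination check: v - vb is parallel to va - vb with ratio w
            assert np.allclose(v - b.vector("x"), w * (a.vector("x") - b.vector("x")))

    def test_single_site_code_averaged_with_nearest_neighbor(self, rng):
        a = EmbeddingModel(
            ["x", "a1", "a2"],
            np.array([[1.0, 0.0], [0.0, 1.0], [0.7, 0.7]]),
        )
        b = EmbeddingModel(["x", "bonly"], np.array([[1.0, 0.0], [0.1, 0.95]]))
        fused = fuse_models(a, b, AnchorSet(pairs=[("x", "x")]), weight_a=0.5)
        # brute-force scan: nearest A-neighbor of bonly by cosine
        from clinalign.embeddings import cosine as cos

        v = b.vector("bonly")
        nn = max(
            ["x", "a1", "a2"], key=lambda c: (cos(a.vector(c), v), c)
        )
        assert nn == "a1"
        assert np.allclose(fused.vector("bonly"), (v + a.vector(nn)) / 2.0)

    def test_union_vocabulary_and_empty_anchor_rejection(self, rng):
        a = EmbeddingModel(["x", "a"], rng.standard_normal((2, 3)))
        b = EmbeddingModel(["x", "b"], rng.standard_normal((2, 3)))
        fused = fuse_models(a, b, AnchorSet(pairs=[("x", "x")]), 0.95)
        assert set(fused.vocabulary) == {"x", "a", "b"}
        with pytest.raises(ConfigError):
            fuse_models(a, b, AnchorSet(pairs=[]), 0.5)
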