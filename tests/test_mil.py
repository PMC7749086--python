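"""Tests for the multiple-instance machinery: patch sampling, bags,
log-map vectorization, the Jensen-Shannon feature map, the
eta-constrained SVM and WAID computation."""

import numpy as np
import pytest
from scipy.stats import chisquare

import waidkit as wk
from waidkit.config import MILConfig
from waidkit.mil import make_negative_pool
from waidkit.spd import matrix_exp

SMALL_MIL = MILConfig(patch_size=32, patches_per_bag=4, n_neg_bags=2)


class TestSamplePatches:
    def test_seed_determinism(self, rng):
        img = rng.integers(0, 256, (80, 80, 3), dtype=np.uint8)
        _, off1 = wk.sample_patches(img, m=10, n=50, seed=7)
        _, off2 = wk.sample_patches(img, m=10, n=50, seed=7)
        np.testing.assert_array_equal(off1, off2)

    def test_exact_size_image_single_placement(self, rng):
        img = rng.integers(0, 256, (50, 50, 3), dtype=np.uint8)
        patches, offsets = wk.sample_patches(img, m=5, n=50, seed=0)
        assert np.all(offsets == 0)
        for p in patches:
            np.testing.assert_array_equal(p, img)

    def test_too_small_image(self, rng):
        img = rng.integers(0, 256, (40, 60, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="smaller"):
            wk.sample_patches(img, m=1, n=50)

    def test_offsets_uniform_over_grid(self, rng):
        # 150x150 image, n=50 -> offsets uniform over {0..100}^2; test the
        # row and column marginals with a chi-square test at alpha = 0.01
        img = rng.integers(0, 256, (150, 150, 3), dtype=np.uint8)
        _, offsets = wk.sample_patches(img, m=5000, n=50, seed=3)
        assert offsets.min() == 0 and offsets.max() == 100
        for axis in (0, 1):
            counts = np.bincount(offsets[:, axis], minlength=101)
            assert chisquare(counts).pvalue > 0.01


class TestNegativeBags:
    def test_noise_bag_reproducible_spd(self):
        b1 = wk.make_negative_bag("noise", m=25, n=50, seed=4)
        b2 = wk.make_negative_bag("noise", m=25, n=50, seed=4)
        assert len(b1.instances) == 25 and b1.label == -1
        for D1, D2 in zip(b1.instances, b2.instances):
            np.testing.assert_array_equal(D1, D2)
            assert D1.shape == (8, 8)
            assert np.linalg.eigvalsh(D1)[0] > 0

    def test_pool_strategies(self):
        pool = wk.texture_pool(3, size=(64, 64), seed=1)
        bag = wk.make_negative_bag("texture", m=4, n=32, seed=0, source_pool=pool)
        assert len(bag.instances) == 4
        with pytest.raises(ValueError, match="source_pool"):
            wk.make_negative_bag("healthy", m=4, n=32, seed=0)
        with pytest.raises(ValueError, match="unknown strategy"):
            wk.make_negative_bag("mnist", m=4, n=32, seed=0)

    def test_noise_far_from_tissue_in_lerm(self):
        # background noise CKDs should sit farther from tissue CKDs than
        # tissue CKDs sit from each other
        noise = wk.make_negative_bag("noise", m=8, n=50, seed=0).instances
        tissue = [
            wk.ckd_from_patch(wk.generate_tile(wk.benign_preset(size=(50, 50), seed=k)))
            .matrix for k in range(8)
        ]
        g = wk.pairwise_gram(noise + tissue).values
        within_noise = g[:8, :8][np.triu_indices(8, 1)].mean()
        within_tissue = g[8:, 8:][np.triu_indices(8, 1)].mean()
        between = g[:8, 8:].mean()
        assert between > max(within_noise, within_tissue)


class TestVectorizeLogm:
    def test_identity_gives_zero_vector(self):
        v = wk.vectorize_logm(np.eye(8))
        assert v.shape == (64,)
        np.testing.assert_allclose(v, 0.0, atol=1e-14)

    def test_scaled_identity_hits_diagonal_positions(self):
        v = wk.vectorize_logm(np.e * np.eye(8))
        expected = np.zeros(64)
        expected[np.arange(8) * 9] = 1.0
        np.testing.assert_allclose(v, expected, atol=1e-12)

    def test_round_trip(self, random_patch):
        D = wk.ckd_from_patch(random_patch)
        v = wk.vectorize_logm(D)
        recon = matrix_exp(v.reshape(8, 8, order="F"))
        np.testing.assert_allclose(recon, D.matrix, atol=1e-8)


class TestJSFeatureMap:
    def test_zero_maps_to_zero(self):
        assert np.all(wk.js_feature_map(np.zeros(64)) == 0.0)

    def test_output_length(self, rng):
        d = rng.normal(size=64)
        for r in (1, 2, 3):
            assert wk.js_feature_map(d, order=r).shape == (64 * 2 * (2 * r + 1),)

    def test_self_kernel_fidelity(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 3, 64)
            approx = float(wk.js_feature_map(x) @ wk.js_feature_map(x))
            exact = wk.js_kernel_exact(x, x)
            assert abs(approx - exact) / exact < 0.02

    def test_signed_split_preserves_inner_products(self, rng):
        # the map on a signed vector equals the sum of JS kernels on the
        # positive and negative parts
        x, y = rng.normal(size=32), rng.normal(size=32)
        approx = float(wk.js_feature_map(x) @ wk.js_feature_map(y))
        exact = (wk.js_kernel_exact(np.maximum(x, 0), np.maximum(y, 0))
                 + wk.js_kernel_exact(np.maximum(-x, 0), np.maximum(-y, 0)))
        assert abs(approx - exact) / max(exact, 1e-12) < 0.05

    def test_error_decreases_with_order(self):
        # at period 0.5 every spectral weight of the map is positive, so
        # adding harmonics strictly refines the approximation (at the 0.6
        # default the order-2 weight vanishes and orders 1 and 2 coincide)
        errs = []
        for r in (1, 2, 3):
            tot = 0.0
            sub = np.random.default_rng(0)
            for _ in range(50):
                x, y = sub.uniform(0.01, 5, 2)
                approx = float(wk.js_feature_map(np.array([x]), order=r, period=0.5)
                               @ wk.js_feature_map(np.array([y]), order=r, period=0.5))
                exact = wk.js_kernel_exact(np.array([x]), np.array([y]))
                tot += abs(approx - exact) / exact
            errs.append(tot / 50)
        assert errs[0] > errs[1] > errs[2]

    def test_order_validation(self):
        with pytest.raises(ValueError, match="order"):
            wk.js_feature_map(np.ones(4), order=0)


def _planted_problem(seed: int, margin: float, dim: int = 10):
    """Stub feature space: a 25-instance positive bag whose first 20
    instances follow the 75-instance background distribution and whose
    last 5 are shifted by `margin` along e1."""
    rng = np.random.default_rng(seed)
    neg = rng.normal(0, 1, (75, dim))
    pos_bg = rng.normal(0, 1, (20, dim))
    planted = rng.normal(0, 1, (5, dim))
    planted[:, 0] += margin
    X = np.vstack([pos_bg, planted, neg])
    from_pos = np.zeros(100, dtype=bool)
    from_pos[:25] = True
    return X, from_pos, set(range(20, 25))


class TestEtaSVM:
    def test_separable_toy_satisfied_at_C0(self, rng):
        pos = np.tile([5.0, 0.0], (20, 1)) + rng.normal(0, 0.1, (20, 2))
        neg = np.tile([-5.0, 0.0], (30, 1)) + rng.normal(0, 0.1, (30, 2))
        X = np.vstack([pos, neg])
        from_pos = np.r_[np.ones(20, bool), np.zeros(30, bool)]
        res = wk.train_eta_svm(X, from_pos, eta=0.9)
        assert res.satisfied
        assert res.C_final == 0.01          # met at the initial C
        assert len(res.positive_set) == 20

    def test_eta_zero_is_vacuous(self, rng):
        X = rng.normal(size=(30, 4))
        from_pos = np.r_[np.ones(10, bool), np.zeros(20, bool)]
        res = wk.train_eta_svm(X, from_pos, eta=0.0)
        assert res.satisfied and res.C_final == 0.01

    def test_planted_recovery_high_margin(self):
        recovered = []
        for seed in range(6):
            X, from_pos, planted = _planted_problem(seed, margin=6.0)
            res = wk.train_eta_svm(X, from_pos, eta=0.15)
            recovered.append(len(planted & set(res.positive_set)) / 5)
        assert np.mean(recovered) >= 0.8

    def test_recovery_degrades_with_margin(self):
        def mean_recovery(margin):
            recs = []
            for seed in range(4):
                X, from_pos, planted = _planted_problem(seed, margin=margin)
                res = wk.train_eta_svm(X, from_pos, eta=0.15)
                recs.append(len(planted & set(res.positive_set)) / 5)
            return np.mean(recs)

        assert mean_recovery(6.0) > mean_recovery(0.5)

    def test_schedule_increases_and_postcondition(self):
        X, from_pos, _ = _planted_problem(1, margin=2.0)
        res = wk.train_eta_svm(X, from_pos, eta=0.15)
        Cs = [c for c, _ in res.history]
        assert all(b > a for a, b in zip(Cs, Cs[1:]))
        if res.satisfied:
            assert len(res.positive_set) / from_pos.sum() >= 0.15

    def test_unsatisfiable_returns_last_solution(self, rng):
        # positives identical to negatives: eta=1 cannot be met
        X = rng.normal(size=(40, 3))
        from_pos = np.r_[np.ones(10, bool), np.zeros(30, bool)]
        res = wk.train_eta_svm(X, from_pos, eta=1.0, C0=1.0, growth=4.0, C_max=16.0)
        assert not res.satisfied
        assert res.C_final <= 16.0
        assert len(res.history) >= 2

    def test_input_validation(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="at least one"):
            wk.train_eta_svm(X, np.ones(10, bool))
        with pytest.raises(ValueError, match="eta"):
            wk.train_eta_svm(X, np.r_[np.ones(5, bool), np.zeros(5, bool)], eta=1.5)


class TestComputeWAID:
    @pytest.fixture(scope="class")
    def tiny_bags(self):
        tile = wk.generate_tile(wk.malignant_preset(size=(64, 64), seed=9))
        pos = wk.make_bag(tile, label=1, m=4, n=32, seed=0, source_id="img")
        negs = [wk.make_negative_bag("noise", m=4, n=32, seed=k,
                                     source_id=f"neg-{k}") for k in range(2)]
        return pos, negs

    def test_deterministic(self, tiny_bags):
        pos, negs = tiny_bags
        w1 = wk.compute_waid(pos, negs, SMALL_MIL)
        w2 = wk.compute_waid(pos, negs, SMALL_MIL)
        np.testing.assert_array_equal(w1.vector, w2.vector)

    def test_length_bookkeeping(self, tiny_bags):
        pos, negs = tiny_bags
        for r in (1, 2):
            cfg = MILConfig(patch_size=32, patches_per_bag=4, n_neg_bags=2, order=r)
            w = wk.compute_waid(pos, negs, cfg)
            assert w.vector.shape == (64 * 2 * (2 * r + 1) + 1,)

    def test_negative_bag_order_invariance(self, tiny_bags):
        pos, negs = tiny_bags
        w1 = wk.compute_waid(pos, negs, SMALL_MIL)
        w2 = wk.compute_waid(pos, negs[::-1], SMALL_MIL)
        np.testing.assert_array_equal(w1.vector, w2.vector)

    def test_label_validation(self, tiny_bags):
        pos, negs = tiny_bags
        with pytest.raises(ValueError, match="label"):
            wk.compute_waid(negs[0], negs[1:], SMALL_MIL)


class TestWaidDataset:
    @pytest.fixture(scope="class")
    def image_set(self):
        images = [wk.generate_tile(wk.benign_preset(size=(64, 64), seed=k))
                  for k in range(2)]
        images += [wk.generate_tile(wk.malignant_preset(size=(64, 64), seed=10 + k))
                   for k in range(2)]
        return images, [-1, -1, 1, 1]

    def test_one_row_per_image(self, image_set):
        images, labels = image_set
        W, y, infos = wk.waid_dataset(images, labels, SMALL_MIL, seed=0)
        assert W.shape == (4, 64 * 2 * 3 + 1)
        np.testing.assert_array_equal(y, labels)
        assert len(infos) == 4

    def test_shuffling_images_permutes_rows(self, image_set):
        images, labels = image_set
        ids = [f"id-{k}" for k in range(4)]
        W1, _, _ = wk.waid_dataset(images, labels, SMALL_MIL, seed=0, image_ids=ids)
        perm = [2, 0, 3, 1]
        W2, _, _ = wk.waid_dataset([images[i] for i in perm],
                                   [labels[i] for i in perm], SMALL_MIL,
                                   seed=0, image_ids=[ids[i] for i in perm])
        np.testing.assert_array_equal(W1[perm], W2)

    def test_shared_negative_pool_is_seed_stable(self):
        p1 = make_negative_pool(SMALL_MIL, master_seed=5)
        p2 = make_negative_pool(SMALL_MIL, master_seed=5)
        for b1, b2 in zip(p1, p2):
            for D1, D2 in zip(b1.instances, b2.instances):
                np.testing.assert_array_equal(D1, D2)
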