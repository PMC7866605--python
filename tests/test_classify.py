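import numpy as np
import pytest

from nirfusion import (
    SpectraSet, pca_fit, pca_scores, simca_fit, simca_distances,
    simca_predict, fld_fit, fld_predict, fld_transform,
)
from conftest import make_set


def labelled(x, labels, m=None):
    x = np.asarray(x, dtype=float)
    return SpectraSet(grid=np.linspace(100, 10, x.shape[1]), intensities=x,
                      labels=tuple(labels), sensor="outer_skin")


class TestPca:
    def test_rank_one_data_fully_explained_by_one_pc(self):
        t = np.linspace(-1, 1, 10)
        direction = np.random.default_rng(0).normal(size=8)
        x = 5.0 + t[:, None] * direction[None, :]
        model = pca_fit(labelled(x, range(10)), k=1)
        np.testing.assert_allclose(model.explained_ratio, [1.0], atol=1e-12)

    def test_full_rank_reconstruction_exact(self):
        x = np.random.default_rng(1).normal(size=(12, 8))
        s = labelled(x, range(12))
        model = pca_fit(s, k=2)
        # isotropic toy in 2 channels embedded: with k=m reconstruction exact
        full = pca_fit(s, k=8)
        rec = full.mean + pca_scores(full, s) @ full.loadings.T
        np.testing.assert_allclose(rec, x, atol=1e-9)
        assert model.explained_ratio[0] >= model.explained_ratio[1]

    def test_matches_covariance_eigendecomposition_oracle(self):
        x = np.random.default_rng(2).normal(size=(20, 6))
        model = pca_fit(labelled(x, range(20)), k=3)
        cov = np.cov(x, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(model.explained_ratio, (w / w.sum())[:3],
                                   atol=1e-10)
        for j in range(3):  # loadings match up to sign
            dot = abs(model.loadings[:, j] @ v[:, j])
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)

    def test_loadings_orthonormal(self):
        model = pca_fit(make_set(n=15, m=10, seed=4), k=5)
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(5), atol=1e-8)

    def test_scores_contract(self):
        s = make_set(n=15, m=10, seed=5)
        model = pca_fit(s, k=4)
        z = pca_scores(model, s)
        # calibration score columns are uncorrelated
        c = np.cov(z, rowvar=False, ddof=1)
        np.testing.assert_allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-8)
        # the mean spectrum scores to the origin
        np.testing.assert_allclose(pca_scores(model, model.mean[None, :]),
                                   0.0, atol=1e-10)
        # manual projection of a random row
        np.testing.assert_allclose(
            z[3], (s.intensities[3] - model.mean) @ model.loadings, atol=1e-12)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            pca_fit(make_set(n=5, m=10), k=5)


def gaussian_classes(seed=0, n_per=12, m=6, centers=((0,) * 6, (4,) * 6, (0, 4, 0, 4, 0, 4))):
    rng = np.random.default_rng(seed)
    xs, labels = [], []
    for ci, c in enumerate(centers):
        xs.append(rng.normal(loc=c, scale=0.5, size=(n_per, m)))
        labels += [ci] * n_per
    return labelled(np.vstack(xs), labels)


class TestSimca:
    def test_residual_scales_match_bruteforce_oracle(self):
        s = gaussian_classes(seed=3)
        model = simca_fit(s, k_per_class=2)
        x = s.intensities
        for c, (pca, s0sq) in model.class_models.items():
            rows = x[np.array([lab == c for lab in s.labels])]
            xc = rows - rows.mean(axis=0)
            # explicit projection residual
            proj = xc @ pca.loadings @ pca.loadings.T
            rss = np.sum((xc - proj) ** 2)
            n_c, m = rows.shape
            np.testing.assert_allclose(s0sq, rss / ((n_c - 3) * (m - 2)),
                                       rtol=1e-10)

    def test_distances_match_explicit_residuals(self):
        s = gaussian_classes(seed=4, m=3, centers=((0, 0, 0), (5, 5, 5)))
        model = simca_fit(s, k_per_class=1)
        probe = s.subset([0, 13, 20])
        d = simca_distances(model, probe)
        for j, (_, (pca, s0sq)) in enumerate(model.class_models.items()):
            xc = probe.intensities - pca.mean
            resid = xc - (xc @ pca.loadings) @ pca.loadings.T
            expected = np.sum(resid**2, axis=1) / (3 - 1) / s0sq
            np.testing.assert_allclose(d[:, j], expected, rtol=1e-10)

    def test_separable_classes_classified_perfectly(self):
        train = gaussian_classes(seed=5, m=4, centers=((0,) * 4, (10,) * 4))
        test = gaussian_classes(seed=6, m=4, centers=((0,) * 4, (10,) * 4))
        model = simca_fit(train, k_per_class=1)
        pred, dist = simca_predict(model, test)
        assert pred == list(test.labels)
        assert dist.shape == (test.n, 2)

    def test_training_centroid_assigned_to_own_class(self):
        s = gaussian_classes(seed=7)
        model = simca_fit(s, k_per_class=2)
        for c, (pca, _) in model.class_models.items():
            pred, _ = simca_predict(model, pca.mean[None, :])
            assert pred == [c]

    def test_duplicated_rows_trigger_residual_floor(self):
        row = np.random.default_rng(8).normal(size=6)
        x = np.vstack([row] * 5 + [row + 3] * 5)
        s = labelled(x, [0] * 5 + [1] * 5)
        model = simca_fit(s, k_per_class=1)
        for _, (_, s0sq) in model.class_models.items():
            assert s0sq >= 1e-12

    def test_single_class_fit_equals_plain_pca(self):
        s = gaussian_classes(seed=9, centers=((0, 1, 2, 3, 4, 5),))
        model = simca_fit(s, k_per_class=2)
        (pca, _), = model.class_models.values()
        ref = pca_fit(s, k=2)
        np.testing.assert_allclose(pca.loadings, ref.loadings, atol=1e-9)

    def test_too_small_class_rejected(self):
        s = labelled(np.random.default_rng(0).normal(size=(4, 6)), [0, 0, 1, 1])
        with pytest.raises(ValueError, match="needs >="):
            simca_fit(s, k_per_class=2)


class TestFld:
    def test_two_separated_1d_classes(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 0.5, 20), rng.normal(10, 0.5, 20)][:, None]
        model = fld_fit(x, [0] * 20 + [1] * 20, r=1)
        assert abs(abs(model.directions[0, 0]) - 1.0) < 1e-12
        assert abs(model.centroids[0][0]) < 1.0
        assert abs(model.centroids[1][0] - 10 * model.directions[0, 0]) < 1.0

    def test_class_identical_data_rejected(self):
        x = np.tile(np.random.default_rng(1).normal(size=(10, 3)), (2, 1))
        with pytest.raises(ValueError, match="no discriminative signal"):
            fld_fit(x, [0] * 10 + [1] * 10)

    def test_beats_random_projections_on_fisher_criterion(self):
        rng = np.random.default_rng(2)
        centers = [(0, 0, 0, 0), (2, 0, 1, 0), (0, 2, 0, 1)]
        x = np.vstack([rng.normal(c, 1.0, size=(15, 4)) for c in centers])
        labels = [0] * 15 + [1] * 15 + [2] * 15

        def fisher(w):
            mu = x.mean(axis=0)
            sb = sw = 0.0
            for c in range(3):
                rows = x[np.array(labels) == c]
                mc = rows.mean(axis=0)
                sb += len(rows) * ((mc - mu) @ w) ** 2
                sw += np.sum(((rows - mc) @ w) ** 2)
            return sb / sw

        model = fld_fit(x, labels, r=1)
        ours = fisher(model.directions[:, 0])
        randoms = rng.normal(size=(1000, 4))
        randoms /= np.linalg.norm(randoms, axis=1, keepdims=True)
        assert all(ours >= fisher(w) - 1e-12 for w in randoms)

    def test_agrees_with_sklearn_lda_direction(self):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal((0, 0), 1, (30, 2)),
                       rng.normal((3, 1), 1, (30, 2))])
        labels = [0] * 30 + [1] * 30
        model = fld_fit(x, labels, r=1)
        lda = sk.LinearDiscriminantAnalysis(solver="eigen").fit(x, labels)
        w_sk = lda.coef_[0] / np.linalg.norm(lda.coef_[0])
        cos = abs(w_sk @ model.directions[:, 0])
        assert cos > 1 - 1e-6

    def test_affine_invariance_of_separation(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal((0, 0, 0), 1, (20, 3)),
                       rng.normal((4, 2, 1), 1, (20, 3))])
        labels = [0] * 20 + [1] * 20
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        pred1 = fld_predict(fld_fit(x, labels, r=1), x)
        xt = x @ a.T + 5.0
        pred2 = fld_predict(fld_fit(xt, labels, r=1), xt)
        assert pred1 == pred2

    def test_nearest_centroid_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        centers = [(0, 0, 0, 0), (3, 0, 2, 0), (0, 3, 0, 2)]
        x = np.vstack([rng.normal(c, 0.8, size=(10, 4)) for c in centers])
        labels = [0] * 10 + [1] * 10 + [2] * 10
        model = fld_fit(x, labels, r=2)
        probe = rng.normal(size=(25, 4))
        pred = fld_predict(model, probe)
        z = fld_transform(model, probe)
        for i in range(25):
            dists = {c: np.linalg.norm(z[i] - model.centroids[c])
                     for c in model.classes}
            assert pred[i] == min(model.classes, key=lambda c: dists[c])

    def test_centroid_and_midpoint_tie_rule(self):
        from nirfusion import FldModel
        model = FldModel(directions=np.array([[1.0]]),
                         centroids={0: np.array([-1.0]), 1: np.array([1.0])})
        assert fld_predict(model, np.array([[-1.0]])) == [0]
        assert fld_predict(model, np.array([[1.0]])) == [1]
        assert fld_predict(model, np.array([[0.0]])) == [0]  # tie -> first class

    def test_singleton_class_and_bad_r_rejected(self):
        x = np.random.default_rng(8).normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            fld_fit(x, [0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            fld_fit(x, [0, 0, 0, 1, 1], r=2)


def test_thirty_pcs_explain_99_percent_on_default_data(default_data,
                                                       default_partition):
    """At study scale, 30 PCs capture ~99% of the calibration variance."""
    outer, inner = default_data
    cal_idx = list(default_partition.cal_indices)
    for s in (outer, inner):
        model = pca_fit(s.subset(cal_idx), k=30)
        assert model.explained_ratio.sum() >= 0.99
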