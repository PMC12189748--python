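"""Metric suite against brute-force oracles and constructed fixtures."""

import numpy as np
import pytest

import gexgan as gg
from gexgan.core_io import ValidationError
from gexgan.evaluation import manifold_radii, wasserstein_1d


def brute_force_precision_recall(real, syn, t):
    """Exhaustive double-loop sphere-membership oracle."""

    def radii(points):
        out = []
        for i, p in enumerate(points):
            d = np.sort([np.linalg.norm(p - q) for j, q in enumerate(points)])
            out.append(d[t])  # d[0] == 0 (self)
        return np.asarray(out)

    def covered(queries, reference, ref_radii):
        flags = []
        for q in queries:
            flags.append(any(np.linalg.norm(q - p) <= r + 1e-12
                             for p, r in zip(reference, ref_radii)))
        return np.asarray(flags)

    rr, rs = radii(real), radii(syn)
    return covered(syn, real, rr).mean(), covered(real, syn, rs).mean()


class TestPrecisionRecall:
    def test_identical_sets_are_perfect(self, rng):
        X = rng.normal(size=(15, 4))
        p, r = gg.precision_recall(X, X.copy(), t=3)
        assert (p, r) == (1.0, 1.0)

    def test_one_dimensional_hand_example(self):
        real = np.array([[0.0], [10.0]])
        syn = np.array([[1.0], [2.0]])
        p, r = gg.precision_recall(real, syn, t=1)
        assert p == 1.0  # both 1 and 2 are within 10 of 0
        assert r == 0.5  # 0 is within 1 of syn point 1; 10 is 8 away

    def test_constant_generator_mode_collapse_signature(self, rng):
        mode_a = rng.normal(0.0, 0.05, size=(30, 5))
        mode_b = rng.normal(5.0, 0.05, size=(30, 5))
        real = np.vstack([mode_a, mode_b])
        syn = np.tile(mode_a[0], (40, 1))  # constant vector inside the real manifold
        p, r = gg.precision_recall(real, syn, t=10)
        assert p == 1.0
        assert r <= 0.05

    @pytest.mark.parametrize("n_real,n_syn,dim,t", [(12, 9, 3, 2), (25, 30, 2, 5), (50, 40, 6, 10)])
    def test_matches_exhaustive_oracle(self, rng, n_real, n_syn, dim, t):
        real = rng.normal(size=(n_real, dim))
        syn = rng.normal(loc=0.5, size=(n_syn, dim))
        expected = brute_force_precision_recall(real, syn, t)
        assert gg.precision_recall(real, syn, t) == pytest.approx(expected)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValidationError, match="11"):
            gg.precision_recall(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), t=10)

    def test_radii_are_tth_neighbor_distances(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        np.testing.assert_allclose(manifold_radii(pts, t=1), [1.0, 1.0, 2.0])
        np.testing.assert_allclose(manifold_radii(pts, t=2), [3.0, 2.0, 3.0])


class TestCorrelationCoefficient:
    def test_row_permutation_preserves_structure(self, rng):
        X = rng.normal(size=(40, 6))
        X[:, 1] = X[:, 0] * 0.9 + rng.normal(scale=0.3, size=40)
        perm = rng.permutation(40)
        assert gg.correlation_coefficient(X, X[perm]) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one_for_single_pair(self, rng):
        a = rng.normal(size=50)
        b = 0.9 * a + rng.normal(scale=0.2, size=50)
        X = np.column_stack([a, b])
        Y = np.column_stack([a, -b])  # corr 0.9 -> -0.9: anti-structure
        assert gg.correlation_coefficient(X, Y) == pytest.approx(-1.0)

    def test_four_gene_fixture_matches_upper_triangle_loop(self, rng):
        A = rng.normal(size=(30, 4))
        B = rng.normal(size=(25, 4))
        ca = np.corrcoef(A, rowvar=False)
        cb = np.corrcoef(B, rowvar=False)
        pairs = [(i, j) for i in range(3) for j in range(i + 1, 4)]
        va = np.array([ca[i, j] for i, j in pairs])
        vb = np.array([cb[i, j] for i, j in pairs])
        za = (va - va.mean()) / va.std()
        zb = (vb - vb.mean()) / vb.std()
        expected = np.mean(za * zb)
        assert gg.correlation_coefficient(A, B) == pytest.approx(expected)

    def test_symmetry_and_self_correlation(self, rng):
        A = rng.normal(size=(20, 5))
        B = rng.normal(size=(22, 5))
        assert gg.correlation_coefficient(A, B) == pytest.approx(
            gg.correlation_coefficient(B, A))
        assert gg.correlation_coefficient(A, A) == pytest.approx(1.0)

    def test_constant_genes_warn_and_drop(self, rng):
        A = rng.normal(size=(20, 3))
        A[:, 2] = 7.0
        B = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="constant"):
            value = gg.correlation_coefficient(A, B)
        assert -1.0 <= value <= 1.0


class TestDetectability:
    def test_shifted_synthetic_is_perfectly_detectable(self, rng):
        real = rng.normal(size=(120, 5))
        syn = real + 100.0  # 100 sd away in every gene
        scores = gg.detectability(real, syn, classifiers=("logistic_regression",), n_runs=3)
        assert scores["logistic_regression"] >= 0.99

    def test_row_order_invariance(self, rng):
        real = rng.normal(size=(60, 4))
        syn = rng.normal(loc=0.3, size=(60, 4))
        a = gg.detectability(real, syn, classifiers=("logistic_regression",), n_runs=3)
        b = gg.detectability(real[::-1], syn[rng.permutation(60)],
                             classifiers=("logistic_regression",), n_runs=3)
        assert a["logistic_regression"] == pytest.approx(b["logistic_regression"])

    def test_pc_space_runs_with_few_components(self, rng):
        real = rng.normal(size=(50, 8))
        syn = rng.normal(size=(50, 8))
        scores = gg.detectability(real, syn, classifiers=("logistic_regression",),
                                  space="pc", n_runs=2)
        assert 0.0 <= scores["logistic_regression"] <= 1.0


class TestTSTR:
    def test_identity_substitution_equals_train_on_real(self, rng):
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] > 0).astype(str)
        X_test = rng.normal(size=(40, 4))
        y_test = (X_test[:, 0] > 0).astype(str)
        via_tstr = gg.tstr(X, y, X_test, y_test, classifiers=("logistic_regression",), seed=3)
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import balanced_accuracy_score
        clf = LogisticRegression(max_iter=2000, C=1.0, random_state=3).fit(X, y)
        expected = balanced_accuracy_score(y_test, clf.predict(X_test))
        assert via_tstr["logistic_regression"]["balanced_accuracy"] == pytest.approx(expected)

    def test_shuffled_labels_fall_to_chance(self, rng):
        K = 4
        X = rng.normal(size=(400, 6))
        y = rng.integers(0, K, size=400).astype(str)
        X_test = rng.normal(size=(1000, 6))
        y_test = rng.integers(0, K, size=1000).astype(str)
        out = gg.tstr(X, y, X_test, y_test, classifiers=("logistic_regression",), seed=0)
        acc = out["logistic_regression"]["balanced_accuracy"]
        assert abs(acc - 1.0 / K) < 0.06  # binomial noise at n=1000

    def test_single_class_synthetic_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValidationError, match="single class"):
            gg.tstr(X, ["a"] * 20, X, ["a"] * 20)

    def test_missing_classes_reported(self, rng):
        X = rng.normal(size=(30, 3))
        y = ["a", "b"] * 15
        X_test = rng.normal(size=(10, 3))
        y_test = ["a", "b", "c", "a", "b", "c", "a", "b", "c", "a"]
        out = gg.tstr(X, y, X_test, y_test, classifiers=("logistic_regression",))
        assert out["missing_classes"] == ["c"]


class TestKS:
    def test_identical_matrices_have_zero_statistics(self, rng):
        X = rng.normal(size=(30, 4))
        out = gg.ks_per_gene(X, X.copy())
        np.testing.assert_array_equal(out["statistic"], np.zeros(4))

    def test_disjoint_supports_have_statistic_one(self, rng):
        real = -np.abs(rng.normal(size=(20, 2))) - 0.1
        syn = np.abs(rng.normal(size=(25, 2))) + 0.1
        out = gg.ks_per_gene(real, syn)
        np.testing.assert_array_equal(out["statistic"], np.ones(2))

    def test_statistic_matches_ecdf_gap_loop(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.4, size=30)
        out = gg.ks_per_gene(a[:, None], b[:, None])
        grid = np.concatenate([a, b])
        gaps = [abs((a <= x).mean() - (b <= x).mean()) for x in grid]
        assert out["statistic"][0] == pytest.approx(max(gaps))

    def test_statistic_monotone_under_location_shift(self, rng):
        a = rng.normal(size=(60, 1))
        stats = [gg.ks_per_gene(a, a + shift)["statistic"][0] for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(x <= y + 1e-12 for x, y in zip(stats, stats[1:]))

    def test_bh_adjustment_is_monotone_in_p(self, rng):
        real = rng.normal(size=(40, 6))
        syn = rng.normal(loc=0.3, size=(40, 6))
        out = gg.ks_per_gene(real, syn)
        order = np.argsort(out["pvalue"])
        adj = out["pvalue_adjusted"][order]
        assert all(x <= y + 1e-12 for x, y in zip(adj, adj[1:]))
        assert np.all(out["pvalue_adjusted"] >= out["pvalue"] - 1e-12)


class TestWasserstein:
    def test_identical_matrices_give_zero(self, rng):
        X = rng.normal(size=(15, 3))
        assert gg.mean_gene_wasserstein(X, X.copy()) == 0.0

    def test_point_mass_translation(self):
        real = np.zeros((4, 1))
        syn = np.full((6, 1), 3.0)
        assert gg.mean_gene_wasserstein(real, syn, order=2) == pytest.approx(3.0)

    def test_equal_size_samples_match_sorted_quantile_oracle(self, rng):
        u = rng.normal(size=5)
        v = rng.normal(size=5)
        expected = (np.mean(np.abs(np.sort(u) - np.sort(v)) ** 2)) ** 0.5
        assert wasserstein_1d(u, v, 2) == pytest.approx(expected)

    def test_unequal_sizes_match_scipy_order_one(self, rng):
        from scipy.stats import wasserstein_distance
        u = rng.normal(size=7)
        v = rng.normal(size=11)
        assert wasserstein_1d(u, v, order=1) == pytest.approx(wasserstein_distance(u, v))

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(10):
            u, v, w = (rng.normal(size=rng.integers(3, 9)) for _ in range(3))
            duv = wasserstein_1d(u, v)
            duw = wasserstein_1d(u, w)
            dwv = wasserstein_1d(w, v)
            assert duv <= duw + dwv + 1e-9
            assert wasserstein_1d(u, u) == 0.0


class TestEvaluateAll:
    def test_report_populated_and_deterministic(self, rng):
        real = rng.normal(size=(60, 5))
        syn = rng.normal(loc=0.1, size=(60, 5))
        kwargs = dict(n_runs=2, seed=7, classifiers=("logistic_regression",))
        a = gg.evaluate_all(real, syn, **kwargs)
        b = gg.evaluate_all(real, syn, **kwargs)
        assert 0 <= a.precision <= 1 and 0 <= a.recall <= 1
        assert -1 <= a.correlation_coefficient <= 1
        assert a.to_json() == b.to_json()

    def test_missing_synthetic_covariates_skip_only_tstr(self, rng, tiny_bundle):
        real = rng.normal(size=(40, 4))
        syn = rng.normal(size=(40, 4))
        report = gg.evaluate_all(real, syn, C_real=tiny_bundle.C, C_syn=None,
                                 label_covariate="condition", n_runs=2,
                                 classifiers=("logistic_regression",))
        assert report.tstr == {"skipped": "synthetic or real covariates not provided"}
        assert report.mean_gene_wasserstein >= 0
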