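import numpy as np
import pytest
import scipy.linalg
import scipy.stats
from sklearn.decomposition import PCA as SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import seedspectra as ss
from seedspectra.discriminant import ConfusionMatrix
from seedspectra.exceptions import CrossValidationError, FitError, ParameterError


class TestPCA:
    def test_rank_one_data_explains_everything_on_pc1(self):
        rng = np.random.default_rng(0)
        direction = rng.uniform(-1, 1, 8)
        X = np.outer(rng.normal(size=30), direction)
        res = ss.pca_fit(X, k=4)
        assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-9)
        assert np.abs(res.explained_variance_pct[1:]).max() < 1e-9

    def test_centring_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        shift = rng.uniform(-5, 5, 6)
        a = ss.pca_fit(X).explained_variance_pct
        b = ss.pca_fit(X + shift).explained_variance_pct
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_eigenvalues_match_dense_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 20))
        res = ss.pca_fit(X)
        # oracle: explicit covariance accumulation + dense eigensolver
        mu = X.mean(axis=0)
        C = np.zeros((20, 20))
        for row in X:
            d = row - mu
            C += np.outer(d, d)
        C /= 49
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(res.eigenvalues, evals[: len(res.eigenvalues)], atol=1e-8)
        np.testing.assert_allclose(
            res.explained_variance_pct, 100 * evals[: len(res.eigenvalues)] / evals.sum(), atol=1e-8
        )

    def test_agrees_with_sklearn_pca(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        res = ss.pca_fit(X, k=5)
        sk = SkPCA(n_components=5).fit(X)
        np.testing.assert_allclose(
            res.explained_variance_pct, 100 * sk.explained_variance_ratio_, atol=1e-10
        )

    def test_loadings_are_orthonormal_and_pct_sums_to_100(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 12))
        res = ss.pca_fit(X)
        gram = res.component_loadings.T @ res.component_loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert res.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(res.explained_variance_pct) <= 1e-12).all()

    def test_k_out_of_range_is_a_parameter_error(self):
        with pytest.raises(ParameterError):
            ss.pca_fit(np.zeros((5, 3)), k=5)


class TestLdaFit:
    def test_centroids_equal_cluster_means(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.01, (10, 4))
        b = 10 + rng.normal(0, 0.01, (10, 4))
        res = ss.lda_fit(np.vstack([a, b]), np.repeat([0, 1], 10))
        np.testing.assert_allclose(res.centroids[0], a.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(res.centroids[1], b.mean(axis=0), atol=1e-12)

    def test_pooled_covariance_matches_textbook_scatter_oracle(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y, regularization_lambda=0.0)
        # oracle: term-by-term pooled within-class scatter / (n - K)
        S = np.zeros((5, 5))
        for k in range(3):
            mk = X[y == k].mean(axis=0)
            for row in X[y == k]:
                d = row - mk
                S += np.outer(d, d)
        np.testing.assert_allclose(res.pooled_covariance, S / (60 - 3), atol=1e-10)

    def test_label_name_permutation_leaves_assignments_invariant(self, gaussian_fixture):
        X, y = gaussian_fixture
        res_a = ss.lda_fit(X, y, class_names=["c0", "c1", "c2"])
        res_b = ss.lda_fit(X, (2 - y), class_names=["c2", "c1", "c0"])
        names_a = [res_a.class_names[i] for i in res_a.predict(X)[0]]
        names_b = [res_b.class_names[i] for i in res_b.predict(X)[0]]
        assert names_a == names_b

    def test_priors_sum_to_one_and_follow_mode(self, gaussian_fixture):
        X, y = gaussian_fixture
        prop = ss.lda_fit(X, y, prior_mode="proportional")
        eq = ss.lda_fit(X, y, prior_mode="equal")
        np.testing.assert_allclose(prop.priors, [1 / 3] * 3)
        np.testing.assert_allclose(eq.priors, [1 / 3] * 3)
        assert prop.priors.sum() == pytest.approx(1.0)

    def test_tiny_class_is_a_fit_error(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(FitError):
            ss.lda_fit(X, np.array([0, 0, 0, 0, 1]))

    def test_regularization_keeps_singular_covariance_invertible(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(12, 1))
        X = np.hstack([base, base, base])  # rank-deficient bands
        y = np.repeat([0, 1], 6)
        with pytest.raises(FitError):
            ss.lda_fit(X, y, regularization_lambda=0.0)
        res = ss.lda_fit(X, y, regularization_lambda=1e-6)
        assert np.isfinite(res.precision).all()


class TestLdaPredict:
    def test_midpoint_has_symmetric_posteriors(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (15, 3))
        b = rng.normal(0, 1, (15, 3)) + 4
        res = ss.lda_fit(np.vstack([a, b]), np.repeat([0, 1], 15), prior_mode="equal")
        mid = (res.centroids[0] + res.centroids[1]) / 2
        _, p, _ = res.predict(mid)
        np.testing.assert_allclose(p[0], [0.5, 0.5], atol=1e-12)

    def test_centroid_classifies_to_its_own_class(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y, prior_mode="equal")
        a, _, d = res.predict(res.centroids)
        np.testing.assert_array_equal(a, [0, 1, 2])
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-10)

    def test_posteriors_match_gaussian_density_oracle(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(1.5, 1, (20, 4))])
        y = np.repeat([0, 1], 20)
        res = ss.lda_fit(X, y, regularization_lambda=0.0)
        # oracle: full Gaussian densities with the pooled covariance, normalised
        dens = np.vstack(
            [
                res.priors[k]
                * scipy.stats.multivariate_normal.pdf(
                    X, mean=res.centroids[k], cov=res.pooled_covariance
                )
                for k in range(2)
            ]
        ).T
        oracle = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(res.posteriors(X), oracle, atol=1e-12)

    def test_matches_sklearn_lda_end_to_end(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y, regularization_lambda=0.0)
        sk = LinearDiscriminantAnalysis().fit(X, y)
        np.testing.assert_array_equal(res.predict(X)[0], sk.predict(X))
        np.testing.assert_allclose(res.posteriors(X), sk.predict_proba(X), atol=1e-9)

    def test_posterior_rows_sum_to_one(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y)
        np.testing.assert_allclose(res.posteriors(X).sum(axis=1), 1.0, atol=1e-9)

    def test_two_class_argmax_equals_half_posterior_rule(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(1, 1, (20, 5))])
        y = np.repeat([0, 1], 20)
        res = ss.lda_fit(X, y)
        a, p, _ = res.predict(X)
        np.testing.assert_array_equal(a == 1, p[:, 1] > 0.5)

    def test_joint_scaling_invariance_under_equal_priors(self, gaussian_fixture):
        X, y = gaussian_fixture
        a1 = ss.lda_fit(X, y, prior_mode="equal").predict(X)[0]
        a2 = ss.lda_fit(X * 37.0, y, prior_mode="equal").predict(X * 37.0)[0]
        np.testing.assert_array_equal(a1, a2)

    def test_band_mismatch_is_a_validation_error(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y)
        with pytest.raises(Exception, match="bands"):
            res.predict(X[:, :3])


class TestLoocv:
    def test_separable_clusters_classify_perfectly(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 0.2, (10, 4)), rng.normal(5, 0.2, (10, 4))])
        rep = ss.loocv(X, np.repeat([0, 1], 10))
        assert rep.overall_correct_pct == 100.0

    def test_confusion_row_sums_equal_class_counts(self, gaussian_fixture):
        X, y = gaussian_fixture
        rep = ss.loocv(X, y)
        np.testing.assert_array_equal(rep.confusion.counts.sum(axis=1), [20, 20, 20])

    def test_confusion_identical_to_naive_refit_oracle(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(2, 1, (15, 4))])
        y = np.repeat([0, 1], 15)
        rep = ss.loocv(X, y, regularization_lambda=0.0)
        # oracle: literally refit 30 independent (sklearn) models
        verdicts = []
        for i in range(30):
            keep = np.ones(30, dtype=bool)
            keep[i] = False
            sk = LinearDiscriminantAnalysis().fit(X[keep], y[keep])
            verdicts.append(int(sk.predict(X[i : i + 1])[0]))
        oracle = np.zeros((2, 2), dtype=int)
        for t, v in zip(y, verdicts):
            oracle[t, v] += 1
        np.testing.assert_array_equal(rep.confusion.counts, oracle)

    def test_class_below_three_members_is_a_cross_validation_error(self):
        X = np.random.default_rng(12).normal(size=(12, 3))
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(CrossValidationError):
            ss.loocv(X, y)


class TestScoreReport:
    @pytest.mark.parametrize(
        "counts, per_class, overall",
        [
            # two-class ageing model, training set
            ([[72, 9], [1, 319]], [88.89, 99.69], 97.51),
            # two-class ageing model, validation set
            ([[16, 3], [0, 81]], [84.21, 100.00], 97.00),
            # germination model: training, cross-validation, validation
            ([[267, 21], [52, 61]], [92.71, 53.98], 81.80),
            ([[259, 29], [55, 58]], [89.93, 51.33], 79.05),
            ([[71, 5], [14, 10]], [93.42, 41.67], 81.00),
            # seedling-condition model
            ([[130, 65], [63, 143]], [66.67, 69.42], 68.08),
            ([[124, 71], [72, 134]], [63.59, 65.05], 64.34),
            ([[26, 16], [22, 36]], [61.90, 62.07], 62.00),
            # germination-speed model (Early/Medium/Dead)
            ([[72, 16, 2], [2, 137, 28], [2, 30, 62]], [80.00, 82.04, 65.96], 77.21),
            ([[70, 18, 2], [3, 135, 29], [2, 34, 58]], [77.78, 80.84, 61.70], 74.93),
            ([[22, 2, 0], [2, 29, 11], [1, 16, 17]], [91.67, 69.05, 50.00], 68.00),
            # five-class ageing model, training set
            (
                [[75, 3, 3, 0, 1], [1, 77, 3, 0, 0], [0, 0, 57, 3, 12],
                 [0, 1, 7, 71, 6], [0, 0, 9, 6, 66]],
                [91.46, 95.06, 79.17, 83.53, 81.48],
                86.28,
            ),
        ],
    )
    def test_reproduces_published_report_tables(self, counts, per_class, overall):
        """Correct-classification percentages from confusion counts, to 2 decimals."""
        k = len(counts)
        cm = ConfusionMatrix(np.array(counts), tuple(f"c{i}" for i in range(k)))
        pc, occ = ss.score_report(cm)
        assert ss.round_half_up(occ) == pytest.approx(overall)
        for got, want in zip(pc, per_class):
            assert ss.round_half_up(got) == pytest.approx(want)

    def test_diagonal_matrix_scores_100_everywhere(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), ("a", "b", "c"))
        pc, occ = ss.score_report(cm)
        assert occ == 100.0
        np.testing.assert_array_equal(pc, [100.0, 100.0, 100.0])

    def test_empty_class_row_reports_nan(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ("a", "b"))
        pc, _ = ss.score_report(cm)
        assert np.isnan(pc[1])

    def test_display_rounding_is_half_up(self):
        assert ss.round_half_up(81.795) == 81.80
        assert ss.round_half_up(53.985) == 53.99


class TestDiscriminantFactors:
    def test_collinear_centroids_give_zero_second_factor(self):
        rng = np.random.default_rng(13)
        noise = rng.normal(0, 0.5, (60, 4))
        shift = np.array([1.0, 2.0, -1.0, 0.5])
        X = noise + np.repeat([0.0, 5.0, 10.0], 20)[:, None] * shift
        # force exactly collinear centroids
        res = ss.lda_fit(X - np.vstack([X[k * 20:(k + 1) * 20].mean(0) - s * shift
                                        for k, s in enumerate((0.0, 5.0, 10.0))
                                        for _ in range(20)]),
                         np.repeat([0, 1, 2], 20))
        _, pct = res.discriminant_scores(X, n_factors=2)
        assert pct[1] == pytest.approx(0.0, abs=1e-8)

    def test_explained_shares_sum_to_100_over_k_minus_1_factors(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y)
        _, pct, _ = res.discriminant_factors(n_factors=2)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_projections_match_generalized_eigenproblem_oracle(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y, regularization_lambda=0.0)
        scores, _ = res.discriminant_scores(X, n_factors=2)
        # oracle: explicit Sw^-1 Sb eigendecomposition
        counts = np.array([20, 20, 20])
        mu = X.mean(axis=0)
        sb = sum(
            counts[k] * np.outer(res.centroids[k] - mu, res.centroids[k] - mu)
            for k in range(3)
        ) / 59
        evals, evecs = np.linalg.eig(np.linalg.inv(res.pooled_covariance) @ sb)
        order = np.argsort(evals.real)[::-1]
        vecs = evecs[:, order[:2]].real
        # normalise both to v^T Sw v = 1 and compare up to sign
        for j in range(2):
            v = vecs[:, j]
            vecs[:, j] = v / np.sqrt(v @ res.pooled_covariance @ v)
        oracle = (X - mu) @ vecs
        for j in range(2):
            np.testing.assert_allclose(
                np.abs(scores[:, j]), np.abs(oracle[:, j]), atol=1e-8
            )

    def test_two_classes_yield_a_single_factor_with_warning(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (10, 3))])
        res = ss.lda_fit(X, np.repeat([0, 1], 10))
        with pytest.warns(UserWarning, match="one discriminant factor"):
            scores, pct = res.discriminant_scores(X, n_factors=2)
        assert scores.shape == (20, 1)
        assert pct[0] == pytest.approx(100.0)


class TestParameterRecovery:
    def test_well_separated_ageing_profiles_recover_at_least_95pct(self):
        """Two-class lot whose profile separation is >= 5 seed-level SDs."""
        profs = ss.make_ageing_profiles(ss.default_seed_profile(), vis_drop_per_24h=0.02)
        m0 = np.asarray(profs["Non-aged"].mean_reflectance)
        m1 = np.asarray(profs["AA96"].mean_reflectance)
        sd = 0.01
        # design condition: 4 x per-24h visible drop >= 5 x seed-level SD
        assert 4 * 0.02 >= 5 * sd
        rng = np.random.default_rng(0)
        X = np.vstack(
            [m0 + rng.normal(0, sd, (100, 20)), m1 + rng.normal(0, sd, (100, 20))]
        )
        rep = ss.loocv(X, np.repeat([0, 1], 100))
        assert rep.overall_correct_pct >= 95.0

    def test_identical_profiles_score_at_chance_level(self):
        """With no class signal, LOOCV accuracy sits inside the binomial 99% band."""
        m0 = np.asarray(ss.default_seed_profile().mean_reflectance)
        rng = np.random.default_rng(0)
        X = m0 + rng.normal(0, 0.01, (200, 20))
        rep = ss.loocv(X, np.repeat([0, 1], 100))
        p, n = 0.5, 200
        half_width = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(rep.overall_correct_pct / 100 - p) <= half_width


class TestSummaries:
    def test_report_summary_prints_counts_and_occ(self, gaussian_fixture):
        X, y = gaussian_fixture
        res = ss.lda_fit(X, y)
        text = res.score(X, y).summary()
        assert "Overall correct classification" in text
        assert res.summary().startswith("Linear discriminant model")
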