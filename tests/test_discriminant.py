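"""Fisher discriminant analysis, its diagnostics, and leave-one-out CV."""

import warnings

import numpy as np
import pytest

import pulsedx as px
from pulsedx.discriminant import (FisherDiscriminant, box_m, fisher_lda, loocv,
                                  wilks_lambda)


def _two_gaussians(rng, n_per_class, shift, p=2, cov=None):
    cov = np.eye(p) if cov is None else cov
    Xd = rng.multivariate_normal(np.zeros(p), cov, size=n_per_class)
    Xe = rng.multivariate_normal(np.asarray(shift), cov, size=n_per_class)
    X = np.vstack([Xd, Xe])
    y = ["deficient"] * n_per_class + ["excess"] * n_per_class
    return X, y


class TestFisherLDA:
    def test_univariate_reduces_to_weighted_midpoint_threshold(self):
        x = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0], [10.0]])
        y = ["deficient"] * 3 + ["excess"] * 4
        res = fisher_lda(x, y)
        # size-weighted cutoff between the class means, on the feature scale
        mu_d, mu_e = 2.0, 8.5
        cutoff_x = (4 * mu_d + 3 * mu_e) / 7
        expected = ["excess" if v >= cutoff_x else "deficient" for v in x.ravel()]
        assert res.predict() == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_training_accuracy_near_brute_force_projection_search(self, seed):
        """On tiny two-feature cohorts, the discriminant's training accuracy
        matches an exhaustive search over 360 projection directions × all
        thresholds, within one tied subject."""
        rng = np.random.default_rng(seed)
        X, y = _two_gaussians(rng, 4, shift=[2.5, 2.0])
        res = fisher_lda(X, y)
        n_correct = int(8 * px.accuracy(res.training_table()))
        best = 0
        yd = np.asarray(y) == "deficient"
        for theta in np.linspace(0, np.pi, 360, endpoint=False):
            proj = X @ np.array([np.cos(theta), np.sin(theta)])
            order = np.sort(proj)
            cuts = np.concatenate(([-np.inf], (order[:-1] + order[1:]) / 2,
                                   [np.inf]))
            for c in cuts:
                hi = proj >= c
                best = max(best,
                           int(np.sum(hi & ~yd) + np.sum(~hi & yd)),
                           int(np.sum(hi & yd) + np.sum(~hi & ~yd)))
        assert best - n_correct <= 1

    def test_recovers_known_discriminant_direction(self):
        rng = np.random.default_rng(11)
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        X, y = _two_gaussians(rng, 250, shift=0.8 * direction / np.linalg.norm(direction),
                              p=4)
        res = fisher_lda(X, y)
        cos = (res.raw_coefficients @ direction) / (
            np.linalg.norm(res.raw_coefficients) * np.linalg.norm(direction))
        assert cos > 0.95

    def test_predictions_invariant_under_affine_feature_maps(self):
        rng = np.random.default_rng(2)
        X, y = _two_gaussians(rng, 20, shift=[1.0, 0.5, 0.0], p=3)
        res = fisher_lda(X, y)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        res2 = fisher_lda(X @ A + b, y)
        assert res2.predict() == res.predict()

    def test_standardized_coefficients_and_orientation(self):
        rng = np.random.default_rng(3)
        X, y = _two_gaussians(rng, 50, shift=[2.0, 0.0])
        res = fisher_lda(X, y)
        assert res.class_means["excess"] > res.class_means["deficient"]
        assert res.class_means["deficient"] < res.cutoff < res.class_means["excess"]
        # canonical scaling: unit pooled within-group score variance
        scores = res.scores()
        yd = np.asarray(y) == "deficient"
        pooled = (scores[yd].var(ddof=1) * (yd.sum() - 1)
                  + scores[~yd].var(ddof=1) * ((~yd).sum() - 1)) / (len(y) - 2)
        assert pooled == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_direction(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(4)
        X, y = _two_gaussians(rng, 40, shift=[1.0, -0.5, 0.3], p=3)
        res = fisher_lda(X, y)
        sk = LinearDiscriminantAnalysis().fit(X, np.asarray(y))
        w = sk.coef_.ravel()
        cos = (res.raw_coefficients @ w) / (
            np.linalg.norm(res.raw_coefficients) * np.linalg.norm(w))
        assert abs(cos) == pytest.approx(1.0, abs=1e-8)

    def test_collinear_features_rejected(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        y = ["deficient", "deficient", "excess", "excess"]
        with pytest.raises(np.linalg.LinAlgError, match="singular|collinear"):
            fisher_lda(X, y)

    def test_summary_reports_diagnostics(self, default_features):
        res = FisherDiscriminant.from_dataframe(
            default_features, ["PP1", "PP2", "PP3"]).fit()
        txt = res.summary()
        assert "Wilks" in txt and "Box" in txt and "cutoff" in txt


class TestWilksAndBoxM:
    def test_identical_class_means_give_lambda_near_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 3))
        y = ["deficient"] * 30 + ["excess"] * 30
        lam, p = wilks_lambda(X, y)
        assert lam > 0.8
        assert p > 0.05

    def test_wilks_matches_eigenvalue_route(self):
        """Λ = 1/(1+λ₁) with λ₁ the sole nonzero eigenvalue of S_w⁻¹S_b —
        an independent derivation of the same statistic."""
        rng = np.random.default_rng(6)
        X, y = _two_gaussians(rng, 30, shift=[1.0, 0.4])
        lam, _ = wilks_lambda(X, y)
        yd = np.asarray(y) == "deficient"
        Xd, Xe = X[yd], X[~yd]
        Sw = ((Xd - Xd.mean(0)).T @ (Xd - Xd.mean(0))
              + (Xe - Xe.mean(0)).T @ (Xe - Xe.mean(0)))
        Xc = X - X.mean(0)
        Sb = Xc.T @ Xc - Sw
        eig = np.linalg.eigvals(np.linalg.solve(Sw, Sb)).real
        assert lam == pytest.approx(1.0 / (1.0 + eig.max()), abs=1e-8)

    def test_box_m_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        X, y = _two_gaussians(rng, 25, shift=[0.5, 0.5])
        M, p = box_m(X, y)
        yd = np.asarray(y) == "deficient"
        n, q = X.shape
        S1 = np.cov(X[yd], rowvar=False)
        S2 = np.cov(X[~yd], rowvar=False)
        Sp = (24 * S1 + 24 * S2) / (n - 2)
        expected = ((n - 2) * np.log(np.linalg.det(Sp))
                    - 24 * np.log(np.linalg.det(S1))
                    - 24 * np.log(np.linalg.det(S2)))
        assert M == pytest.approx(expected, abs=1e-8)
        assert 0 <= p <= 1

    def test_box_m_calibrated_under_equal_covariances(self):
        """Generated with one covariance for both classes, the test should
        not reject: the median p over seeds stays comfortably high."""
        pvals = []
        for seed in range(15):
            rng = np.random.default_rng(200 + seed)
            X, y = _two_gaussians(rng, 100, shift=[0.5, 0.0])
            pvals.append(box_m(X, y)[1])
        assert np.median(pvals) > 0.2


class TestLOOCV:
    def test_separable_classes_cross_validate_perfectly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)),
                       rng.normal(10, 0.1, (5, 2))])
        y = ["deficient"] * 5 + ["excess"] * 5
        cv = loocv(lambda Xt, yt: FisherDiscriminant(Xt, yt).fit(), X, y)
        assert cv.accuracy == 1.0

    def test_counts_sum_to_cohort_size(self):
        rng = np.random.default_rng(8)
        X, y = _two_gaussians(rng, 12, shift=[0.5, 0.5])
        cv = loocv(lambda Xt, yt: FisherDiscriminant(Xt, yt).fit(), X, y)
        assert cv.table.total == len(y)
        assert len(cv.per_subject) == len(y)

    def test_fold_losing_a_class_is_excluded_with_warning(self):
        class Centroid:
            def __init__(self, Xt, yt):
                yt = np.asarray(yt)
                self.mu = {c: Xt[yt == c].mean(axis=0) for c in set(yt)}

            def predict(self, Xn):
                return [min(self.mu, key=lambda c: np.linalg.norm(row - self.mu[c]))
                        for row in np.atleast_2d(Xn)]

        X = np.array([[0.0, 0], [0.1, 0], [0.2, 0], [10, 10], [10.1, 10],
                      [10.2, 10.4]])
        y = ["deficient"] * 5 + ["excess"]
        with pytest.warns(UserWarning, match="lost a class"):
            cv = loocv(Centroid, X, y)
        assert cv.n_invalid == 1
        assert cv.table.total == 5

    def test_cross_validation_shows_optimism_on_average(self):
        """Training accuracy is an optimistic estimate: across many small
        synthetic cohorts, train − LOOCV accuracy is positive on average."""
        gaps = []
        for seed in range(25):
            rng = np.random.default_rng(300 + seed)
            X, y = _two_gaussians(rng, 15, shift=[0.8, 0.0, 0.0, 0.0], p=4)
            res = fisher_lda(X, y)
            train = px.accuracy(res.training_table())
            cv = loocv(lambda Xt, yt: FisherDiscriminant(Xt, yt).fit(), X, y)
            gaps.append(train - cv.accuracy)
        assert np.mean(gaps) > 0
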