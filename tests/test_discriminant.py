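"""From-scratch LDA/QDA/PDA against hand computations and analytic limits."""

import numpy as np
import pytest
from scipy.stats import norm

import spectrabench as sb
from spectrabench.discriminant import LDAModel


def _two_class_1d():
    # fitted class means 0 and 2, pooled variance exactly 1, equal priors
    h = np.sqrt(0.5)
    X = np.array([[-h], [h], [2.0 - h], [2.0 + h]])
    y = np.array(["A", "A", "B", "B"])
    return X, y


class TestLDA:
    def test_symmetric_midpoint_boundary_1d(self):
        X, y = _two_class_1d()
        model = sb.fit_lda(X, y)
        assert model.means[0, 0] == pytest.approx(0.0)
        assert model.means[1, 0] == pytest.approx(2.0)
        assert model.covariance[0, 0] == pytest.approx(1.0)
        assert sb.classify_lda(model, [[0.9]])[0] == "A"
        assert sb.classify_lda(model, [[1.1]])[0] == "B"

    def test_class_mean_classified_to_its_class(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (30, 3))])
        y = np.array(["A"] * 30 + ["B"] * 30)
        model = sb.fit_lda(X, y)
        assert sb.classify_lda(model, model.means[0])[0] == "A"
        assert sb.classify_lda(model, model.means[1])[0] == "B"

    def test_hand_evaluated_discriminant_difference(self):
        # identity pooled covariance, means (0,0) and (2,0), equal priors:
        # delta_1 - delta_2 at (0.9, 7) = -2*0.9 + 2 = 0.2 > 0 -> class 1
        model = LDAModel.from_parameters(
            classes=np.array(["c1", "c2"]),
            priors=[0.5, 0.5],
            means=[[0.0, 0.0], [2.0, 0.0]],
            covariance=np.eye(2),
        )
        delta = model.discriminants([[0.9, 7.0]])[0]
        assert delta[0] - delta[1] == pytest.approx(0.2)
        assert sb.classify_lda(model, [[0.9, 7.0]])[0] == "c1"

    def test_singular_pooled_covariance_guidance(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="PC scores|dimension"):
            sb.fit_lda(X, y)

    def test_true_parameter_rule_attains_bayes_error(self, rng):
        # equal-covariance Gaussians: Bayes error = Phi(-d/2), d = Mahalanobis
        # distance between the means.  The known-parameter rule should attain
        # it within binomial sampling error; the fitted rule should be close.
        mu = np.array([[0.0, 0.0], [2.0, 0.0]])
        n = 20_000
        X = np.vstack(
            [rng.normal(size=(n // 2, 2)) + mu[0], rng.normal(size=(n // 2, 2)) + mu[1]]
        )
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        oracle = LDAModel.from_parameters(["A", "B"], [0.5, 0.5], mu, np.eye(2))
        bayes = norm.cdf(-1.0)  # d = 2
        se = np.sqrt(bayes * (1 - bayes) / n)
        rate = sb.misclassification_rate(y, sb.classify_lda(oracle, X))
        assert abs(rate - bayes) < 3 * se
        fitted = sb.fit_lda(X[::10], y[::10])
        fitted_rate = sb.misclassification_rate(y, sb.classify_lda(fitted, X))
        assert abs(fitted_rate - bayes) < 0.02


class TestQDA:
    def test_unequal_variances_hand_example(self):
        # classes N(0,1) and N(0,4), equal priors
        model = sb.fit_qda(*_qda_1d_data())
        delta = model.discriminants([[0.0], [3.0]])
        # x*=0: delta_1 = log(0.5), delta_2 = -0.5*log(4) + log(0.5)
        assert delta[0, 0] - delta[0, 1] == pytest.approx(0.5 * np.log(4.0))
        assert sb.classify_qda(model, [[0.0]])[0] == "narrow"
        # x*=3: quadratic term wins for the wide class
        d1 = -0.5 * 9.0
        d2 = -0.5 * np.log(4.0) - 9.0 / 8.0
        assert delta[1, 0] - delta[1, 1] == pytest.approx(d1 - d2)
        assert sb.classify_qda(model, [[3.0]])[0] == "wide"

    def test_equal_covariances_reduce_to_lda(self):
        base = np.array([[-1.5], [-0.5], [0.5], [1.5]])
        X = np.vstack([base, base + 2.0])
        y = np.array(["A"] * 4 + ["B"] * 4)
        qda = sb.fit_qda(X, y)
        lda = sb.fit_lda(X, y)
        grid = np.linspace(-4, 6, 101)[:, None]
        np.testing.assert_array_equal(
            sb.classify_qda(qda, grid), sb.classify_lda(lda, grid)
        )

    def test_class_count_must_exceed_dimension(self, rng):
        X = rng.normal(size=(6, 4))
        y = np.array(["A", "A", "A", "B", "B", "B"])
        with pytest.raises(ValueError, match="n_c"):
            sb.fit_qda(X, y)


def _qda_1d_data():
    # sample moments exactly: mean 0 variance 1 vs mean 0 variance 4
    a = np.array([-1.0, 1.0]) * np.sqrt(0.5)
    X = np.concatenate([a, 2.0 * a])[:, None]
    y = np.array(["narrow", "narrow", "wide", "wide"])
    return X, y


class TestPDA:
    def test_zero_penalty_equals_lda(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(2, 1, (20, 3))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        query = rng.normal(1, 2, (50, 3))
        np.testing.assert_array_equal(
            sb.classify_pda(sb.fit_pda(X, y, 0.0), query),
            sb.classify_lda(sb.fit_lda(X, y), query),
        )

    def test_dominant_penalty_equals_nearest_mean(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(3, 1, (20, 3))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        model = sb.fit_pda(X, y, 1e9 * np.trace(np.cov(X, rowvar=False)) / 3)
        query = rng.normal(1.5, 3, (100, 3))
        nearest = np.where(
            np.linalg.norm(query - model.means[0], axis=1)
            < np.linalg.norm(query - model.means[1], axis=1),
            "A",
            "B",
        )
        np.testing.assert_array_equal(sb.classify_pda(model, query), nearest)

    def test_singular_covariance_dense_solve_oracle(self):
        # perfectly correlated features: Sigma singular, lambda = 1 regularizes
        t = np.array([-1.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([t, t])
        y = np.array(["A"] * 3 + ["B"] * 3)
        model = sb.fit_pda(X, y, 1.0)
        # brute-force dense inverse of Sigma + I
        classes = np.array(["A", "B"])
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        pooled = sum(
            (X[y == c] - means[i]).T @ (X[y == c] - means[i])
            for i, c in enumerate(classes)
        ) / (len(y) - 2)
        inv = np.linalg.inv(pooled + np.eye(2))
        query = np.array([[0.5, 0.5], [2.5, 2.5]])
        expected = query @ inv @ means.T - 0.5 * np.diag(means @ inv @ means.T) + np.log(0.5)
        np.testing.assert_allclose(model.discriminants(query), expected, atol=1e-8)

    def test_negative_lambda_rejected(self):
        X, y = _two_class_1d()
        with pytest.raises(ValueError):
            sb.fit_pda(X, y, -0.1)

    def test_pda_handles_p_much_larger_than_n(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 50)), rng.normal(1, 1, (10, 50))])
        y = np.array(["A"] * 10 + ["B"] * 10)
        model = sb.fit_pda(X, y, 1.0)
        assert set(sb.classify_pda(model, X)) <= {"A", "B"}


def test_label_permutation_invariance(rng):
    """Relabeling classes relabels predictions consistently for all rules."""
    X = np.vstack([rng.normal(i * 2, 1, (15, 2)) for i in range(3)])
    y = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
    swap = {"a": "z", "b": "b", "c": "a"}
    y2 = np.array([swap[c] for c in y])
    query = rng.normal(2, 3, (40, 2))
    pairs = [
        (lambda X, y: sb.classify_lda(sb.fit_lda(X, y), query)),
        (lambda X, y: sb.classify_qda(sb.fit_qda(X, y), query)),
        (lambda X, y: sb.classify_pda(sb.fit_pda(X, y, 0.5), query)),
        (lambda X, y: sb.knn_classify(X, y, query, 3)),
    ]
    for classify in pairs:
        base = classify(X, y)
        relabeled = classify(X, y2)
        np.testing.assert_array_equal(np.array([swap[c] for c in base]), relabeled)
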