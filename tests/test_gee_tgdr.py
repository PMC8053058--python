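import numpy as np
import pytest

from geetgdr import (
    VarianceProfile,
    WorkingCorrelation,
    build_matrix,
    fit,
    gee_gradient,
    mse,
    predict,
    quasi_objective,
    safe_inverse,
    selected_features,
    tgdr_fit,
    threshold_matrix,
)
from geetgdr.gee_tgdr import GeeTgdrModel


def _random_instance(rng, n=8, t=3, P=5, kind="exchangeable"):
    X = rng.standard_normal((n, P))
    Y = rng.standard_normal((n, t))
    beta = 0.3 * rng.standard_normal((t, P))
    if kind == "independent":
        wc = WorkingCorrelation(kind, None, t)
    elif kind == "unstructured":
        A = np.eye(t)
        A[0, 1] = A[1, 0] = 0.4
        A[1, 2] = A[2, 1] = -0.2
        A[0, 2] = A[2, 0] = 0.1
        wc = WorkingCorrelation(kind, A, t)
    else:
        wc = WorkingCorrelation(kind, 0.5, t)
    var = VarianceProfile(rng.uniform(0.5, 2.0, t))
    return X, Y, beta, wc, var


class TestQuasiObjective:
    def test_exact_fit_gives_zero(self, rng):
        X = rng.standard_normal((6, 3))
        beta = rng.standard_normal((2, 3))
        Y = X @ beta.T
        wc = WorkingCorrelation("exchangeable", 0.3, 2)
        assert quasi_objective(beta, (X, Y), wc, VarianceProfile(np.ones(2))) == 0.0

    def test_independent_unit_variance_is_mean_sse(self, rng):
        X, Y, beta, _, _ = _random_instance(rng)
        wc = WorkingCorrelation("independent", None, 3)
        got = quasi_objective(beta, (X, Y), wc, VarianceProfile(np.ones(3)))
        r = Y - X @ beta.T
        assert got == pytest.approx(np.sum(r**2) / X.shape[0])

    def test_matches_dense_quadratic_form_oracle(self, rng):
        X, Y, beta, wc, var = _random_instance(rng)
        got = quasi_objective(beta, (X, Y), wc, var)
        # independent dense evaluation: build V, invert, loop over subjects
        A_half = np.diag(np.sqrt(var.sigma2))
        V = A_half @ build_matrix(wc) @ A_half
        Vinv = np.linalg.inv(V)
        want = sum(
            (Y[i] - X[i] @ beta.T) @ Vinv @ (Y[i] - X[i] @ beta.T)
            for i in range(X.shape[0])
        ) / X.shape[0]
        assert got == pytest.approx(want, rel=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        X, Y, beta, wc, var = _random_instance(rng)
        with pytest.raises(ValueError):
            quasi_objective(beta[:, :-1], (X, Y), wc, var)


class TestGeeGradient:
    def test_zero_data_zero_gradient(self):
        wc = WorkingCorrelation("exchangeable", 0.2, 2)
        g = gee_gradient(
            np.zeros((2, 3)), (np.zeros((4, 3)), np.zeros((4, 2))), wc, VarianceProfile(np.ones(2))
        )
        np.testing.assert_array_equal(g, np.zeros((2, 3)))

    def test_reduces_to_per_time_gradient_under_independence(self, rng):
        X, Y, beta, _, _ = _random_instance(rng)
        wc = WorkingCorrelation("independent", None, 3)
        g = gee_gradient(beta, (X, Y), wc, VarianceProfile(np.ones(3)))
        r = Y - X @ beta.T
        want = (X.T @ r).T / X.shape[0]
        np.testing.assert_allclose(g, want, atol=1e-12)

    @pytest.mark.parametrize("kind", ["independent", "exchangeable", "ar1", "unstructured"])
    def test_matches_finite_differences(self, kind, rng):
        """gee_gradient is half the negative FD gradient of quasi_objective."""
        X, Y, beta, wc, var = _random_instance(rng, kind=kind)
        g = gee_gradient(beta, (X, Y), wc, var)
        h = 1e-6
        for j in range(beta.shape[0]):
            for p in range(beta.shape[1]):
                bp, bm = beta.copy(), beta.copy()
                bp[j, p] += h
                bm[j, p] -= h
                fd = -(quasi_objective(bp, (X, Y), wc, var) - quasi_objective(bm, (X, Y), wc, var)) / (2 * h) / 2
                assert g[j, p] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_literal_variant_coincides_for_equal_variances(self, rng):
        """With equal variances across time the printed asymmetric weight is a
        positive rescaling of the objective gradient."""
        X, Y, beta, wc, _ = _random_instance(rng)
        var = VarianceProfile(np.full(3, 1.7))
        g = gee_gradient(beta, (X, Y), wc, var)
        g_lit = gee_gradient(beta, (X, Y), wc, var, literal_eq5=True)
        np.testing.assert_allclose(g_lit, 1.7 * g, rtol=1e-10)


class TestThresholdMatrix:
    def test_row_maxima_in_distinct_columns(self):
        g = np.array([[0.9, 0.1, 0.2], [0.1, 0.8, 0.2]])
        f = threshold_matrix(g, 1.0)
        np.testing.assert_array_equal(f, [[1, 0, 0], [0, 1, 0]])

    def test_tau_zero_all_ones(self):
        f = threshold_matrix(np.array([[0.2, -0.1], [0.0, 0.3]]), 0.0)
        np.testing.assert_array_equal(f, np.ones((2, 2)))

    def test_direct_row_evaluation(self):
        # row threshold = 0.5 * 0.2 = 0.1; 0.05 drops out
        f = threshold_matrix(np.array([[0.2, 0.05, 0.19]]), 0.5)
        np.testing.assert_array_equal(f, [[1, 0, 1]])


class TestFit:
    def test_k_zero_null_model(self, small_panel):
        from geetgdr import standardize

        data, _ = small_panel
        std, _ = standardize(data)
        model = fit(std, kind="exchangeable", K=0)
        np.testing.assert_array_equal(model.beta, 0.0)
        assert all(len(s) == 0 for s in model.selected)
        assert len(model.objective_trace) == 1

    def test_reduces_to_tgdr_for_single_time_point(self, rng):
        n, P = 60, 25
        X = rng.standard_normal((n, P))
        y = X[:, 2] - 0.5 * X[:, 7] + rng.standard_normal(n)
        path = tgdr_fit(X, y, tau=1.0, delta_v=0.01, K=500)
        model = fit((X, y[:, None]), kind="independent", tau=1.0, delta_v=0.01, K=500)
        np.testing.assert_allclose(model.beta[0], path.beta, atol=1e-10)

    def test_tau_zero_converges_to_per_time_least_squares(self, rng):
        n, t, P = 100, 3, 10
        X = rng.standard_normal((n, P))
        B = np.zeros((t, P))
        B[:, :3] = rng.standard_normal((t, 3))
        Y = X @ B.T + rng.standard_normal((n, t))
        model = fit((X, Y), kind="independent", tau=0.0, delta_v=0.005, K=20_000)
        ols = np.linalg.solve(X.T @ X, X.T @ Y).T
        np.testing.assert_allclose(model.beta, ols, atol=1e-3)

    def test_single_time_point_nonindependent_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            fit((X, rng.standard_normal((10, 1))), kind="ar1")

    def test_frozen_nuisance_descent(self, rng):
        for kind in ("exchangeable", "unstructured", "independent"):
            n, t, P = 30, 3, 8
            X = rng.standard_normal((n, P))
            Y = rng.standard_normal((n, t))
            L = float(np.linalg.eigvalsh(X.T @ X / n).max())
            model = fit(
                (X, Y), kind=kind, tau=0.5, delta_v=0.5 / L, K=150, nuisance_refresh=10**9
            )
            assert np.all(np.diff(model.objective_trace) <= 1e-12)

    def test_checkpoints_match_shorter_runs(self, rng):
        X = rng.standard_normal((40, 12))
        Y = rng.standard_normal((40, 2))
        long = fit((X, Y), kind="exchangeable", tau=1.0, K=80, k_checkpoints=[20, 80])
        short = fit((X, Y), kind="exchangeable", tau=1.0, K=20)
        np.testing.assert_array_equal(long.checkpoints[20], short.beta)
        np.testing.assert_array_equal(long.checkpoints[80], long.beta)


class TestPredictAndMse:
    def test_zero_model_predicts_training_means(self, small_panel):
        from geetgdr import standardize

        data, _ = small_panel
        std, rec = standardize(data)
        model = fit(std, kind="exchangeable", K=0, record=rec)
        pred = predict(model, data.X)
        np.testing.assert_allclose(pred, np.tile(data.Y.mean(axis=0), (data.n, 1)))

    def test_hand_computed_products(self):
        model = GeeTgdrModel(
            beta=np.array([[1.0, 2.0], [0.0, -1.0]]),
            wc=WorkingCorrelation("independent", None, 2),
            var=VarianceProfile(np.ones(2)),
            tau=1.0,
            delta_v=0.01,
            K=0,
            objective_trace=np.zeros(1),
            feature_names=["a", "b"],
            time_labels=["t0", "t1"],
        )
        pred = predict(model, np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(pred, [[3 + 8, -4]])

    def test_feature_mismatch_rejected(self, small_panel):
        from geetgdr import standardize

        data, _ = small_panel
        std, rec = standardize(data)
        model = fit(std, kind="independent", K=1, record=rec)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(model, data.X[:, :-1])

    def test_mse_hand_values(self):
        assert mse(np.ones((3, 2)), np.ones((3, 2))) == 0.0
        assert mse(np.full((2, 2), 3.0), np.full((2, 2), 1.0)) == 4.0
        pred = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert mse(pred, np.zeros((2, 2))) == pytest.approx(7.5)
        with pytest.raises(ValueError):
            mse(np.ones((2, 2)), np.ones((3, 2)))


class TestSelectedFeatures:
    def _model_with_beta(self, beta):
        t, P = beta.shape
        return GeeTgdrModel(
            beta=beta,
            wc=WorkingCorrelation("independent", None, t),
            var=VarianceProfile(np.ones(t)),
            tau=1.0,
            delta_v=0.01,
            K=1,
            objective_trace=np.zeros(2),
            feature_names=[f"f{p}" for p in range(P)],
            time_labels=[f"t{j}" for j in range(t)],
        )

    def test_shared_feature_union(self):
        beta = np.zeros((2, 4))
        beta[0, 2] = beta[1, 2] = 0.5
        rep = selected_features(self._model_with_beta(beta))
        assert rep.by_time == {"t0": ["f2"], "t1": ["f2"]}
        assert rep.union == ["f2"]
        assert rep.overlap.loc["t0", "t1"] == 1

    def test_zero_model_empty(self):
        rep = selected_features(self._model_with_beta(np.zeros((3, 4))))
        assert rep.union == []
        assert all(v == [] for v in rep.by_time.values())

    def test_disjoint_supports_add_up(self):
        beta = np.zeros((2, 6))
        beta[0, [0, 1]] = 1.0
        beta[1, [3, 4, 5]] = 1.0
        rep = selected_features(self._model_with_beta(beta))
        assert len(rep.union) == 5
        assert rep.overlap.loc["t0", "t1"] == 0
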