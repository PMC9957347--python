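"""LS-SVM kernels and the exactness of the KKT linear-system solve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p2c.lssvm import (KernelSpec, LSSVMModel, decision_function, fit_lssvm,
                       kernel_matrix, predict)


def kkt_solve_oracle(X, y, C, spec):
    """Independent dense solve of [[0,1^T],[1,K+I/C]] [b;a] = [0;y]."""
    n = X.shape[0]
    K = kernel_matrix(X, X, spec)
    A = np.block([[np.zeros((1, 1)), np.ones((1, n))],
                  [np.ones((n, 1)), K + np.eye(n) / C]])
    rhs = np.concatenate([[0.0], y.astype(float)])
    sol = np.linalg.solve(A, rhs)
    sol += np.linalg.solve(A, rhs - A @ sol)  # one refinement step
    return sol[0], sol[1:]


def kkt_residual(model, y):
    n = model.support_X.shape[0]
    K = kernel_matrix(model.support_X, model.support_X, model.kernel)
    A = np.block([[np.zeros((1, 1)), np.ones((1, n))],
                  [np.ones((n, 1)), K + np.eye(n) / model.C]])
    lhs = A @ np.concatenate([[model.bias], model.alphas])
    return np.max(np.abs(lhs - np.concatenate([[0.0], y.astype(float)])))


def random_problem(rng, n=None, d=2):
    n = n if n is not None else int(rng.integers(4, 12))
    X = rng.standard_normal((n, d))
    y = np.concatenate([[-1, 1], rng.choice([-1, 1], n - 2)])
    return X, y


class TestKernelMatrix:
    def test_linear_is_gram_matrix(self, rng):
        X = rng.standard_normal((5, 3))
        assert np.allclose(kernel_matrix(X, X, KernelSpec("linear")), X @ X.T)

    def test_linear_hand_values(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert np.allclose(kernel_matrix(X, X, KernelSpec("linear")),
                           [[1.0, 0.0], [0.0, 4.0]])

    def test_rbf_diagonal_is_one(self, rng):
        X = rng.standard_normal((6, 4))
        K = kernel_matrix(X, X, KernelSpec("rbf", gamma=0.3))
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.01, 5.0))
    def test_rbf_kernel_positive_semidefinite(self, seed, gamma):
        X = np.random.default_rng(seed).standard_normal((6, 3))
        K = kernel_matrix(X, X, KernelSpec("rbf", gamma=gamma))
        assert np.linalg.eigvalsh(K).min() > -1e-9

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            kernel_matrix(rng.standard_normal((3, 2)),
                          rng.standard_normal((3, 4)), KernelSpec("linear"))

    def test_rbf_requires_positive_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            KernelSpec("rbf", gamma=-1.0)


class TestFit:
    def test_two_point_problem_classified_correctly(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = fit_lssvm(X, y, C=10.0, spec=KernelSpec("linear"))
        scores = decision_function(model, X)
        assert scores[0] < 0 < scores[1]
        b_o, a_o = kkt_solve_oracle(X, y, 10.0, KernelSpec("linear"))
        assert model.bias == pytest.approx(b_o, abs=1e-10)
        assert np.allclose(model.alphas, a_o, atol=1e-10)

    @pytest.mark.parametrize("spec", [KernelSpec("linear"), KernelSpec("rbf", gamma=0.7)])
    def test_oracle_equivalence_small_problems(self, spec, rng):
        for _ in range(10):
            X, y = random_problem(rng, n=int(rng.integers(3, 7)))
            C = float(10 ** rng.uniform(-1, 2))
            model = fit_lssvm(X, y, C, spec)
            b_o, a_o = kkt_solve_oracle(X, y, C, spec)
            assert abs(model.bias - b_o) < 1e-10
            assert np.max(np.abs(model.alphas - a_o)) < 1e-10

    def test_kkt_residual_over_many_random_fits(self, rng):
        for _ in range(50):
            X, y = random_problem(rng)
            spec = (KernelSpec("linear") if rng.random() < 0.5
                    else KernelSpec("rbf", gamma=float(10 ** rng.uniform(-2, 1))))
            model = fit_lssvm(X, y, float(10 ** rng.uniform(-2, 3)), spec)
            assert kkt_residual(model, y) < 1e-8
            assert abs(model.alphas.sum()) < 1e-8

    def test_point_symmetric_data_has_zero_bias(self, rng):
        Xh = rng.standard_normal((5, 3))
        X = np.vstack([Xh, -Xh])
        y = np.concatenate([np.ones(5), -np.ones(5)]).astype(int)
        model = fit_lssvm(X, y, C=5.0, spec=KernelSpec("linear"))
        assert abs(model.bias) < 1e-8

    def test_regularization_monotonicity(self):
        # doubling C never increases the training squared slack
        for seed in range(10):
            g = np.random.default_rng(seed)
            X, y = random_problem(g, n=20, d=3)
            sse = []
            for C in (1.0, 2.0):
                model = fit_lssvm(X, y, C, KernelSpec("rbf", gamma=0.5))
                resid = y - decision_function(model, X)
                sse.append(np.sum(resid ** 2))
            assert sse[1] <= sse[0] + 1e-10

    def test_vanishing_gamma_approaches_constant_scores(self, rng):
        X, y = random_problem(rng, n=12, d=3)
        model = fit_lssvm(X, y, C=1.0, spec=KernelSpec("rbf", gamma=1e-10))
        scores = decision_function(model, X)
        # smoke property: the kernel is nearly constant, scores nearly flat
        # around the majority/bias level
        assert scores.std() < 10 * abs(scores.mean() - model.bias) + 1.0

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(ValueError, match="two classes"):
            fit_lssvm(X, np.ones(4), C=1.0)

    def test_label_mapping_round_trip(self, rng):
        X, y_pm = random_problem(rng, n=10)
        labels = np.where(y_pm == -1, "benign", "tumor")
        model = fit_lssvm(X, labels, C=50.0, spec=KernelSpec("rbf", gamma=1.0))
        assert set(predict(model, X)) <= {"benign", "tumor"}


class TestDecisionAndPredict:
    def test_constant_model_scores(self, rng):
        X = rng.standard_normal((3, 2))
        model = LSSVMModel(alphas=np.zeros(3), bias=0.5, C=1.0,
                           kernel=KernelSpec("linear"), support_X=X)
        assert np.allclose(decision_function(model, X), 0.5)

    def test_linear_kernel_equals_primal_weights(self, rng):
        X, y = random_problem(rng, n=8, d=3)
        model = fit_lssvm(X, y, C=10.0, spec=KernelSpec("linear"))
        w = X.T @ model.alphas  # w = sum_i a_i x_i in the label-target form
        Xt = rng.standard_normal((5, 3))
        assert np.allclose(decision_function(model, Xt), Xt @ w + model.bias, atol=1e-10)

    def test_sign_rule_and_tie(self, rng):
        X = rng.standard_normal((2, 2))
        model = LSSVMModel(alphas=np.zeros(2), bias=0.0, C=1.0,
                           kernel=KernelSpec("linear"), support_X=X)
        assert np.all(predict(model, X) == 1)  # exact zero maps to +1

    def test_separable_training_accuracy(self):
        g = np.random.default_rng(4)
        X = np.vstack([g.normal(-2, 0.3, (20, 2)), g.normal(2, 0.3, (20, 2))])
        y = np.concatenate([-np.ones(20), np.ones(20)]).astype(int)
        model = fit_lssvm(X, y, C=100.0, spec=KernelSpec("linear"))
        assert np.array_equal(predict(model, X), y)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = random_problem(rng, n=6)
        model = fit_lssvm(X, y, C=1.0)
        with pytest.raises(ValueError, match="dimension"):
            decision_function(model, rng.standard_normal((2, 5)))


def test_json_round_trip(tmp_path, rng):
    X, y = random_problem(rng, n=6)
    model = fit_lssvm(X, y, C=3.0, spec=KernelSpec("rbf", gamma=0.2))
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = LSSVMModel.from_json(path)
    Xt = rng.standard_normal((4, 2))
    assert np.allclose(decision_function(loaded, Xt), decision_function(model, Xt))
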