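import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import LinearConstraint, minimize

from intervalcure.svm import (
    DecisionRule,
    PlattCalibration,
    data_driven_gamma_grid,
    decision_value,
    impute_and_estimate_pi,
    kernel_matrix,
    platt_fit,
    platt_probability,
    platt_targets,
    rbf_kernel,
    svm_train,
    tune_hyperparameters,
    _platt_objective,
)


class TestKernel:
    def test_zero_distance_gives_one(self):
        z = np.array([1.2, -0.7])
        assert rbf_kernel(z, z, gamma=0.3) == 1.0

    def test_unit_scaled_distance_gives_exp_minus_one(self):
        # ||zi - zj||^2 = 1/gamma  =>  K = e^-1
        gamma = 0.25
        zi = np.zeros(1)
        zj = np.array([np.sqrt(1.0 / gamma)])
        assert rbf_kernel(zi, zj, gamma) == pytest.approx(np.exp(-1), rel=1e-12)

    @given(st.integers(0, 1000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        assert rbf_kernel(a, b, 0.7) == pytest.approx(rbf_kernel(b, a, 0.7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(3), 1.0)

    @given(st.integers(0, 500))
    def test_gram_matrix_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((8, 2))
        K = kernel_matrix(pts, pts, gamma=0.5)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


def qp_oracle(points, labels, Q, gamma):
    """Dense solve of the dual QP with a generic constrained optimizer."""
    K = kernel_matrix(points, points, gamma)
    V = np.asarray(labels, dtype=float)
    H = np.outer(V, V) * K
    n = len(V)

    def neg_obj(c):
        return 0.5 * c @ H @ c - c.sum()

    def jac(c):
        return H @ c - 1.0

    res = minimize(
        neg_obj,
        np.full(n, min(Q, 1.0) / 2),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, Q)] * n,
        constraints=[LinearConstraint(V, 0.0, 0.0)],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return -res.fun


class TestSVMTrain:
    def test_two_separable_points_classified(self):
        pts = np.array([[0.0], [10.0]])
        rule = svm_train(pts, np.array([-1.0, 1.0]), Q=100.0, gamma=0.5)
        assert decision_value(rule, np.array([0.0])) < 0
        assert decision_value(rule, np.array([10.0])) > 0
        assert np.allclose(rule.c, rule.c[0])  # equal coefficients by symmetry

    def test_dual_feasibility(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((30, 2))
        labels = np.where(pts[:, 0] + 0.3 * rng.standard_normal(30) > 0, 1.0, -1.0)
        rule = svm_train(pts, labels, Q=8.0, gamma=0.7)
        assert abs(np.sum(rule.c * rule.V)) <= 1e-6
        assert np.all(rule.c >= -1e-12)
        assert np.all(rule.c <= 8.0 + 1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_dual_objective_matches_dense_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((6, 1))
        labels = np.where(rng.random(6) < 0.5, 1.0, -1.0)
        if len(np.unique(labels)) < 2:
            labels[0] = -labels[0]
        Q, gamma = 4.0, 0.8
        rule = svm_train(pts, labels, Q=Q, gamma=gamma)
        assert rule.dual_objective() == pytest.approx(
            qp_oracle(pts, labels, Q, gamma), abs=1e-4
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            svm_train(np.zeros((3, 1)), np.ones(3), Q=1.0, gamma=1.0)

    def test_decision_value_matches_direct_summation(self):
        rule = DecisionRule(
            c=np.array([0.5, 1.2]),
            V=np.array([1.0, -1.0]),
            support_points=np.array([[0.0, 1.0], [2.0, -1.0]]),
            b=0.3,
            gamma=0.4,
            Q=10.0,
        )
        z = np.array([1.0, 0.5])
        expected = (
            0.5 * rbf_kernel(np.array([0.0, 1.0]), z, 0.4)
            - 1.2 * rbf_kernel(np.array([2.0, -1.0]), z, 0.4)
            - 0.3
        )
        assert decision_value(rule, z) == pytest.approx(expected, rel=1e-12)

    def test_zero_rule_gives_zero_everywhere(self):
        rule = DecisionRule(
            c=np.zeros(1), V=np.ones(1), support_points=np.zeros((1, 2)),
            b=0.0, gamma=1.0, Q=1.0,
        )
        assert decision_value(rule, np.array([3.0, -2.0])) == 0.0

    def test_agrees_with_solver_decision_function(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        pts = rng.standard_normal((40, 2))
        labels = np.where(pts[:, 0] * pts[:, 1] > 0, 1.0, -1.0)
        clf = SVC(C=16.0, kernel="rbf", gamma=0.25, tol=1e-6).fit(pts, labels)
        rule = svm_train(pts, labels, Q=16.0, gamma=0.25)
        grid = rng.standard_normal((15, 2))
        assert np.allclose(
            rule.decision_value(grid), clf.decision_function(grid), atol=1e-8
        )


class TestPlatt:
    def test_targets_shrink_toward_interior(self):
        t = platt_targets(np.array([1, 1, 1, -1, -1]))
        assert np.allclose(t, [0.8, 0.8, 0.8, 0.25, 0.25])

    def test_all_positive_targets_constant(self):
        t = platt_targets(np.ones(8))
        assert np.allclose(t, 9.0 / 10.0)

    def test_zero_decision_values_fit_mean_target(self):
        labels = np.array([1, 1, -1, -1, -1])
        g = np.zeros(5)
        calib = platt_fit(g, labels)
        pi = platt_probability(calib, 0.0)
        assert pi == pytest.approx(platt_targets(labels).mean(), abs=1e-7)

    def test_antisymmetric_g_gives_zero_intercept(self):
        g = np.array([1.5, -1.5, 0.7, -0.7])
        labels = np.array([1, -1, 1, -1])
        calib = platt_fit(g, labels)
        assert calib.B == pytest.approx(0.0, abs=1e-7)
        assert calib.A < 0  # larger g => larger uncured probability

    def test_solution_dominates_origin(self):
        rng = np.random.default_rng(9)
        g = rng.standard_normal(30)
        labels = np.where(g + 0.5 * rng.standard_normal(30) > 0, 1, -1)
        if len(np.unique(labels)) < 2:
            labels[0] = -labels[0]
        calib = platt_fit(g, labels)
        t = platt_targets(labels)
        assert _platt_objective(calib.A, calib.B, g, t) >= _platt_objective(
            0.0, 0.0, g, t
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_concave_optimum_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(25)
        labels = np.where(g > 0, 1, -1)
        calib = platt_fit(g, labels)
        t = platt_targets(labels)
        best = calib_obj = _platt_objective(calib.A, calib.B, g, t)
        for A in np.linspace(calib.A - 1, calib.A + 1, 41):
            for B in np.linspace(calib.B - 1, calib.B + 1, 41):
                best = max(best, _platt_objective(A, B, g, t))
        assert calib_obj >= best - 1e-3

    def test_probability_examples(self):
        assert platt_probability(PlattCalibration(0.0, 0.0), 1.7) == 0.5
        assert platt_probability(
            PlattCalibration(-1.0, 0.0), np.log(3.0)
        ) == pytest.approx(0.75)
        assert platt_probability(PlattCalibration(-1.0, 0.0), 60.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_parameter_recovery_from_logistic_labels(self):
        # labels drawn from the model pi = 1/(1+exp(A g + B)) recover (A, B)
        rng = np.random.default_rng(3)
        A_true, B_true = -2.0, 0.4
        n = 6000
        g = rng.standard_normal(n)
        p = 1.0 / (1.0 + np.exp(A_true * g + B_true))
        labels = np.where(rng.random(n) < p, 1, -1)
        calib = platt_fit(g, labels)
        assert calib.A == pytest.approx(A_true, abs=0.15)
        assert calib.B == pytest.approx(B_true, abs=0.15)


class TestTuning:
    def test_returned_pair_in_grid_with_tie_break(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(-8, 0.3, (20, 2)), rng.normal(8, 0.3, (20, 2))])
        labels = np.repeat([-1.0, 1.0], 20)
        gg, qq = (0.0625, 0.125, 0.25), (1.0, 2.0)
        gamma, Q = tune_hyperparameters(pts, labels, gg, qq, folds=5, seed=0)
        # separable blobs: zero CV error everywhere, tie-break to smallest
        assert (gamma, Q) == (0.0625, 1.0)

    def test_uninformative_labels_error_near_class_floor(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((60, 2))
        labels = np.where(np.arange(60) % 3 == 0, 1.0, -1.0)  # 20 vs 40
        gamma, Q = tune_hyperparameters(
            pts, labels, (0.1,), (4.0,), folds=5, seed=1
        )
        assert (gamma, Q) == (0.1, 4.0)

    def test_minority_smaller_than_two_errors(self):
        pts = np.random.default_rng(0).standard_normal((10, 1))
        labels = np.array([1.0] + [-1.0] * 9)
        with pytest.raises(ValueError, match="impossible"):
            tune_hyperparameters(pts, labels, (0.1,), (1.0,), folds=5, seed=0)


class TestGammaGrid:
    def test_one_dimensional_example(self):
        grid = data_driven_gamma_grid(np.array([[0.0], [1.0], [2.0]]))
        # pairwise squared distances {1, 1, 4}: median 1, gamma0 = 1
        assert np.allclose(grid, [0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])

    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance(self, s):
        pts = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 1.0]])
        g1 = data_driven_gamma_grid(pts)
        g2 = data_driven_gamma_grid(pts * s)
        assert np.allclose(g2, g1 / s**2, rtol=1e-10)
        assert len(g1) == 7

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="median"):
            data_driven_gamma_grid(np.ones((4, 2)))


class TestImputation:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, 2))
        rc = rng.random(n) < 0.5
        if not rc.any():
            rc[0] = True
        w = np.ones(n)
        w[rc] = rng.random(rc.sum())
        return z, rc, w, rng

    def test_deterministic_weights_give_single_model_output(self):
        z, rc, w, rng = self._setup()
        w[rc] = np.round(w[rc])  # all weights in {0, 1}
        if w[rc].min() == 1.0:
            w[np.flatnonzero(rc)[0]] = 0.0
        est = impute_and_estimate_pi(z, rc, w, gamma=0.25, Q=16.0, M=1, rng=rng)
        V = np.where(w > 0.5, 1.0, -1.0)
        rule = svm_train(z, V, Q=16.0, gamma=0.25)
        calib = platt_fit(rule.decision_value(z), V)
        assert np.allclose(est.pi_hat, platt_probability(calib, rule.decision_value(z)))

    def test_zero_weights_label_cured(self):
        z, rc, w, rng = self._setup(seed=5)
        w[rc] = 0.0
        est = impute_and_estimate_pi(z, rc, w, gamma=0.25, Q=16.0, M=3, rng=rng)
        for rule in est.rules:
            # right-censored subjects were labelled -1 in every imputation:
            # the count of +1 support labels cannot exceed the uncensored count
            assert np.sum(rule.V == 1) <= (~rc).sum()

    def test_average_lies_within_componentwise_envelope(self):
        z, rc, w, rng = self._setup(seed=7)
        est = impute_and_estimate_pi(z, rc, w, gamma=0.25, Q=16.0, M=4, rng=rng)
        parts = np.array(
            [
                platt_probability(c, r.decision_value(z))
                for r, c in zip(est.rules, est.calibrations)
            ]
        )
        assert np.all(est.pi_hat >= parts.min(axis=0) - 1e-12)
        assert np.all(est.pi_hat <= parts.max(axis=0) + 1e-12)
        assert np.all((est.pi_hat > 0) & (est.pi_hat < 1))

    def test_weight_validation(self):
        z, rc, w, rng = self._setup()
        w[~rc] = 0.5
        with pytest.raises(ValueError, match="non-right-censored"):
            impute_and_estimate_pi(z, rc, w, gamma=0.3, Q=4.0, M=1, rng=rng)

    def test_rule_serialization_round_trip(self):
        z, rc, w, rng = self._setup(seed=2)
        est = impute_and_estimate_pi(z, rc, w, gamma=0.3, Q=8.0, M=2, rng=rng)
        from intervalcure.svm import IncidenceEstimate

        back = IncidenceEstimate.from_dict(est.to_dict())
        znew = np.random.default_rng(1).standard_normal((5, 2))
        assert np.allclose(back.predict(znew), est.predict(znew))
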