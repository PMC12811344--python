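import numpy as np
import pytest
from scipy.optimize import minimize

import intervalcure as ic
from intervalcure.turnbull import (
    baseline_survival_at,
    turnbull_fit,
    turnbull_intervals,
    turnbull_loglik,
    _membership,
)

from conftest import make_dataset


def intervals_of(rows):
    return turnbull_intervals(make_dataset(rows))


class TestIntervals:
    def test_disjoint_intervals_are_their_own_classes(self):
        assert intervals_of([(1, 2, 0, 1), (3, 4, 0, 1)]) == [(1, 2), (3, 4)]

    def test_overlap_reduces_to_intersection(self):
        assert intervals_of([(1, 3, 0, 1), (2, 4, 0, 1)]) == [(2, 3)]

    def test_right_censoring_adds_tail_class(self):
        got = intervals_of([(0, 1, 1, 0), (0.5, np.inf, 0, 0)])
        assert got == [(0.5, 1.0), (1.0, np.inf)]

    def test_interiors_contain_no_endpoints(self):
        rng = np.random.default_rng(5)
        ds, _ = ic.generate_dataset(ic.scenario_spec(1), 60, rng)
        classes = turnbull_intervals(ds)
        endpoints = np.concatenate(
            [ds.u_left, ds.u_right[np.isfinite(ds.u_right)]]
        )
        for a, b in classes:
            inside = (endpoints > a) & (endpoints < b)
            assert not np.any(inside)
        # sorted and disjoint
        for (a1, b1), (a2, b2) in zip(classes, classes[1:]):
            assert b1 <= a2


def simplex_oracle(dataset):
    """Direct maximization of the Turnbull likelihood over the probability
    simplex (softmax parametrization), independent of the EM route."""
    classes = turnbull_intervals(dataset)
    A = _membership(dataset, classes).astype(float)
    m = A.shape[1]

    def neg(theta):
        s = np.exp(theta - theta.max())
        s = s / s.sum()
        probs = A @ s
        if np.any(probs <= 0):
            return 1e12
        return -np.sum(np.log(probs))

    best = None
    for start in range(4):
        theta0 = np.random.default_rng(start).standard_normal(m)
        res = minimize(neg, theta0, method="Nelder-Mead",
                       options={"fatol": 1e-12, "xatol": 1e-10, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    s = np.exp(best.x - best.x.max())
    return s / s.sum(), -best.fun


class TestFit:
    def test_two_disjoint_subjects_split_mass_equally(self):
        ds = make_dataset([(1, 2, 0, 1), (3, 4, 0, 1)])
        base = turnbull_fit(ds)
        assert np.allclose(base.masses, [0.5, 0.5], atol=1e-6)
        assert base.residual_mass == 0.0

    def test_binomial_split_with_right_censoring(self):
        rows = [(0, 1, 1, 0)] * 3 + [(1, np.inf, 0, 0)] * 3
        base = turnbull_fit(make_dataset(rows))
        assert np.allclose(base.masses, [0.5], atol=1e-6)
        assert base.residual_mass == pytest.approx(0.5, abs=1e-6)

    def test_survival_is_one_before_first_class(self):
        rows = [(0, 1, 1, 0)] + [(2.0, np.inf, 0, 0)] * 4
        base = turnbull_fit(make_dataset(rows))
        assert baseline_survival_at(base, 0.0) == 1.0
        assert baseline_survival_at(base, 0.999) == 1.0

    def test_mass_sums_to_one(self, sc1_data):
        base = turnbull_fit(sc1_data[0])
        assert base.masses.sum() + base.residual_mass == pytest.approx(1, abs=1e-8)
        assert base.converged

    def test_disjoint_singletons_equal_empirical_proportions(self):
        rows = [(1, 2, 0, 1)] * 3 + [(3, 4, 0, 1)] * 1
        base = turnbull_fit(make_dataset(rows))
        assert np.allclose(base.masses, [0.75, 0.25], atol=1e-6)

    def test_self_consistency_residual_small_at_return(self, sc1_data):
        base = turnbull_fit(sc1_data[0], tol=1e-8)
        classes = [(a, b) for a, b in zip(base.q, base.p)]
        masses = list(base.masses)
        if np.isfinite(base.tail_q):
            classes.append((base.tail_q, np.inf))
            masses.append(base.residual_mass)
        A = _membership(sc1_data[0], classes).astype(float)
        s = np.asarray(masses)
        update = s * (A / (A @ s)[:, None]).sum(axis=0) / A.shape[0]
        assert np.max(np.abs(update - s)) < 1e-6

    @pytest.mark.parametrize(
        "rows",
        [
            [(1, 2, 0, 1), (3, 4, 0, 1)],
            [(0, 1, 1, 0), (0, 1, 1, 0), (1, np.inf, 0, 0)],
            [(1, 3, 0, 1), (2, 4, 0, 1), (0.5, 3.5, 0, 1)],
            [(0, 2, 1, 0), (1, np.inf, 0, 0), (1.5, 2.5, 0, 1), (0.5, 1.2, 0, 1)],
        ],
    )
    def test_masses_match_simplex_oracle(self, rows):
        ds = make_dataset(rows)
        base = turnbull_fit(ds, tol=1e-10)
        s_oracle, ll_oracle = simplex_oracle(ds)
        assert turnbull_loglik(ds, base) == pytest.approx(ll_oracle, abs=1e-5)
        fitted = np.concatenate(
            [base.masses, [base.residual_mass]]
            if base.residual_mass > 0 or not np.isfinite(ds.u_right).all()
            else [base.masses]
        )
        if len(fitted) == len(s_oracle):
            assert np.allclose(fitted, s_oracle, atol=1e-4)

    def test_monotone_loglik_across_iterations(self):
        rng = np.random.default_rng(11)
        ds, _ = ic.generate_dataset(ic.scenario_spec(1), 40, rng)
        lls = []
        for k in range(1, 30, 3):
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    base = turnbull_fit(ds, tol=0.0, max_iter=k)
            lls.append(turnbull_loglik(ds, base))
        assert np.all(np.diff(lls) >= -1e-9)


class TestSurvivalAt:
    @pytest.fixture
    def step(self):
        return turnbull_fit(make_dataset([(1, 2, 0, 1), (3, 4, 0, 1)]))

    def test_at_zero_is_one(self, step):
        assert baseline_survival_at(step, 0.0) == 1.0

    def test_step_at_right_endpoint(self, step):
        assert baseline_survival_at(step, 2.0) == pytest.approx(0.5)

    def test_constant_between_classes(self, step):
        assert baseline_survival_at(step, 2.5) == pytest.approx(0.5)

    def test_negative_time_rejected(self, step):
        with pytest.raises(ValueError):
            baseline_survival_at(step, -0.5)

    def test_right_continuous_non_increasing(self, sc1_data):
        base = turnbull_fit(sc1_data[0])
        grid = np.linspace(0, 3.0, 500)
        vals = baseline_survival_at(base, grid)
        assert np.all(np.diff(vals) <= 1e-12)
        assert baseline_survival_at(base, np.inf) == pytest.approx(
            base.residual_mass, abs=1e-9
        )


def test_agrees_with_lifelines_npmle(sc1_data):
    """Independent cross-check against an established NPMLE implementation."""
    lifelines = pytest.importorskip("lifelines")
    from lifelines.fitters.npmle import npmle

    ds, _ = sc1_data
    probs, ivls = npmle(ds.u_left, ds.u_right, tol=1e-10)
    base = turnbull_fit(ds, tol=1e-10)
    # compare the survival curves at points strictly between all endpoints
    finite_ends = np.unique(
        np.concatenate([ds.u_left, ds.u_right[np.isfinite(ds.u_right)]])
    )
    ts = (finite_ends[:-1] + finite_ends[1:]) / 2.0
    ours = np.asarray(baseline_survival_at(base, ts))
    rights = np.array([iv.right for iv in ivls])
    ll_surv = np.array([1.0 - probs[rights <= t].sum() for t in ts])
    assert np.allclose(ours, ll_surv, atol=2e-3)


def test_export_csv(tmp_path, sc1_data):
    base = turnbull_fit(sc1_data[0])
    path = tmp_path / "baseline.csv"
    base.write_csv(path)
    text = path.read_text().splitlines()
    assert text[0] == "q,p,mass"
    assert "inf" in text[-1]
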