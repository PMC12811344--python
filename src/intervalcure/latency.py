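"""Proportional-hazards latency over a fixed nonparametric baseline.

The conditional survival of uncured subjects is S(t|x) = S0(t)^{exp(x'beta)}
with S0 the frozen Turnbull step function.  The weighted complete-data
latency log-likelihood Q_c2 replaces the unknown cured statuses of
right-censored subjects with their E-step posterior weights w_i:

    Q_c2(beta) = sum_i delta1_i log(1 - S0(U_Ri)^{e_i})
               + sum_i delta2_i log(S0(U_Li)^{e_i} - S0(U_Ri)^{e_i})
               + sum_{right-censored i} w_i e_i log S0(U_Li),

where e_i = exp(x_i' beta).  It is maximized by Nelder-Mead simplex search
(one restart), matching the derivative-free update the estimation procedure
prescribes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .turnbull import BaselineSurvival, baseline_survival_at
from .types import Dataset

__all__ = [
    "LatencyModel",
    "conditional_survival",
    "interval_survival_arrays",
    "q_c2",
    "maximize_q_c2",
]

_SENTINEL = -1e12
_S0_FLOOR = 1e-12


@dataclass
class LatencyModel:
    """Cox-PH latency: regression vector beta (no intercept) and baseline."""

    beta: np.ndarray
    baseline: BaselineSurvival

    def survival(self, x: np.ndarray, t) -> np.ndarray | float:
        return conditional_survival(self, x, t)


def conditional_survival(model: LatencyModel, x: np.ndarray, t) -> np.ndarray | float:
    """S(t|x) = S0(t)^{exp(x' beta)}."""
    s0 = baseline_survival_at(model.baseline, t)
    eta = float(np.dot(np.asarray(x, dtype=float), model.beta))
    return _power_survival(np.asarray(s0, dtype=float), np.exp(eta))


def _power_survival(s0, expo):
    """s0 ** expo with exact zeros preserved (no 0**large -> nan issues)."""
    s0 = np.asarray(s0, dtype=float)
    out = np.zeros(np.broadcast(s0, np.asarray(expo)).shape)
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        res = np.exp(np.asarray(expo) * np.log(np.maximum(s0, _S0_FLOOR)))
    out = np.where(s0 <= 0.0, 0.0, res)
    if np.ndim(s0) == 0 and np.ndim(expo) == 0:
        return float(out)
    return out


def interval_survival_arrays(
    dataset: Dataset, baseline: BaselineSurvival
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline survival at each subject's interval endpoints (S0L, S0R)."""
    s0l = np.asarray(baseline_survival_at(baseline, dataset.u_left), dtype=float)
    u_right = np.where(np.isfinite(dataset.u_right), dataset.u_right, np.inf)
    s0r = np.asarray(baseline_survival_at(baseline, u_right), dtype=float)
    return s0l, s0r


def q_c2(
    beta: np.ndarray,
    dataset: Dataset,
    weights: np.ndarray,
    baseline: BaselineSurvival | None = None,
    s0_arrays: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Weighted complete-data latency log-likelihood at ``beta``.

    Returns a large negative sentinel (never raises) when an interval term
    is non-positive, so simplex optimizers can back away.
    """
    beta = np.asarray(beta, dtype=float)
    if s0_arrays is None:
        if baseline is None:
            raise ValueError("need baseline or precomputed s0 arrays")
        s0_arrays = interval_survival_arrays(dataset, baseline)
    s0l, s0r = s0_arrays
    w = np.asarray(weights, dtype=float)
    with np.errstate(over="ignore"):
        e = np.exp(np.clip(dataset.x @ beta, -700, 700))
    pow_l = _power_survival(s0l, e)
    pow_r = _power_survival(s0r, e)
    lc = dataset.delta1 == 1
    ic = dataset.delta2 == 1
    rc = ~lc & ~ic
    total = 0.0
    if np.any(lc):
        term = 1.0 - pow_r[lc]
        if np.any(term <= 0.0):
            return _SENTINEL
        total += float(np.sum(np.log(term)))
    if np.any(ic):
        term = pow_l[ic] - pow_r[ic]
        if np.any(term <= 0.0):
            return _SENTINEL
        total += float(np.sum(np.log(term)))
    if np.any(rc):
        log_s0l = np.log(np.clip(s0l[rc], _S0_FLOOR, 1.0))
        total += float(np.sum(w[rc] * e[rc] * log_s0l))
    if not np.isfinite(total):
        return _SENTINEL
    return total


def maximize_q_c2(
    dataset: Dataset,
    weights: np.ndarray,
    baseline: BaselineSurvival,
    beta_init: np.ndarray,
    fatol: float = 1e-8,
    maxiter: int | None = None,
) -> np.ndarray:
    """Nelder-Mead ascent of Q_c2 with a single restart.

    Guarantees Q_c2(returned) >= Q_c2(beta_init); when the objective is flat
    around the start (unidentified beta, e.g. all subjects falling in one
    Turnbull class) the initial value is returned with a warning.
    """
    beta_init = np.asarray(beta_init, dtype=float)
    s0_arrays = interval_survival_arrays(dataset, baseline)
    f0 = q_c2(beta_init, dataset, weights, s0_arrays=s0_arrays)
    if f0 <= _SENTINEL:
        raise ValueError("infeasible latency likelihood at beta_init")

    def neg(b):
        return -q_c2(b, dataset, weights, s0_arrays=s0_arrays)

    opts = {"fatol": fatol, "xatol": 1e-6}
    if maxiter is not None:
        opts["maxiter"] = maxiter
    res = minimize(neg, beta_init, method="Nelder-Mead", options=opts)
    res2 = minimize(neg, res.x, method="Nelder-Mead", options=opts)
    best = res2 if res2.fun <= res.fun else res
    if -best.fun < f0:
        return beta_init
    if abs(-best.fun - f0) < 1e-10 and not np.allclose(best.x, beta_init):
        warnings.warn(
            "latency objective is flat around beta_init; returning beta_init",
            RuntimeWarning,
        )
        return beta_init
    return np.asarray(best.x, dtype=float)
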