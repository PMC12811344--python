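"""Logistic-incidence comparator: the same EM and latency machinery with a
parametric logistic model pi(z) = expit(b0 + z'b) for the uncured
probability, whose M-step maximizes the weighted Bernoulli likelihood Q_c1
exactly (damped Newton).  Because both M-steps are exact maximizations, the
observed-data log-likelihood is non-decreasing across iterations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .em import FitResult, e_step, observed_loglik
from .latency import interval_survival_arrays, maximize_q_c2
from .turnbull import turnbull_fit
from .types import Dataset, EMConfig

__all__ = ["LogitIncidence", "q_c1", "fit_q_c1", "fit_mcm_logit"]

_PI_EPS = 1e-12


@dataclass
class LogitIncidence:
    """Logistic incidence parameters: pi(z) = expit(intercept + z'coef)."""

    intercept: float
    coef: np.ndarray

    def predict(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return expit(self.intercept + z @ self.coef)

    def to_dict(self) -> dict:
        return {"intercept": float(self.intercept), "coef": self.coef.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LogitIncidence":
        return cls(float(d["intercept"]), np.asarray(d["coef"], dtype=float))


def q_c1(params: LogitIncidence, dataset: Dataset, weights: np.ndarray) -> float:
    """Weighted Bernoulli incidence log-likelihood.

    Left/interval-censored subjects contribute log pi; right-censored ones
    contribute w log pi + (1 - w) log(1 - pi).
    """
    w = np.asarray(weights, dtype=float)
    pi = np.clip(params.predict(dataset.z), _PI_EPS, 1.0 - _PI_EPS)
    return float(np.sum(w * np.log(pi) + (1.0 - w) * np.log(1.0 - pi)))


def fit_q_c1(
    z: np.ndarray,
    weights: np.ndarray,
    start: LogitIncidence | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> LogitIncidence:
    """Damped-Newton maximization of the weighted Bernoulli likelihood.

    Separation (diverging coefficients or a singular Hessian) triggers one
    retry with a small ridge penalty (1e-6).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    w = np.asarray(weights, dtype=float)
    X = np.column_stack([np.ones(len(z)), z])
    if start is not None:
        params = np.concatenate([[start.intercept], start.coef])
    else:
        params = np.zeros(X.shape[1])

    def loglik(th):
        p = np.clip(expit(X @ th), _PI_EPS, 1.0 - _PI_EPS)
        ll = np.sum(w * np.log(p) + (1.0 - w) * np.log(1.0 - p))
        return ll - 0.5 * ridge * np.sum(th**2)

    ll = loglik(params)
    for _ in range(max_iter):
        p = expit(X @ params)
        grad = X.T @ (w - p) - ridge * params
        if np.max(np.abs(grad)) <= tol:
            break
        W = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * W[:, None]).T @ X + (ridge + 1e-12) * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            break
        lam = 1.0
        for _ in range(30):
            cand = params + lam * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-15:
                break
            lam *= 0.5
        params, ll = cand, ll_new
    if ridge == 0.0 and (
        not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 50.0
    ):
        import warnings

        warnings.warn(
            "possible separation in the logistic incidence fit; "
            "refitting with ridge 1e-6",
            RuntimeWarning,
        )
        return fit_q_c1(z, weights, start=None, max_iter=max_iter, tol=tol,
                        ridge=1e-6)
    return LogitIncidence(float(params[0]), params[1:])


def fit_mcm_logit(
    dataset: Dataset,
    config: EMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """EM fit of the mixture cure model with logistic incidence."""
    config = config or EMConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    baseline = turnbull_fit(dataset)
    s0_arrays = interval_survival_arrays(dataset, baseline)
    # initialization mirrors the SVM variant: delta-based labels for pi,
    # no-cure latency fit for beta
    w0 = np.asarray(dataset.observed_uncured, dtype=float)
    inc = fit_q_c1(dataset.z, w0)
    pi = np.clip(inc.predict(dataset.z), _PI_EPS, 1.0 - _PI_EPS)
    beta = maximize_q_c2(dataset, np.ones(dataset.n), baseline,
                         np.zeros(dataset.p))
    trace: list[dict] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        w = e_step(dataset, pi, beta, baseline, s0_arrays).w
        inc = fit_q_c1(dataset.z, w, start=inc)
        pi_new = np.clip(inc.predict(dataset.z), _PI_EPS, 1.0 - _PI_EPS)
        beta_new = maximize_q_c2(dataset, w, baseline, beta)
        crit = float(np.sum((pi_new - pi) ** 2) + np.sum((beta_new - beta) ** 2))
        if config.normalize_criterion:
            crit /= dataset.n + dataset.p
        pi, beta = pi_new, beta_new
        ll = observed_loglik(dataset, pi, beta, baseline, s0_arrays)
        trace.append({"iter": it, "loglik": ll, "criterion": crit})
        if crit < config.epsilon:
            converged = True
            break
    return FitResult(
        model="logit",
        pi_hat=pi,
        beta_hat=beta,
        baseline=baseline,
        incidence=inc,
        trace=trace,
        converged=converged,
        n_iter=it,
        config=config,
    )
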