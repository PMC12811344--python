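"""EM-type estimation of the SVM-based mixture cure model.

Alternates an exact E-step,

    w_i = delta1_i + delta2_i + (1 - delta1_i - delta2_i)
          * pi(z_i) S0(U_Li)^{exp(x_i'beta)}
            / (1 - pi(z_i) + pi(z_i) S0(U_Li)^{exp(x_i'beta)}),

with an M-step that (a) re-estimates the uncured probabilities by multiple
imputation of the missing cured statuses followed by SVM + Platt fits, and
(b) updates beta by maximizing the weighted latency log-likelihood.  The
Turnbull baseline is estimated once from all intervals and frozen.  The
stopping rule is the squared L2 distance between successive concatenated
parameter vectors (the per-subject pi-vector and beta) falling below
epsilon.  Standard errors come from a nonparametric bootstrap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from . import svm as _svm
from .latency import interval_survival_arrays, maximize_q_c2, _power_survival
from .turnbull import BaselineSurvival, turnbull_fit
from .types import Dataset, EMConfig

__all__ = [
    "WeightVector",
    "FitResult",
    "e_step",
    "observed_loglik",
    "initialize",
    "fit_mcm_svm",
    "bootstrap_se",
]

_PI_EPS = 1e-12


@dataclass
class WeightVector:
    """Posterior probabilities of being uncured given data and parameters."""

    w: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class FitResult:
    """Output of one EM fit."""

    model: str
    pi_hat: np.ndarray
    beta_hat: np.ndarray
    baseline: BaselineSurvival
    incidence: object  # IncidenceEstimate (svm) or LogitIncidence (logit)
    trace: list
    converged: bool
    n_iter: int
    config: EMConfig
    se: np.ndarray | None = None
    n_failed_bootstrap: int = 0

    def predict_pi(self, z: np.ndarray) -> np.ndarray:
        """Uncured probability at new incidence covariate values."""
        return self.incidence.predict(z)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "pi_hat": self.pi_hat.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "baseline": self.baseline.to_dict(),
            "incidence": self.incidence.to_dict(),
            "trace": self.trace,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "config": self.config.to_dict(),
            "se": None if self.se is None else self.se.tolist(),
            "n_failed_bootstrap": int(self.n_failed_bootstrap),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        from .logit import LogitIncidence

        incidence_cls = (
            _svm.IncidenceEstimate if d["model"] == "svm" else LogitIncidence
        )
        return cls(
            model=d["model"],
            pi_hat=np.asarray(d["pi_hat"], dtype=float),
            beta_hat=np.asarray(d["beta_hat"], dtype=float),
            baseline=BaselineSurvival.from_dict(d["baseline"]),
            incidence=incidence_cls.from_dict(d["incidence"]),
            trace=d["trace"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            config=EMConfig(**d["config"]),
            se=None if d.get("se") is None else np.asarray(d["se"], dtype=float),
            n_failed_bootstrap=d.get("n_failed_bootstrap", 0),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _susceptible_survival_at_left(dataset, beta, s0l):
    with np.errstate(over="ignore"):
        e = np.exp(np.clip(dataset.x @ np.asarray(beta, dtype=float), -700, 700))
    return _power_survival(s0l, e)


def e_step(
    dataset: Dataset,
    pi: np.ndarray,
    beta: np.ndarray,
    baseline: BaselineSurvival,
    s0_arrays=None,
) -> WeightVector:
    """Posterior uncured probability for every subject at (pi, beta)."""
    pi = np.clip(np.asarray(pi, dtype=float), _PI_EPS, 1.0 - _PI_EPS)
    if s0_arrays is None:
        s0_arrays = interval_survival_arrays(dataset, baseline)
    s0l, _ = s0_arrays
    surv = _susceptible_survival_at_left(dataset, beta, s0l)
    rc = dataset.right_censored
    w = np.asarray(dataset.observed_uncured, dtype=float)
    num = pi * surv
    w = w + rc * num / (1.0 - pi + num)
    return WeightVector(np.clip(w, 0.0, 1.0))


def observed_loglik(
    dataset: Dataset,
    pi: np.ndarray,
    beta: np.ndarray,
    baseline: BaselineSurvival,
    s0_arrays=None,
) -> float:
    """Observed-data log-likelihood of the mixture cure model."""
    pi = np.clip(np.asarray(pi, dtype=float), _PI_EPS, 1.0 - _PI_EPS)
    if s0_arrays is None:
        s0_arrays = interval_survival_arrays(dataset, baseline)
    s0l, s0r = s0_arrays
    with np.errstate(over="ignore"):
        e = np.exp(np.clip(dataset.x @ np.asarray(beta, dtype=float), -700, 700))
    pow_l = _power_survival(s0l, e)
    pow_r = _power_survival(s0r, e)
    lc = dataset.delta1 == 1
    ic = dataset.delta2 == 1
    rc = ~lc & ~ic
    total = 0.0
    if np.any(lc):
        term = 1.0 - pow_r[lc]
        if np.any(term <= 0.0):
            return -np.inf
        total += float(np.sum(np.log(pi[lc])) + np.sum(np.log(term)))
    if np.any(ic):
        term = pow_l[ic] - pow_r[ic]
        if np.any(term <= 0.0):
            return -np.inf
        total += float(np.sum(np.log(pi[ic])) + np.sum(np.log(term)))
    if np.any(rc):
        total += float(np.sum(np.log(1.0 - pi[rc] + pi[rc] * pow_l[rc])))
    return total


def initialize(
    dataset: Dataset,
    config: EMConfig,
    rng: np.random.Generator,
    baseline: BaselineSurvival,
    tuned: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Initial (pi0, beta0) and the tuned (gamma, Q) pair.

    pi0 comes from a single SVM + Platt fit treating delta1 + delta2 as the
    uncured label; beta0 maximizes the no-cure latency likelihood (all
    weights one) from the origin.
    """
    labels0 = dataset.observed_uncured
    if labels0.sum() == 0:
        raise ValueError("all subjects right-censored: cannot initialize")
    if tuned is None:
        V0 = 2.0 * labels0 - 1.0
        if len(np.unique(V0)) < 2:
            # no right-censored subjects: tuning impossible, grid heads used
            gamma_grid = (
                _svm.data_driven_gamma_grid(dataset.z)
                if config.gamma_grid is None
                else config.gamma_grid
            )
            tuned = (float(gamma_grid[0]), float(config.Q_grid[0]))
        else:
            gamma_grid = (
                _svm.data_driven_gamma_grid(dataset.z)
                if config.gamma_grid is None
                else config.gamma_grid
            )
            tuned = _svm.tune_hyperparameters(
                dataset.z,
                V0,
                gamma_grid,
                config.Q_grid,
                folds=config.cv_folds,
                seed=int(rng.integers(2**31 - 1)),
            )
    inc0 = _svm.impute_and_estimate_pi(
        dataset.z,
        dataset.right_censored,
        np.asarray(labels0, dtype=float),
        gamma=tuned[0],
        Q=tuned[1],
        M=1,
        rng=rng,
    )
    beta0 = maximize_q_c2(
        dataset, np.ones(dataset.n), baseline, np.zeros(dataset.p)
    )
    return inc0.pi_hat, beta0, tuned


def fit_mcm_svm(
    dataset: Dataset,
    config: EMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Full EM fit of the SVM-based mixture cure model."""
    config = config or EMConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    baseline = turnbull_fit(dataset)
    s0_arrays = interval_survival_arrays(dataset, baseline)
    pi, beta, tuned = initialize(dataset, config, rng, baseline)
    incidence = None
    trace: list[dict] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        w = e_step(dataset, pi, beta, baseline, s0_arrays).w
        if config.retune_every_iter:
            V = np.where(w >= 0.5, 1.0, -1.0)
            if len(np.unique(V)) == 2:
                gamma_grid = (
                    _svm.data_driven_gamma_grid(dataset.z)
                    if config.gamma_grid is None
                    else config.gamma_grid
                )
                tuned = _svm.tune_hyperparameters(
                    dataset.z, V, gamma_grid, config.Q_grid,
                    folds=config.cv_folds, seed=int(rng.integers(2**31 - 1)),
                )
        incidence = _svm.impute_and_estimate_pi(
            dataset.z,
            dataset.right_censored,
            w,
            gamma=tuned[0],
            Q=tuned[1],
            M=config.M,
            rng=rng,
        )
        pi_new = incidence.pi_hat
        beta_new = maximize_q_c2(dataset, w, baseline, beta)
        crit = float(
            np.sum((pi_new - pi) ** 2) + np.sum((beta_new - beta) ** 2)
        )
        if config.normalize_criterion:
            crit /= dataset.n + dataset.p
        pi, beta = pi_new, beta_new
        ll = observed_loglik(dataset, pi, beta, baseline, s0_arrays)
        trace.append({"iter": it, "loglik": ll, "criterion": crit})
        if crit < config.epsilon:
            converged = True
            break
    return FitResult(
        model="svm",
        pi_hat=pi,
        beta_hat=beta,
        baseline=baseline,
        incidence=incidence,
        trace=trace,
        converged=converged,
        n_iter=it,
        config=config,
    )


def bootstrap_se(
    dataset: Dataset,
    config: EMConfig | None = None,
    rng: np.random.Generator | None = None,
    fit_fn=fit_mcm_svm,
) -> tuple[np.ndarray, int]:
    """Bootstrap standard errors of beta_hat.

    Draws ``config.bootstrap_B`` nonparametric resamples of subjects with
    replacement, refits, and reports the sample standard deviation of the
    beta components over successful refits.  More than 20% failed refits is
    an error.
    """
    config = config or EMConfig()
    if config.bootstrap_B < 2:
        raise ValueError("bootstrap_B must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    betas = []
    failed = 0
    for _ in range(config.bootstrap_B):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        try:
            sub = dataset.subset(idx)
            fit = fit_fn(sub, config, rng)
            betas.append(fit.beta_hat)
        except Exception as exc:  # noqa: BLE001 - failed refits are counted
            failed += 1
            warnings.warn(f"bootstrap refit failed: {exc}", RuntimeWarning)
    if failed > 0.2 * config.bootstrap_B:
        raise RuntimeError(
            f"{failed}/{config.bootstrap_B} bootstrap refits failed"
        )
    return np.std(np.asarray(betas), axis=0, ddof=1), failed
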