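"""Synthetic mixed-case interval-censored cure data.

Four data-generating scenarios share one censoring mechanism and differ in
the true incidence surface and covariate law:

1. logistic incidence pi(z) = expit(0.3 - 5 z1 - 3 z2), z1, z2 iid N(0,1),
   x = z (linear cure/uncure boundary);
2. the same logistic link with the interaction term 5 z1 z2 - 3 z1 z2
   (implemented literally, net 2 z1 z2), producing a nonlinear boundary;
3. a complementary-log-log-style surface in ten correlated N(0, Sigma)
   covariates, Sigma_ij = 0.7^|i-j|, x = z;
4. the same surface with z1..z4 Bernoulli(0.5, 0.3, 0.5, 0.7) and z5..z10
   standard normal; all ten covariates enter the latency while the models
   see only (z1..z5) as incidence covariates (z != x).

Subjects are cured with probability 1 - pi(z); uncured event times are
Weibull with shape alpha and scale exp(x'beta)^(-1/alpha) (so S(t|x) =
exp(-e^{x'beta} t^alpha)).  Examination times accumulate Uniform(0.1, 0.25)
gaps until they pass min(t, 2.5); the event is then recorded as left,
interval, or right censored.  Per-subject ground truth (true pi, cure label,
event time) is retained for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .types import Dataset

__all__ = [
    "ScenarioSpec",
    "SimulationTruth",
    "scenario_spec",
    "scenario_pi",
    "generate_covariates",
    "generate_dataset",
    "generate_hdsd_like",
]

_CAP = 2.5  # administrative end of the examination schedule
_GAP = (0.1, 0.25)


@dataclass(frozen=True)
class ScenarioSpec:
    """True incidence surface, covariate law, and Weibull latency truth."""

    id: int
    alpha: float
    beta_true: np.ndarray
    n_covariates: int
    incidence_columns: tuple  # columns of the full covariate matrix exposed as z

    @property
    def z_equals_x(self) -> bool:
        return len(self.incidence_columns) == self.n_covariates


_BETA_34 = (-0.8, 1.5, 0.5, 1.3, -0.6, -1.4, -0.5, -0.8, 0.5, 1.8)


def scenario_spec(scenario_id: int) -> ScenarioSpec:
    if scenario_id in (1, 2):
        return ScenarioSpec(scenario_id, 1.0, np.array([-5.0, 5.0]), 2, (0, 1))
    if scenario_id == 3:
        return ScenarioSpec(3, 0.2, np.array(_BETA_34), 10, tuple(range(10)))
    if scenario_id == 4:
        return ScenarioSpec(4, 0.2, np.array(_BETA_34), 10, tuple(range(5)))
    raise ValueError("scenario id must be in {1, 2, 3, 4}")


def _cloglog_surface(z: np.ndarray) -> np.ndarray:
    z1, z2, z3, z4, z5 = (z[:, k] for k in range(5))
    z6, z7, z8, z9, z10 = (z[:, k] for k in range(5, 10))
    with np.errstate(over="ignore"):
        eta = (
            -0.8 * z1 * z2
            + 1.1 * z2 * z4
            + 0.5 * z3
            + 0.2 * z7**2
            - 1.3 * np.sin(z5 * z6)
            + 1.9 * np.cos(z7 * z8)
            - 1.5 * np.exp(z5 * z6 * z7)
            - 1.6 * z7 * z8 * z9 * z10
            + 0.8 * z6 * z7 * z8**2 * z9**2
            + 1.8 * np.cos(z5 * z6 * z7 * z8 * z9)
            + 1.2 * np.abs(z6 * z7 * z8 * z9 * z10) ** 0.5
            - 2.4
        )
        pi = np.exp(-np.exp(eta))
    return np.clip(pi, 0.0, 1.0)


def scenario_pi(spec: ScenarioSpec, z: np.ndarray) -> np.ndarray:
    """True uncured probability evaluated on the FULL covariate matrix."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != spec.n_covariates:
        raise ValueError(
            f"scenario {spec.id} needs {spec.n_covariates} covariates, "
            f"got {z.shape[1]}"
        )
    if spec.id == 1:
        return expit(0.3 - 5.0 * z[:, 0] - 3.0 * z[:, 1])
    if spec.id == 2:
        prod = z[:, 0] * z[:, 1]
        return expit(0.3 + 5.0 * prod - 3.0 * prod)
    return _cloglog_surface(z)


def generate_covariates(
    spec: ScenarioSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Full covariate matrix (latency covariates x); the incidence covariates
    z are the columns ``spec.incidence_columns``."""
    if spec.id in (1, 2):
        return rng.standard_normal((n, 2))
    if spec.id == 3:
        idx = np.arange(10)
        cov = 0.7 ** np.abs(idx[:, None] - idx[None, :])
        chol = np.linalg.cholesky(cov)
        return rng.standard_normal((n, 10)) @ chol.T
    z = np.empty((n, 10))
    for j, prob in enumerate((0.5, 0.3, 0.5, 0.7)):
        z[:, j] = rng.random(n) < prob
    z[:, 4:] = rng.standard_normal((n, 6))
    return z


@dataclass
class SimulationTruth:
    """Per-subject ground truth retained for evaluation."""

    pi_true: np.ndarray
    J_true: np.ndarray   # 1 = uncured
    t_true: np.ndarray   # event time, inf for cured

    def __post_init__(self) -> None:
        cured = self.J_true == 0
        if not np.array_equal(cured, ~np.isfinite(self.t_true)):
            raise ValueError("J_true = 0 must coincide with t_true = inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pi_true": self.pi_true, "J_true": self.J_true, "t_true": self.t_true}
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["t_true"] = ["inf" if not np.isfinite(v) else repr(float(v))
                        for v in df["t_true"]]
        df["pi_true"] = [repr(float(v)) for v in df["pi_true"]]
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SimulationTruth":
        df = pd.read_csv(
            path, dtype={"t_true": str}, float_precision="round_trip"
        )
        t = np.array(
            [np.inf if s.strip().lower() == "inf" else float(s)
             for s in df["t_true"]]
        )
        return cls(df["pi_true"].to_numpy(float), df["J_true"].to_numpy(int), t)

    def subset(self, idx) -> "SimulationTruth":
        idx = np.asarray(idx)
        return SimulationTruth(
            self.pi_true[idx], self.J_true[idx], self.t_true[idx]
        )


def _censor_times(t: np.ndarray, rng: np.random.Generator):
    """First examination time past min(t, cap) plus its predecessor."""
    n = len(t)
    target = np.minimum(t, _CAP)
    # 26 gaps of at least 0.1 always exceed the 2.5 cap
    n_gaps = int(np.ceil(_CAP / _GAP[0])) + 2
    gaps = rng.uniform(_GAP[0], _GAP[1], size=(n, n_gaps))
    cum = np.cumsum(gaps, axis=1)
    j = np.argmax(cum > target[:, None], axis=1)
    u_j = cum[np.arange(n), j]
    u_prev = np.where(j > 0, cum[np.arange(n), np.maximum(j - 1, 0)], 0.0)
    return u_prev, u_j


def generate_dataset(
    spec: ScenarioSpec, n: int, rng: np.random.Generator
) -> tuple[Dataset, SimulationTruth]:
    """Draw one dataset plus its ground truth from a scenario."""
    x = generate_covariates(spec, n, rng)
    pi = scenario_pi(spec, x)
    cured = rng.random(n) <= 1.0 - pi
    t = np.full(n, np.inf)
    uncured = ~cured
    if np.any(uncured):
        rate = np.exp(x[uncured] @ spec.beta_true)
        u = rng.random(uncured.sum())
        t[uncured] = (-np.log(u) / rate) ** (1.0 / spec.alpha)
    u_prev, u_j = _censor_times(t, rng)
    right = t > _CAP  # includes cured (t = inf)
    left = ~right & (t <= _GAP[0])
    inter = ~right & ~left
    u_left = np.where(right, u_j, np.where(left, 0.0, u_prev))
    u_right = np.where(right, np.inf, u_j)
    # An uncured event inside the very first gap leaves u_prev = 0; such
    # subjects are left-censored by definition (delta1 = I(U_L = 0)).
    delta1 = ((u_left == 0.0) & np.isfinite(u_right)).astype(int)
    delta2 = ((u_left > 0.0) & np.isfinite(u_right)).astype(int)
    z = x[:, list(spec.incidence_columns)]
    x_names = [f"x{k+1}" for k in range(x.shape[1])]
    z_names = [f"z{k+1}" for k in spec.incidence_columns]
    dataset = Dataset(u_left, u_right, delta1, delta2, x, z, x_names, z_names)
    truth = SimulationTruth(pi, uncured.astype(int), t)
    return dataset, truth


# -- HDSD-like synthetic fixture ------------------------------------------

_HDSD_AGE = (31.882, 7.126, 20.0, 54.0)
_HDSD_TR = (1.637, 0.227, 1.04, 1.89)
_HDSD_P_MALE = 177.0 / 238.0
_HDSD_P_AMB = 195.0 / 238.0


def generate_hdsd_like(
    n: int = 238, rng: np.random.Generator | None = None
) -> tuple[Dataset, SimulationTruth]:
    """Synthetic stand-in emulating the covariate structure of NASA's
    hypobaric decompression sickness study (238 subjects, ~71% right
    censored): Age, Sex, TR360 (decompression stress) and NOADYN
    (ambulatory indicator), with a nonlinear age-by-sex incidence surface.

    This is a synthetic fixture for exercising the real-data workflow; it
    reproduces marginal moments and the censoring share, not the study's
    results.
    """
    rng = rng if rng is not None else np.random.default_rng(0)

    def _tnorm(mean, sd, lo, hi):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    age = _tnorm(*_HDSD_AGE)
    sex = (rng.random(n) < _HDSD_P_MALE).astype(float)  # 1 = male
    tr360 = _tnorm(*_HDSD_TR)
    noadyn = (rng.random(n) < _HDSD_P_AMB).astype(float)
    a_std = (age - _HDSD_AGE[0]) / _HDSD_AGE[1]
    t_std = (tr360 - _HDSD_TR[0]) / _HDSD_TR[1]
    # nonlinear (interaction) incidence calibrated to ~71% right censoring
    pi = expit(-1.1 + 2.0 * a_std * (2.0 * sex - 1.0))
    cured = rng.random(n) <= 1.0 - pi
    t = np.full(n, np.inf)
    unc = ~cured
    eta = 1.0 + 0.4 * a_std - 0.3 * sex + 0.5 * t_std - 1.0 * noadyn
    if np.any(unc):
        t[unc] = -np.log(rng.random(unc.sum())) / np.exp(eta[unc])
    u_prev, u_j = _censor_times(t, rng)
    right = t > _CAP
    left = ~right & (t <= _GAP[0])
    u_left = np.where(right, u_j, np.where(left, 0.0, u_prev))
    u_right = np.where(right, np.inf, u_j)
    delta1 = ((u_left == 0.0) & np.isfinite(u_right)).astype(int)
    delta2 = ((u_left > 0.0) & np.isfinite(u_right)).astype(int)
    x = np.column_stack([age, sex, tr360, noadyn])
    z = np.column_stack([age, sex])
    dataset = Dataset(
        u_left, u_right, delta1, delta2, x, z,
        ["Age", "Sex", "TR360", "NOADYN"], ["Age", "Sex"],
    )
    truth = SimulationTruth(pi, unc.astype(int), t)
    return dataset, truth
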