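"""Turnbull NPMLE of the baseline survival from censoring intervals.

The nonparametric maximum-likelihood estimate of a survival function under
interval censoring places all probability mass on the maximal intersections
("Turnbull equivalence classes") of the observed intervals ``(u_left,
u_right]`` and is computed by the self-consistency (EM) iteration.  The fit
uses every subject's interval, ignoring covariates and cure status, and the
resulting step function is held fixed throughout the cure-model EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Dataset

__all__ = [
    "BaselineSurvival",
    "turnbull_intervals",
    "turnbull_fit",
    "baseline_survival_at",
]


@dataclass
class BaselineSurvival:
    """Step-function NPMLE: mass ``masses[j]`` on interval ``(q[j], p[j]]``.

    ``residual_mass`` is the probability beyond the last finite interval
    (the mass of the tail class ``(max endpoint, inf)`` when right-censored
    subjects are present).  Evaluation places each interval's mass at its
    right endpoint, giving a right-continuous, non-increasing step function
    with S0(0) = 1 and S0(inf) = residual_mass.
    """

    q: np.ndarray
    p: np.ndarray
    masses: np.ndarray
    residual_mass: float
    tail_q: float = np.nan  # left endpoint of the (tail_q, inf) residual class
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan

    def __call__(self, t) -> np.ndarray | float:
        return baseline_survival_at(self, t)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"q": self.q, "p": self.p, "mass": self.masses})
        tq = self.tail_q if np.isfinite(self.tail_q) else (
            self.p[-1] if len(self.p) else 0.0)
        tail = pd.DataFrame({"q": [tq], "p": [np.inf],
                             "mass": [self.residual_mass]})
        return pd.concat([df, tail], ignore_index=True)

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["p"] = ["inf" if not np.isfinite(v) else v for v in df["p"]]
        df.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "q": self.q.tolist(),
            "p": self.p.tolist(),
            "masses": self.masses.tolist(),
            "residual_mass": float(self.residual_mass),
            "tail_q": float(self.tail_q),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineSurvival":
        return cls(
            np.asarray(d["q"], dtype=float),
            np.asarray(d["p"], dtype=float),
            np.asarray(d["masses"], dtype=float),
            float(d["residual_mass"]),
            float(d.get("tail_q", np.nan)),
        )


def turnbull_intervals(dataset: Dataset) -> list[tuple[float, float]]:
    """Maximal intersections of the observed intervals, sorted and disjoint.

    A finite class ``(a, b]`` has ``a`` among the observed left endpoints,
    ``b`` among the observed finite right endpoints, and no observed endpoint
    strictly inside.  When right-censored subjects exist, the tail class
    ``(max endpoint, inf)`` is appended to carry the residual mass.
    """
    left = np.asarray(dataset.u_left, dtype=float)
    right = np.asarray(dataset.u_right, dtype=float)
    lefts = set(np.unique(left))
    rights_fin = set(np.unique(right[np.isfinite(right)]))
    endpoints = np.array(sorted(lefts | rights_fin))
    classes: list[tuple[float, float]] = []
    for a, b in zip(endpoints[:-1], endpoints[1:]):
        if a in lefts and b in rights_fin:
            classes.append((float(a), float(b)))
    if np.any(~np.isfinite(right)):
        classes.append((float(endpoints[-1]), np.inf))
    return classes


def _membership(dataset: Dataset, classes) -> np.ndarray:
    """a[i, j] = 1 if class j is contained in subject i's interval."""
    q = np.array([c[0] for c in classes])
    p = np.array([c[1] for c in classes])
    left = dataset.u_left[:, None]
    right = dataset.u_right[:, None]
    return (q[None, :] >= left) & (p[None, :] <= right)


def turnbull_fit(
    dataset: Dataset, tol: float = 1e-6, max_iter: int = 10000
) -> BaselineSurvival:
    """Self-consistency (EM) fit of the Turnbull-interval masses."""
    classes = turnbull_intervals(dataset)
    if not classes:
        raise ValueError("no Turnbull classes: empty or degenerate intervals")
    A = _membership(dataset, classes).astype(float)
    if np.any(A.sum(axis=1) == 0):
        raise ValueError("a subject's interval contains no Turnbull class")
    n, m = A.shape
    s = np.full(m, 1.0 / m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = A @ s  # P(interval_i contains the event)
        s_new = s * (A / denom[:, None]).sum(axis=0) / n
        delta = np.max(np.abs(s_new - s))
        s = s_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Turnbull self-consistency did not converge in {max_iter} "
            "iterations; returning last iterate",
            RuntimeWarning,
        )
    loglik = float(np.sum(np.log(A @ s)))
    p = np.array([c[1] for c in classes])
    finite = np.isfinite(p)
    residual = float(s[~finite].sum()) if np.any(~finite) else 0.0
    tail_q = float(classes[-1][0]) if np.any(~finite) else np.nan
    return BaselineSurvival(
        q=np.array([c[0] for c in classes])[finite],
        p=p[finite],
        masses=s[finite],
        residual_mass=residual,
        tail_q=tail_q,
        converged=converged,
        n_iter=it,
        loglik=loglik,
    )


def baseline_survival_at(baseline: BaselineSurvival, t) -> np.ndarray | float:
    """S0(t) = 1 - sum of masses on classes with right endpoint <= t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(np.isnan(t_arr)) or np.any(t_arr[~np.isnan(t_arr)] < 0):
        raise ValueError("t must be >= 0 (inf allowed)")
    cum = np.concatenate([[0.0], np.cumsum(baseline.masses)])
    idx = np.searchsorted(baseline.p, t_arr, side="right")
    out = 1.0 - cum[idx]
    # guard tiny negative round-off
    out = np.clip(out, 0.0, 1.0)
    if np.ndim(t) == 0:
        return float(out)
    return out


def turnbull_loglik(dataset: Dataset, baseline: BaselineSurvival) -> float:
    """Observed-data log-likelihood of a baseline under the intervals."""
    classes = [(a, b) for a, b in zip(baseline.q, baseline.p)]
    masses = list(baseline.masses)
    if np.isfinite(baseline.tail_q):
        classes.append((float(baseline.tail_q), np.inf))
        masses.append(baseline.residual_mass)
    A = _membership(dataset, classes).astype(float)
    probs = A @ np.asarray(masses)
    if np.any(probs <= 0):
        return -np.inf
    return float(np.sum(np.log(probs)))
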