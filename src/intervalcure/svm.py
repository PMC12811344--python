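"""SVM incidence: cured/uncured classification with calibrated probabilities.

The uncured probability pi(z) is obtained in two stages.  A soft-margin SVM
with a radial-basis kernel is trained on cured/uncured labels V in {-1, +1}
by solving the dual quadratic program

    max_c  -1/2 sum_ij c_i c_j V_i V_j K(z_i, z_j) + sum_i c_i
    s.t.   sum_i c_i V_i = 0,   0 <= c_i <= Q,

yielding the decision value g(z) = sum_i c_i V_i K(z_i, z) - b.  Platt
scaling then fits a two-parameter sigmoid pi(z) = 1 / (1 + exp(A g(z) + B))
by maximizing a smoothed Bernoulli likelihood with shrunken targets, which
converts margins into posterior uncured probabilities.

Because cured statuses are unknown for right-censored subjects, the M-step
of the cure-model EM imputes them: M label vectors are drawn from
Bernoulli(w_i) using the E-step weights, an SVM + Platt model is fitted per
draw, and the M probability vectors are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "DecisionRule",
    "PlattCalibration",
    "IncidenceEstimate",
    "rbf_kernel",
    "kernel_matrix",
    "svm_train",
    "decision_value",
    "platt_targets",
    "platt_fit",
    "platt_probability",
    "tune_hyperparameters",
    "data_driven_gamma_grid",
    "impute_and_estimate_pi",
]


def rbf_kernel(z_i: np.ndarray, z_j: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||z_i - z_j||^2), with gamma = 1 / (2 sigma^2)."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape:
        raise ValueError("covariate vectors differ in length")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d = z_i - z_j
    return float(np.exp(-gamma * np.dot(d, d)))


def kernel_matrix(za: np.ndarray, zb: np.ndarray, gamma: float) -> np.ndarray:
    """RBF Gram matrix between the rows of ``za`` and ``zb``."""
    za = np.atleast_2d(np.asarray(za, dtype=float))
    zb = np.atleast_2d(np.asarray(zb, dtype=float))
    sq = (
        np.sum(za**2, axis=1)[:, None]
        + np.sum(zb**2, axis=1)[None, :]
        - 2.0 * za @ zb.T
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


@dataclass
class DecisionRule:
    """Dual SVM solution: g(z) = sum_i c_i V_i K(z_i, z) - b."""

    c: np.ndarray          # support coefficients, 0 < c_i <= Q
    V: np.ndarray          # labels of the support points, +-1
    support_points: np.ndarray
    b: float
    gamma: float
    Q: float

    def decision_value(self, z: np.ndarray) -> np.ndarray | float:
        return decision_value(self, z)

    def dual_objective(self) -> float:
        """Value of the dual objective at this solution."""
        cv = self.c * self.V
        K = kernel_matrix(self.support_points, self.support_points, self.gamma)
        return float(self.c.sum() - 0.5 * cv @ K @ cv)

    def to_dict(self) -> dict:
        return {
            "c": self.c.tolist(),
            "V": self.V.tolist(),
            "support_points": self.support_points.tolist(),
            "b": float(self.b),
            "gamma": float(self.gamma),
            "Q": float(self.Q),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionRule":
        return cls(
            np.asarray(d["c"], dtype=float),
            np.asarray(d["V"], dtype=float),
            np.asarray(d["support_points"], dtype=float),
            float(d["b"]),
            float(d["gamma"]),
            float(d["Q"]),
        )


@dataclass
class PlattCalibration:
    """Sigmoid parameters of pi(z) = 1 / (1 + exp(A g(z) + B))."""

    A: float
    B: float

    def to_dict(self) -> dict:
        return {"A": float(self.A), "B": float(self.B)}

    @classmethod
    def from_dict(cls, d: dict) -> "PlattCalibration":
        return cls(float(d["A"]), float(d["B"]))


@dataclass
class IncidenceEstimate:
    """Multiple-imputation average of per-draw SVM + Platt probabilities."""

    pi_hat: np.ndarray
    rules: list
    calibrations: list
    gamma: float
    Q: float

    def predict(self, z: np.ndarray) -> np.ndarray:
        """Average uncured probability at new covariate values."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        parts = [
            platt_probability(cal, rule.decision_value(z))
            for rule, cal in zip(self.rules, self.calibrations)
        ]
        return np.mean(parts, axis=0)

    def to_dict(self) -> dict:
        return {
            "pi_hat": self.pi_hat.tolist(),
            "rules": [r.to_dict() for r in self.rules],
            "calibrations": [c.to_dict() for c in self.calibrations],
            "gamma": float(self.gamma),
            "Q": float(self.Q),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IncidenceEstimate":
        return cls(
            np.asarray(d["pi_hat"], dtype=float),
            [DecisionRule.from_dict(r) for r in d["rules"]],
            [PlattCalibration.from_dict(c) for c in d["calibrations"]],
            float(d["gamma"]),
            float(d["Q"]),
        )


def svm_train(
    points: np.ndarray, labels: np.ndarray, Q: float, gamma: float
) -> DecisionRule:
    """Solve the soft-margin RBF dual (via libsvm's SMO) for a decision rule.

    The intercept is the margin-support-vector average of the KKT relation
    b = sum_i c_i V_i K(z_i, z_j) - V_j, as computed by the solver.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("degenerate labels: both classes are required")
    clf = SVC(C=Q, kernel="rbf", gamma=gamma, tol=1e-6)
    clf.fit(points, labels)
    dual = clf.dual_coef_[0]  # = V_i * c_i over support vectors
    return DecisionRule(
        c=np.abs(dual),
        V=np.sign(dual),
        support_points=points[clf.support_],
        b=-float(clf.intercept_[0]),
        gamma=float(gamma),
        Q=float(Q),
    )


def decision_value(rule: DecisionRule, z: np.ndarray) -> np.ndarray | float:
    """g(z) = sum_i c_i V_i K(z_i, z) - b."""
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 1
    z2 = np.atleast_2d(z)
    if z2.shape[1] != rule.support_points.shape[1]:
        raise ValueError("covariate dimension mismatch")
    K = kernel_matrix(z2, rule.support_points, rule.gamma)
    g = K @ (rule.c * rule.V) - rule.b
    return float(g[0]) if scalar else g


def platt_targets(labels: np.ndarray) -> np.ndarray:
    """Shrunken sigmoid-fit targets: (n1+1)/(n1+2) for V=+1, 1/(n0+2) for V=-1."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty labels")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == -1))
    return np.where(labels == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))


def _platt_objective(A: float, B: float, g: np.ndarray, t: np.ndarray) -> float:
    h = A * g + B
    # sum (1 - t) h - sum log(1 + e^h), computed stably
    return float(np.sum((1.0 - t) * h) + np.sum(log_expit(-h)))


def platt_fit(
    g_values: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PlattCalibration:
    """Maximize the Platt sigmoid likelihood by damped Newton iteration.

    The objective is concave in (A, B); initialization A = -1,
    B = log((n0+1)/(n1+1)) follows Platt's recommendation and yields A < 0
    (larger decision value => larger uncured probability) whenever the
    classes are separated in g.
    """
    g = np.asarray(g_values, dtype=float)
    labels = np.asarray(labels)
    if len(g) != len(labels):
        raise ValueError("g_values and labels differ in length")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("both classes are required for Platt scaling")
    t = platt_targets(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == -1))
    A, B = -1.0, float(np.log((n0 + 1.0) / (n1 + 1.0)))
    obj = _platt_objective(A, B, g, t)
    for _ in range(max_iter):
        h = A * g + B
        p = expit(-h)  # current sigmoid value 1/(1+e^h)
        r = p - t  # dLL/dh
        grad = np.array([np.sum(r * g), np.sum(r)])
        if np.max(np.abs(grad)) <= tol:
            return PlattCalibration(A, B)
        w = p * (1.0 - p)
        H = np.array(
            [[np.sum(w * g * g), np.sum(w * g)], [np.sum(w * g), np.sum(w)]]
        )
        H[0, 0] += 1e-12
        H[1, 1] += 1e-12
        step = np.linalg.solve(H, grad)
        lam = 1.0
        for _ in range(30):
            A_new, B_new = A + lam * step[0], B + lam * step[1]
            obj_new = _platt_objective(A_new, B_new, g, t)
            if obj_new >= obj - 1e-15:
                break
            lam *= 0.5
        A, B, obj = A_new, B_new, obj_new
    h = A * g + B
    r = expit(-h) - t
    grad = np.array([np.sum(r * g), np.sum(r)])
    if np.max(np.abs(grad)) > 1e-6:
        raise RuntimeError(
            f"Platt scaling did not converge: gradient {grad} after {max_iter} "
            "Newton iterations"
        )
    return PlattCalibration(A, B)


def platt_probability(calib: PlattCalibration, g) -> np.ndarray | float:
    """pi = 1 / (1 + exp(A g + B)), in (0, 1)."""
    val = expit(-(calib.A * np.asarray(g, dtype=float) + calib.B))
    tiny = np.finfo(float).tiny
    val = np.clip(val, tiny, 1.0 - 1e-16)
    return float(val) if np.ndim(g) == 0 else val


def data_driven_gamma_grid(points: np.ndarray) -> np.ndarray:
    """Seven-point grid {gamma0 * 2^k, k = -3..3} around the median heuristic
    gamma0 = 1 / median{||z_i - z_j||^2, i < j}."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("need at least two points")
    sq = (
        np.sum(points**2, axis=1)[:, None]
        + np.sum(points**2, axis=1)[None, :]
        - 2.0 * points @ points.T
    )
    iu = np.triu_indices(points.shape[0], k=1)
    med = float(np.median(np.maximum(sq[iu], 0.0)))
    if med <= 0:
        raise ValueError("zero median distance: all points identical")
    gamma0 = 1.0 / med
    return gamma0 * 2.0 ** np.arange(-3, 4)


def tune_hyperparameters(
    points: np.ndarray,
    labels: np.ndarray,
    gamma_grid,
    Q_grid,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Grid search minimizing stratified-CV misclassification rate.

    Ties are broken toward smaller Q, then smaller gamma.  The fold count is
    reduced to the minority-class size when necessary (stratified folds with
    both classes present are required; fewer than two minority members is an
    error).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes are required for tuning")
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("stratified cross-validation impossible: minority class < 2")
    n_splits = min(folds, min_count)
    if n_splits < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed))
    splits = list(skf.split(points, labels))
    best = None
    for gamma in gamma_grid:
        for Q in Q_grid:
            errs = []
            for tr, te in splits:
                clf = SVC(C=Q, kernel="rbf", gamma=gamma)
                clf.fit(points[tr], labels[tr])
                errs.append(np.mean(clf.predict(points[te]) != labels[te]))
            err = float(np.mean(errs))
            key = (err, Q, gamma)
            if best is None or key < best:
                best = key
    return best[2], best[1]


def impute_and_estimate_pi(
    z: np.ndarray,
    right_censored: np.ndarray,
    weights: np.ndarray,
    gamma: float,
    Q: float,
    M: int,
    rng: np.random.Generator,
    max_redraws: int = 10,
) -> IncidenceEstimate:
    """M-step for the incidence: impute labels, fit SVM + Platt, average.

    For each of the M imputations, cured statuses of right-censored subjects
    are drawn from Bernoulli(w_i); non-right-censored subjects are fixed
    uncured (V = +1).  A draw that produces a single class is redrawn a
    bounded number of times, then repaired by flipping the right-censored
    subject whose weight is closest to 1/2.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    rc = np.asarray(right_censored, dtype=bool)
    w = np.asarray(weights, dtype=float)
    n = z.shape[0]
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    if np.any(~rc & (w < 1.0)):
        raise ValueError("weights must equal 1 for non-right-censored subjects")
    rules, calibs, pis = [], [], []
    for _ in range(M):
        V = np.ones(n)
        for _attempt in range(max_redraws + 1):
            draws = rng.random(rc.sum()) < w[rc]
            V[rc] = np.where(draws, 1.0, -1.0)
            if len(np.unique(V)) == 2:
                break
        if len(np.unique(V)) < 2:
            if np.any(rc):
                flip = np.flatnonzero(rc)[np.argmin(np.abs(w[rc] - 0.5))]
                V[flip] = -V[flip]
            else:
                # No imputable subject: every label is observed uncured.  Use
                # the constant shrunken-target probability (n+1)/(n+2).
                p_const = (n + 1.0) / (n + 2.0)
                rule = DecisionRule(
                    c=np.zeros(1),
                    V=np.ones(1),
                    support_points=z[:1],
                    b=0.0,
                    gamma=float(gamma),
                    Q=float(Q),
                )
                calib = PlattCalibration(A=0.0, B=float(np.log((1 - p_const) / p_const)))
                rules.append(rule)
                calibs.append(calib)
                pis.append(np.full(n, p_const))
                continue
        rule = svm_train(z, V, Q=Q, gamma=gamma)
        g = rule.decision_value(z)
        calib = platt_fit(g, V)
        rules.append(rule)
        calibs.append(calib)
        pis.append(platt_probability(calib, g))
    return IncidenceEstimate(
        pi_hat=np.mean(pis, axis=0),
        rules=rules,
        calibrations=calibs,
        gamma=float(gamma),
        Q=float(Q),
    )
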