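"""Evaluation metrics for cure-model fits.

Covers the population survival decomposition S_p(t|x,z) = 1 - pi(z) +
pi(z) S(t|x), per-replication bias and MSE of estimated quantities against
simulation truth, rank-based ROC/AUC for cure discrimination with known
labels, the simulation-based averaged ROC when cure labels are unknown
(cured statuses drawn repeatedly from their posterior), and minority-class
oversampling for imbalanced training sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .em import FitResult, e_step
from .latency import _power_survival
from .simulate import ScenarioSpec, SimulationTruth, scenario_pi
from .turnbull import baseline_survival_at
from .types import Dataset

__all__ = [
    "MetricReport",
    "population_survival",
    "bias_mse",
    "roc_auc",
    "roc_points",
    "simulated_label_roc",
    "oversample_minority",
    "survival_errors",
    "survival_bias_mse",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class MetricReport:
    """Bias and MSE averaged across Monte-Carlo replications."""

    bias: float
    mse: float
    n_reps: int
    scenario: int | None = None
    model: str | None = None


def population_survival(pi, s_cond):
    """S_p = 1 - pi + pi * S(t|x): the improper mixture survival function."""
    pi = np.asarray(pi, dtype=float)
    s_cond = np.asarray(s_cond, dtype=float)
    if np.any((pi < 0) | (pi > 1)) or np.any((s_cond < 0) | (s_cond > 1)):
        raise ValueError("pi and s_cond must lie in [0, 1]")
    out = 1.0 - pi + pi * s_cond
    return float(out) if out.ndim == 0 else out


def bias_mse(
    estimates_per_rep,
    truths_per_rep,
    scenario: int | None = None,
    model: str | None = None,
) -> MetricReport:
    """Per replication: mean_i(est - truth) and mean_i(est - truth)^2;
    reported values are the means of these across replications."""
    if len(estimates_per_rep) == 0:
        raise ValueError("no replications supplied")
    biases, mses = [], []
    for est, tru in zip(estimates_per_rep, truths_per_rep, strict=True):
        d = np.asarray(est, dtype=float) - np.asarray(tru, dtype=float)
        if len(d) == 0:
            raise ValueError("empty replication")
        biases.append(float(np.mean(d)))
        mses.append(float(np.mean(d**2)))
    return MetricReport(
        bias=float(np.mean(biases)),
        mse=float(np.mean(mses)),
        n_reps=len(biases),
        scenario=scenario,
        model=model,
    )


def roc_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + P(tie)/2, by the rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes are required for AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(scores, labels):
    """ROC curve points (fpr, tpr) with labels in {0, 1}."""
    fpr, tpr, _ = _sk_roc_curve(np.asarray(labels), np.asarray(scores))
    return fpr, tpr


def simulated_label_roc(
    fit: FitResult,
    dataset: Dataset,
    n_draws: int = 500,
    rng: np.random.Generator | None = None,
) -> dict:
    """Averaged ROC/AUC when true cure labels are unknown.

    For each draw, cured statuses of right-censored subjects are sampled
    from their posterior uncured probability (the E-step weight at the
    fitted parameters); left/interval-censored subjects are known uncured.
    The fitted pi-hat is scored against the drawn labels; AUC is averaged
    over draws and the ROC curve is vertically averaged on a fixed
    false-positive-rate grid.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    # pi evaluated on THIS dataset (identical to fit.pi_hat on the training
    # set, and well-defined on held-out subjects)
    pi = np.asarray(fit.predict_pi(dataset.z), dtype=float)
    w = e_step(dataset, pi, fit.beta_hat, fit.baseline).w
    rc = dataset.right_censored
    score = pi
    aucs, tprs = [], []
    skipped = 0
    for _ in range(n_draws):
        labels = np.asarray(dataset.observed_uncured, dtype=int).copy()
        labels[rc] = (rng.random(rc.sum()) < w[rc]).astype(int)
        if labels.min() == labels.max():
            skipped += 1
            continue
        aucs.append(roc_auc(score, labels))
        fpr, tpr = roc_points(score, labels)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    if skipped > 0.5 * n_draws:
        raise RuntimeError(f"{skipped}/{n_draws} draws had a single class")
    return {
        "auc": float(np.mean(aucs)),
        "auc_se": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs)))
        if len(aucs) > 1
        else 0.0,
        "fpr": FPR_GRID,
        "tpr": np.mean(tprs, axis=0),
        "n_draws_used": len(aucs),
        "n_skipped": skipped,
    }


def oversample_minority(
    dataset: Dataset, rng: np.random.Generator
) -> tuple[Dataset, np.ndarray]:
    """Balance classes (by the delta1 + delta2 uncured proxy) by duplicating
    minority-class subjects sampled with replacement; all original subjects
    are retained.  Returns the balanced dataset and the row indices into the
    original dataset."""
    lab = np.asarray(dataset.observed_uncured)
    n1, n0 = int((lab == 1).sum()), int((lab == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both censoring classes are required")
    if n1 == n0:
        idx = np.arange(dataset.n)
        return dataset, idx
    minority = np.flatnonzero(lab == (1 if n1 < n0 else 0))
    extra = rng.choice(minority, size=abs(n1 - n0), replace=True)
    idx = np.concatenate([np.arange(dataset.n), extra])
    return dataset.subset(idx), idx


def _eval_times(dataset: Dataset) -> np.ndarray:
    """Default survival evaluation time per subject: the last finite
    examination endpoint (u_left for right-censored, u_right otherwise)."""
    return np.where(dataset.right_censored, dataset.u_left, dataset.u_right)


def survival_errors(
    dataset: Dataset,
    truth: SimulationTruth,
    spec: ScenarioSpec,
    pi_hat: np.ndarray,
    beta_hat: np.ndarray,
    baseline,
    eval_times: np.ndarray | None = None,
) -> dict:
    """Per-dataset errors of fitted overall (S_p) and susceptible (S)
    survival probabilities against the generating truth, each subject
    evaluated at its own time."""
    t = _eval_times(dataset) if eval_times is None else np.asarray(eval_times)
    s0 = np.asarray(baseline_survival_at(baseline, t), dtype=float)
    with np.errstate(over="ignore"):
        e_hat = np.exp(np.clip(dataset.x @ np.asarray(beta_hat), -700, 700))
        e_true = np.exp(np.clip(dataset.x @ spec.beta_true, -700, 700))
    s_fit = _power_survival(s0, e_hat)
    s_true = np.exp(-e_true * np.minimum(t, 1e300) ** spec.alpha)
    sp_fit = population_survival(pi_hat, s_fit)
    sp_true = population_survival(truth.pi_true, s_true)
    return {
        "overall_err": sp_fit - sp_true,
        "susceptible_err": s_fit - s_true,
    }


def survival_bias_mse(
    per_rep_errors: list[dict],
    scenario: int | None = None,
    model: str | None = None,
) -> tuple[MetricReport, MetricReport]:
    """Aggregate outputs of :func:`survival_errors` across replications into
    (overall, susceptible) metric reports."""
    overall = bias_mse(
        [d["overall_err"] for d in per_rep_errors],
        [np.zeros_like(d["overall_err"]) for d in per_rep_errors],
        scenario,
        model,
    )
    susceptible = bias_mse(
        [d["susceptible_err"] for d in per_rep_errors],
        [np.zeros_like(d["susceptible_err"]) for d in per_rep_errors],
        scenario,
        model,
    )
    return overall, susceptible
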