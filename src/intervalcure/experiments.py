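"""Scripted Monte-Carlo studies and the real-data-style workflow.

`run_simulation_study` repeats, for a chosen scenario: generate a dataset,
split it into training and testing sets (stratified on censoring type),
fit the requested cure models on the training set, and score them —
bias/MSE of the fitted uncured probabilities, training/testing AUC against
the true cure labels, and bias/MSE of the fitted overall and susceptible
survival probabilities.  `run_hdsd_like_workflow` exercises the end-to-end
pipeline used for imbalanced observational data: train/test split,
minority-class oversampling, EM fit, bootstrap standard errors, an uncured
probability surface, and the simulation-based averaged ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import EMConfig, bootstrap_se, fit_mcm_svm
from .evaluate import (
    bias_mse,
    oversample_minority,
    roc_auc,
    simulated_label_roc,
    survival_bias_mse,
    survival_errors,
)
from .logit import fit_mcm_logit
from .simulate import generate_dataset, generate_hdsd_like, scenario_spec
from .types import Dataset

__all__ = ["ExperimentConfig", "run_simulation_study", "run_hdsd_like_workflow"]

_FITTERS = {"svm": fit_mcm_svm, "logit": fit_mcm_logit}


@dataclass
class ExperimentConfig:
    """Scale and contents of one Monte-Carlo study."""

    scenario: int = 1
    n: int = 300
    reps: int = 200
    train_fraction: float = 2.0 / 3.0
    models: tuple = ("svm", "logit")
    seed: int = 0
    em: EMConfig = field(default_factory=lambda: EMConfig(max_iter=10))
    max_retries: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.models) - set(_FITTERS)
        if unknown:
            raise ValueError(f"unknown models: {unknown}")


def stratified_split(
    dataset: Dataset, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test indices, stratified on censoring type so each split stays
    fittable."""
    strata = dataset.delta1 * 1 + dataset.delta2 * 2  # 0 = right censored
    train_parts = []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        k = int(round(train_fraction * len(idx)))
        train_parts.append(idx[:k])
    train = np.sort(np.concatenate(train_parts))
    test = np.setdiff1d(np.arange(dataset.n), train)
    return train, test


def run_simulation_study(config: ExperimentConfig) -> pd.DataFrame:
    """Monte-Carlo study for one scenario; one result row per model.

    A replication whose fit raises is logged, dropped, and replaced by a
    freshly generated dataset (bounded retries); the replacement count is
    reported in the ``n_resampled`` column.
    """
    spec = scenario_spec(config.scenario)
    master = np.random.default_rng(config.seed)
    acc = {
        m: {"pi_err": [], "auc_train": [], "auc_test": [], "surv": [],
            "beta": []}
        for m in config.models
    }
    resampled = 0
    rep = 0
    while rep < config.reps:
        rng = np.random.default_rng(master.integers(2**31 - 1))
        for attempt in range(config.max_retries + 1):
            try:
                dataset, truth = generate_dataset(spec, config.n, rng)
                tr_idx, te_idx = stratified_split(
                    dataset, config.train_fraction, rng
                )
                train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
                truth_tr, truth_te = truth.subset(tr_idx), truth.subset(te_idx)
                rep_out = {}
                for m in config.models:
                    fit = _FITTERS[m](train, config.em, rng)
                    pi_err = fit.pi_hat - truth_tr.pi_true
                    auc_tr = roc_auc(fit.pi_hat, truth_tr.J_true)
                    auc_te = roc_auc(fit.predict_pi(test.z), truth_te.J_true)
                    surv = survival_errors(
                        train, truth_tr, spec, fit.pi_hat, fit.beta_hat,
                        fit.baseline,
                    )
                    rep_out[m] = (pi_err, auc_tr, auc_te, surv,
                                  fit.beta_hat)
                break
            except Exception as exc:  # noqa: BLE001 - logged and resampled
                warnings.warn(
                    f"replication failed ({exc}); resampling", RuntimeWarning
                )
                resampled += 1
                if attempt == config.max_retries:
                    raise
        for m, (pi_err, auc_tr, auc_te, surv, beta) in rep_out.items():
            acc[m]["pi_err"].append(pi_err)
            acc[m]["auc_train"].append(auc_tr)
            acc[m]["auc_test"].append(auc_te)
            acc[m]["surv"].append(surv)
            acc[m]["beta"].append(beta)
        rep += 1
    rows = []
    for m in config.models:
        zeros = [np.zeros_like(e) for e in acc[m]["pi_err"]]
        pi_rep = bias_mse(acc[m]["pi_err"], zeros, config.scenario, m)
        overall, susceptible = survival_bias_mse(
            acc[m]["surv"], config.scenario, m
        )
        beta_mean = np.mean(acc[m]["beta"], axis=0)
        rows.append(
            {
                "scenario": config.scenario,
                "n": config.n,
                "model": m,
                "bias_pi": pi_rep.bias,
                "mse_pi": pi_rep.mse,
                "auc_train": float(np.mean(acc[m]["auc_train"])),
                "auc_test": float(np.mean(acc[m]["auc_test"])),
                "bias_overall": overall.bias,
                "mse_overall": overall.mse,
                "bias_susceptible": susceptible.bias,
                "mse_susceptible": susceptible.mse,
                "n_reps": config.reps,
                "n_resampled": resampled,
                **{f"beta{j + 1}_mean": float(b)
                   for j, b in enumerate(beta_mean)},
            }
        )
    return pd.DataFrame(rows)


def run_hdsd_like_workflow(
    dataset: Dataset | None = None,
    config: EMConfig | None = None,
    rng: np.random.Generator | None = None,
    train_fraction: float = 0.7,
    n_roc_draws: int = 500,
    bootstrap: bool = True,
) -> dict:
    """End-to-end pipeline on (synthetic) observational data.

    Splits 70/30, oversamples the minority censoring class in the training
    set, fits the SVM cure model, and reports latency estimates with
    bootstrap standard errors, an uncured-probability surface over
    (Age, Sex), and the simulation-based averaged ROC/AUC.
    """
    config = config or EMConfig(max_iter=10)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if dataset is None:
        dataset, _ = generate_hdsd_like(rng=rng)
    tr_idx, te_idx = stratified_split(dataset, train_fraction, rng)
    train = dataset.subset(tr_idx)
    test = dataset.subset(te_idx)
    balanced, _ = oversample_minority(train, rng)
    fit = fit_mcm_svm(balanced, config, rng)
    se = None
    n_failed = 0
    if bootstrap:
        se, n_failed = bootstrap_se(balanced, config, rng)
    ages = np.linspace(20.0, 54.0, 35)
    surface = {
        "age": ages,
        "pi_male": fit.predict_pi(np.column_stack([ages, np.ones_like(ages)])),
        "pi_female": fit.predict_pi(np.column_stack([ages, np.zeros_like(ages)])),
    }
    roc = simulated_label_roc(fit, train, n_draws=n_roc_draws, rng=rng)
    return {
        "fit": fit,
        "beta_hat": fit.beta_hat,
        "se": se,
        "n_failed_bootstrap": n_failed,
        "x_names": dataset.x_names,
        "pi_surface": surface,
        "roc": roc,
        "train_index": tr_idx,
        "test_index": te_idx,
        "test_dataset": test,
    }
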