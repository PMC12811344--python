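"""Core data model for mixed-case interval-censored cure data.

A subject is observed only through a censoring interval ``(u_left, u_right]``
that contains the (latent) event time, together with indicators for left
censoring (``delta1``, event before the first examination) and interval
censoring (``delta2``); right-censored subjects have ``u_right = inf`` and
``delta1 = delta2 = 0``.  Incidence covariates ``z`` drive the probability of
being uncured, latency covariates ``x`` drive the event time of the uncured.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservedSubject",
    "Dataset",
    "CuredStatus",
    "EMConfig",
    "validate_dataset",
    "read_dataset_csv",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class ObservedSubject:
    """One subject's censoring interval, indicators, and covariates."""

    u_left: float
    u_right: float
    delta1: int
    delta2: int
    x: np.ndarray
    z: np.ndarray

    @property
    def right_censored(self) -> bool:
        return self.delta1 == 0 and self.delta2 == 0


@dataclass(frozen=True)
class CuredStatus:
    """Cured/uncured label; J = 1 means uncured (susceptible), V = 2J - 1."""

    J: int
    known: bool

    @property
    def V(self) -> int:
        return 2 * self.J - 1


@dataclass
class EMConfig:
    """Knobs of the EM estimation procedure.

    M : number of multiple imputations of the missing cured statuses.
    epsilon : squared-L2 convergence tolerance on the concatenated
        (pi-vector, beta) parameter.
    gamma_grid / Q_grid : SVM hyperparameter grids for cross-validated tuning;
        ``gamma_grid=None`` requests the data-driven median-distance grid.
    cv_folds : folds of the (stratified) tuning cross-validation.
    bootstrap_B : resamples for bootstrap standard errors.
    """

    M: int = 5
    epsilon: float = 1e-3
    max_iter: int = 50
    gamma_grid: Sequence[float] | None = (2.0**-6, 2.0**-5, 2.0**-4)
    Q_grid: Sequence[float] = (2.0**4, 2.0**5, 2.0**6)
    cv_folds: int = 10
    seed: int = 0
    bootstrap_B: int = 100
    retune_every_iter: bool = False
    normalize_criterion: bool = False

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.gamma_grid is not None and len(tuple(self.gamma_grid)) == 0:
            raise ValueError("gamma_grid must be non-empty")
        if len(tuple(self.Q_grid)) == 0:
            raise ValueError("Q_grid must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["gamma_grid"] is not None:
            d["gamma_grid"] = list(d["gamma_grid"])
        d["Q_grid"] = list(d["Q_grid"])
        return d


class Dataset:
    """Array-backed collection of :class:`ObservedSubject`.

    Parameters are validated against the censoring-type invariants: exactly
    one of left/interval/right censoring holds for every subject, and at
    least one subject is not right-censored.
    """

    def __init__(
        self,
        u_left: np.ndarray,
        u_right: np.ndarray,
        delta1: np.ndarray,
        delta2: np.ndarray,
        x: np.ndarray,
        z: np.ndarray,
        x_names: Sequence[str] | None = None,
        z_names: Sequence[str] | None = None,
    ) -> None:
        self.u_left = np.asarray(u_left, dtype=float)
        self.u_right = np.asarray(u_right, dtype=float)
        self.delta1 = np.asarray(delta1, dtype=int)
        self.delta2 = np.asarray(delta2, dtype=int)
        self.x = np.atleast_2d(np.asarray(x, dtype=float))
        self.z = np.atleast_2d(np.asarray(z, dtype=float))
        if self.x.shape[0] != len(self.u_left):
            self.x = self.x.T
        if self.z.shape[0] != len(self.u_left):
            self.z = self.z.T
        self.x_names = list(x_names) if x_names is not None else [
            f"x{i+1}" for i in range(self.x.shape[1])
        ]
        self.z_names = list(z_names) if z_names is not None else [
            f"z{i+1}" for i in range(self.z.shape[1])
        ]
        self._validate()

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.u_left)
        for name, arr in (
            ("u_right", self.u_right),
            ("delta1", self.delta1),
            ("delta2", self.delta2),
        ):
            if len(arr) != n:
                raise ValueError(f"length mismatch in column {name}")
        if self.x.shape != (n, len(self.x_names)):
            raise ValueError("x matrix shape does not match x_names")
        if self.z.shape != (n, len(self.z_names)):
            raise ValueError("z matrix shape does not match z_names")
        if np.any(~np.isfinite(self.u_left)) or np.any(self.u_left < 0):
            raise ValueError("u_left must be finite and >= 0")
        if np.any(np.isnan(self.u_right)) or np.any(self.u_right < 0):
            raise ValueError("u_right must be >= 0 (inf allowed)")
        if not np.all(np.isin(self.delta1, (0, 1))) or not np.all(
            np.isin(self.delta2, (0, 1))
        ):
            raise ValueError("delta indicators must be 0/1")
        if np.any(self.delta1 + self.delta2 > 1):
            raise ValueError("delta1 + delta2 must be in {0, 1}")
        finite_r = np.isfinite(self.u_right)
        bad = finite_r & (self.u_left >= self.u_right)
        if np.any(bad):
            raise ValueError("u_left >= u_right for a finite interval")
        lc = self.delta1 == 1
        if np.any(lc & ((self.u_left != 0) | ~finite_r)):
            raise ValueError("delta1 = 1 requires u_left = 0 and finite u_right")
        ic = self.delta2 == 1
        if np.any(ic & ((self.u_left <= 0) | ~finite_r)):
            raise ValueError("delta2 = 1 requires 0 < u_left < u_right < inf")
        rc = (self.delta1 == 0) & (self.delta2 == 0)
        if np.any(rc & ((self.u_left <= 0) | finite_r)):
            raise ValueError(
                "right-censored subjects require u_left > 0 and u_right = inf"
            )
        if not np.any(~rc):
            raise ValueError("dataset needs at least one non-right-censored subject")

    # -- container protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.u_left)

    @property
    def n(self) -> int:
        return len(self.u_left)

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def q(self) -> int:
        return self.z.shape[1]

    @property
    def right_censored(self) -> np.ndarray:
        return (self.delta1 == 0) & (self.delta2 == 0)

    @property
    def observed_uncured(self) -> np.ndarray:
        """delta1 + delta2: 1 for subjects known to be uncured."""
        return self.delta1 + self.delta2

    def subject(self, i: int) -> ObservedSubject:
        return ObservedSubject(
            float(self.u_left[i]),
            float(self.u_right[i]),
            int(self.delta1[i]),
            int(self.delta2[i]),
            self.x[i].copy(),
            self.z[i].copy(),
        )

    def __iter__(self) -> Iterator[ObservedSubject]:
        return (self.subject(i) for i in range(self.n))

    def subset(self, idx: np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            self.u_left[idx],
            self.u_right[idx],
            self.delta1[idx],
            self.delta2[idx],
            self.x[idx],
            self.z[idx],
            self.x_names,
            self.z_names,
        )

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {
            "u_left": self.u_left,
            "u_right": self.u_right,
            "delta1": self.delta1,
            "delta2": self.delta2,
        }
        for j, name in enumerate(self.x_names):
            data[f"x_{name}"] = self.x[:, j]
        for j, name in enumerate(self.z_names):
            data[f"z_{name}"] = self.z[:, j]
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        write_dataset_csv(self, path)

    def __eq__(self, other) -> bool:  # structural equality, used in round-trips
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.u_left, other.u_left)
            and np.array_equal(self.u_right, other.u_right)
            and np.array_equal(self.delta1, other.delta1)
            and np.array_equal(self.delta2, other.delta2)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.z, other.z)
            and self.x_names == other.x_names
            and self.z_names == other.z_names
        )


def validate_dataset(raw) -> Dataset:
    """Build a :class:`Dataset` from tabular records.

    Accepts a DataFrame (or anything ``pd.DataFrame`` accepts) with columns
    ``u_left``, ``u_right``, optional ``delta1``/``delta2`` and covariate
    columns prefixed ``x_``/``z_``.  ``u_right`` given as the string ``"inf"``
    (any case) or left empty parses to +infinity.  Missing delta columns are
    derived from the interval: delta1 = [u_left = 0], delta2 = [0 < u_left,
    u_right finite].
    """
    df = raw if isinstance(raw, pd.DataFrame) else pd.DataFrame(raw)
    for col in ("u_left", "u_right"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    def _coerce_inf(v) -> float:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.inf
        if isinstance(v, str):
            s = v.strip()
            if s == "" or s.lower() == "inf":
                return np.inf
            return float(s)
        return float(v)

    u_left = df["u_left"].astype(float).to_numpy()
    u_right = np.array([_coerce_inf(v) for v in df["u_right"]], dtype=float)
    finite_r = np.isfinite(u_right)
    if "delta1" in df.columns and "delta2" in df.columns:
        delta1 = df["delta1"].astype(int).to_numpy()
        delta2 = df["delta2"].astype(int).to_numpy()
    else:
        delta1 = ((u_left == 0) & finite_r).astype(int)
        delta2 = ((u_left > 0) & finite_r).astype(int)
    x_cols = [c for c in df.columns if c.startswith("x_")]
    z_cols = [c for c in df.columns if c.startswith("z_")]
    if not x_cols or not z_cols:
        raise ValueError("need at least one x_ and one z_ covariate column")
    x = df[x_cols].astype(float).to_numpy()
    z = df[z_cols].astype(float).to_numpy()
    return Dataset(
        u_left,
        u_right,
        delta1,
        delta2,
        x,
        z,
        [c[2:] for c in x_cols],
        [c[2:] for c in z_cols],
    )


def read_dataset_csv(path) -> Dataset:
    return validate_dataset(
        pd.read_csv(path, dtype={"u_right": str}, float_precision="round_trip")
    )


def write_dataset_csv(dataset: Dataset, path) -> None:
    df = dataset.to_frame()
    df["u_right"] = [
        "inf" if not np.isfinite(v) else repr(float(v)) for v in df["u_right"]
    ]
    for col in df.columns:
        if df[col].dtype == float:  # exact round-trip via shortest repr
            df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False)
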