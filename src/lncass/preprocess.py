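"""Deterministic data transforms: log(1+x), unit-interval scaling,
standardization, and the univariate Wald screen for p >> n classification.

Every fitted transform returns a :class:`TransformRecord` carrying the
training-set constants so the identical transform can be re-applied to new
data (e.g. test folds) without leaking their statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import RegressionDataset

__all__ = [
    "TransformRecord",
    "log1p_columns",
    "scale_unit_interval",
    "standardize_columns",
    "wald_screen",
    "read_design_csv",
]


@dataclass
class TransformRecord:
    """Fitted per-column constants of a deterministic transform."""

    kind: str
    constants: dict[str, np.ndarray] = field(default_factory=dict)
    clamp_warnings: int = 0

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "constants": {k: np.asarray(v).tolist() for k, v in self.constants.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "TransformRecord":
        d = json.loads(s)
        return cls(
            kind=d["kind"],
            constants={k: np.asarray(v, dtype=float) for k, v in d["constants"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TransformRecord":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def log1p_columns(X) -> np.ndarray:
    """Elementwise log(1 + x); rejects negative entries by position."""
    X = _as_matrix(X)
    neg = np.argwhere(X < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"log1p requires non-negative entries; first negative at row {r}, column {c}"
        )
    return np.log1p(X)


def scale_unit_interval(X, record: TransformRecord | None = None):
    """Min-max scale each column to [0, 1].

    Fitting stores per-column minima/maxima; re-application uses the stored
    constants and clamps out-of-range values into [0, 1], counting the clamps
    on the returned record.
    """
    X = _as_matrix(X)
    if record is None:
        mins = X.min(axis=0)
        maxs = X.max(axis=0)
        const = np.flatnonzero(maxs - mins == 0)
        if const.size:
            raise ValueError(f"constant column(s) at fit time: {const.tolist()}")
        record = TransformRecord("unit_interval", {"min": mins, "max": maxs})
    else:
        if record.kind != "unit_interval":
            raise ValueError(f"record kind {record.kind!r} is not 'unit_interval'")
        mins = record.constants["min"]
        maxs = record.constants["max"]
    out = (X - mins) / (maxs - mins)
    n_clamped = int(np.count_nonzero((out < 0.0) | (out > 1.0)))
    record.clamp_warnings += n_clamped
    return np.clip(out, 0.0, 1.0), record


def standardize_columns(X, record: TransformRecord | None = None):
    """Center and scale columns to mean 0, sd 1 (sample sd, denominator n-1)."""
    X = _as_matrix(X)
    if record is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s) at fit time: {zero.tolist()}")
        record = TransformRecord("standardize", {"mean": means, "sd": sds})
    else:
        if record.kind != "standardize":
            raise ValueError(f"record kind {record.kind!r} is not 'standardize'")
        means = record.constants["mean"]
        sds = record.constants["sd"]
    return (X - means) / sds, record


def _univariate_wald_z(x: np.ndarray, y: np.ndarray, ridge: float = 1.0) -> float:
    """|Z| of the slope in a univariate logistic fit (intercept + x).

    Newton iterations with a unit ridge penalty (equivalent to a weak N(0,1)
    prior on the log-odds scale) on both parameters; the ridge keeps the fit
    and its standard error finite under perfect separation, where the
    unpenalized Wald statistic degenerates.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(50):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        hess = X.T @ (X * w[:, None]) + ridge * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1.0 - mu)
    hess = X.T @ (X * w[:, None]) + ridge * np.eye(2)
    se = np.sqrt(np.linalg.inv(hess)[1, 1])
    return abs(beta[1]) / se


def wald_screen(data: RegressionDataset, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank predictors by univariate Wald |Z| and keep the top k.

    Returns (indices, |Z| scores), both sorted by |Z| descending; exact ties
    break toward the lower predictor index.
    """
    if data.family != "binomial":
        raise ValueError("wald_screen requires a binomial dataset")
    p = data.p
    if not (1 <= k <= p):
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    z = np.array(
        [_univariate_wald_z(data.X[:, j], data.y) for j in range(p)]
    )
    order = np.argsort(-z, kind="stable")
    top = order[:k]
    return top, z[top]


def read_design_csv(path, *, sep: str = ",", id_column: bool | None = None):
    """Read a CSV/TSV design matrix with a header row.

    If the first column is non-numeric (or ``id_column=True``) it is treated
    as an observation identifier.  Returns (X matrix, column names, ids).
    """
    df = pd.read_csv(path, sep=sep)
    ids = None
    first = df.columns[0]
    if id_column is None:
        id_column = not pd.api.types.is_numeric_dtype(df[first])
    if id_column:
        ids = df[first].astype(str).to_numpy()
        df = df.drop(columns=[first])
    if df.isna().any().any():
        raise ValueError(
            "input contains missing values; impute upstream (e.g. with mice in R) "
            "before fitting"
        )
    return df.to_numpy(dtype=float), list(df.columns), ids
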