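"""Performance measures and cross-validation drivers.

AUC follows the Mann–Whitney convention (ties count one half), which makes
the trapezoidal area under the ROC curve exactly equal to the pairwise
concordance probability: the chance that a randomly chosen positive case
receives a larger score than a randomly chosen negative case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .models import RegressionDataset

__all__ = [
    "ROCResult",
    "CVPlan",
    "CVResult",
    "roc_auc",
    "pairwise_concordance_auc",
    "mae",
    "sparsity_recovery_auc",
    "make_folds",
    "run_cv",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _validate_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("AUC is undefined for single-class labels")
    return labels.astype(int)


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC; ties handled Mann–Whitney style."""
    scores = np.asarray(scores, dtype=float)
    labels = _validate_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=area)


def pairwise_concordance_auc(scores, labels) -> float:
    """AUC as the mean over (positive, negative) pairs of concordance.

    Computed through the rank-sum (Mann–Whitney U) statistic with midranks,
    which is algebraically the pairwise mean with ties counting one half —
    an independent route from the trapezoidal curve integration above.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _validate_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mae(estimates, truth) -> float:
    """Mean absolute difference between two equal-length vectors."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {estimates.shape} vs {truth.shape}"
        )
    return float(np.mean(np.abs(estimates - truth)))


def sparsity_recovery_auc(beta_hat, beta_true) -> float:
    """AUC of |beta_hat| against the zero/non-zero pattern of beta_true.

    Measures whether truly non-zero parameters are estimated larger in
    absolute value than truly zero ones.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("beta_hat and beta_true must have equal length")
    labels = (beta_true != 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("truth must contain both zero and non-zero entries")
    return roc_auc(np.abs(beta_hat), labels).auc


@dataclass
class CVPlan:
    """Cross-validation layout: repeated k-fold or (class-balanced) LOOCV."""

    scheme: str = "kfold"  # kfold | loocv
    folds: int = 10
    repeats: int = 1
    class_balance: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("kfold", "loocv"):
            raise ValueError("scheme must be 'kfold' or 'loocv'")
        if self.scheme == "kfold" and self.folds < 2:
            raise ValueError("kfold needs folds >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def make_folds(plan: CVPlan, y: np.ndarray) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per-repeat lists of (train_idx, test_idx); test sets partition 0..n-1.

    With ``class_balance`` under LOOCV, each training set additionally drops
    one randomly chosen observation of the class opposite to the held-out one
    (fold-indexed seed), so the class proportions are identical across folds.
    k-fold with ``class_balance`` stratifies by class.
    """
    y = np.asarray(y)
    n = y.size
    out = []
    for rep in range(plan.repeats):
        rep_folds = []
        if plan.scheme == "loocv":
            for i in range(n):
                train = np.delete(np.arange(n), i)
                if plan.class_balance:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([plan.seed, rep, i])
                    )
                    opposite = train[y[train] != y[i]]
                    if opposite.size == 0:
                        raise ValueError("class balancing impossible: one class absent")
                    drop = rng.choice(opposite)
                    train = train[train != drop]
                rep_folds.append((train, np.array([i])))
        else:
            if plan.folds > n:
                raise ValueError(f"folds={plan.folds} exceeds n={n}")
            if plan.class_balance:
                splitter = StratifiedKFold(
                    n_splits=plan.folds, shuffle=True, random_state=plan.seed + rep
                )
                split_iter = splitter.split(np.zeros(n), y)
            else:
                splitter = KFold(
                    n_splits=plan.folds, shuffle=True, random_state=plan.seed + rep
                )
                split_iter = splitter.split(np.zeros(n))
            rep_folds = [(tr, te) for tr, te in split_iter]
        out.append(rep_folds)
    return out


@dataclass
class CVResult:
    scores: pd.DataFrame  # observation_id, repeat, fold, score, label
    pooled_auc: float  # AUC over all held-out scores
    auc_per_repeat: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.auc_per_repeat.mean())


def run_cv(
    data: RegressionDataset,
    plan: CVPlan,
    fit: Callable[[RegressionDataset], Callable[[np.ndarray], np.ndarray]],
) -> CVResult:
    """Score every observation out-of-fold with a freshly fitted model.

    ``fit`` receives a training :class:`RegressionDataset` and must return a
    scorer mapping a test design matrix to predicted scores.
    """
    if data.family != "binomial":
        raise ValueError("run_cv scores classifiers; need a binomial dataset")
    y = data.y.astype(int)
    folds = make_folds(plan, y)
    rows = []
    for rep, rep_folds in enumerate(folds):
        for fold_id, (train, test) in enumerate(rep_folds):
            scorer = fit(data.subset(rows=train))
            s = np.asarray(scorer(data.X[test]), dtype=float)
            for idx, sc in zip(test, s):
                rows.append((int(idx), rep, fold_id, float(sc), int(y[idx])))
    scores = pd.DataFrame(
        rows, columns=["observation_id", "repeat", "fold", "score", "label"]
    )
    pooled = roc_auc(scores["score"], scores["label"]).auc
    per_rep = np.array(
        [
            roc_auc(g["score"], g["label"]).auc
            for _, g in scores.groupby("repeat", sort=True)
        ]
    )
    return CVResult(scores=scores, pooled_auc=pooled, auc_per_repeat=per_rep)
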