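"""Biomarker-panel evaluation: stratified split, cross-validated random
forest, and rank-statistic ROC analysis.

The harness mirrors the standard diagnostic protocol: samples are split
4:1 into training and held-out test sets (stratified), a random forest is
evaluated by 5-fold cross-validation on the training set (AUC over pooled
out-of-fold scores), then refit on the full training set and scored on the
held-out samples.  Features are log2(TPM + 1)-transformed panel rows.

AUC is computed from the Mann-Whitney rank statistic — the probability
that a random positive outranks a random negative, ties counting one half
— which equals trapezoidal integration of the empirical ROC step curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold, cross_val_predict, train_test_split

from .io import ExpressionMatrix


@dataclass
class PanelEvalConfig:
    split_fraction: float = 0.2  # held-out fraction (4:1 split)
    cv_folds: int = 5
    n_trees: int = 500
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class PanelEvalResult:
    auc_train_cv: float
    auc_test: float
    roc_points: list[tuple[float, float]]
    scores: pd.Series  # held-out predicted probabilities
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by the rank statistic; ties contribute one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC step-curve points (FPR, TPR) from (0,0) to (1,1), plus the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(scores, labels)  # validates classes
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(sorted_scores):
        k = i
        while k < len(sorted_scores) and sorted_scores[k] == sorted_scores[i]:
            k += 1
        tp += int(sorted_labels[i:k].sum())
        fp += int((sorted_labels[i:k] == 0).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = k
    return points, auc


def cross_validated_auc(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    labels: pd.Series,
    cfg: PanelEvalConfig | None = None,
) -> float:
    """Calibration utility: rank AUC over pooled out-of-fold scores.

    Scores every sample by k-fold cross-validation (no held-out split), so
    the AUC is computed at the full cohort size — the appropriate quantity
    when checking null calibration, where a small held-out set would make
    the AUC estimate needlessly noisy.
    """
    cfg = cfg or PanelEvalConfig()
    labels = labels.loc[[s for s in matrix.sample_ids if s in labels.index]]
    y = labels.to_numpy(dtype=int)
    X = np.log2(matrix.values.loc[list(panel), list(labels.index)].to_numpy().T + 1.0)
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1
    )
    oof = cross_val_predict(model, X, y, cv=cv, method="predict_proba")[:, 1]
    return roc_auc(oof, y)


def evaluate_panel(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    labels: pd.Series,
    cfg: PanelEvalConfig | None = None,
) -> PanelEvalResult:
    """Evaluate a transcript panel's ability to separate two sample classes.

    ``labels`` maps every sample id to 0/1.  Raises if a panel transcript is
    missing from the matrix or if only one class is present.
    """
    cfg = cfg or PanelEvalConfig()
    missing = [t for t in panel if t not in set(matrix.transcript_ids)]
    if missing:
        raise KeyError(f"panel transcripts missing from matrix: {missing[:5]}")
    labels = labels.loc[[s for s in matrix.sample_ids if s in labels.index]]
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    X = np.log2(matrix.values.loc[list(panel), list(labels.index)].to_numpy().T + 1.0)
    sample_ids = np.asarray(list(labels.index))

    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=cfg.split_fraction,
        random_state=cfg.seed,
        stratify=y if cfg.stratified else None,
    )
    X_train, y_train = X[idx_train], y[idx_train]
    X_test, y_test = X[idx_test], y[idx_test]

    def make_model() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1
        )

    if cfg.stratified:
        cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    else:
        cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    oof = cross_val_predict(
        make_model(), X_train, y_train, cv=cv, method="predict_proba"
    )[:, 1]
    auc_train_cv = roc_auc(oof, y_train)

    model = make_model()
    model.fit(X_train, y_train)
    test_scores = model.predict_proba(X_test)[:, 1]
    points, auc_test = roc_curve(test_scores, y_test)

    return PanelEvalResult(
        auc_train_cv=auc_train_cv,
        auc_test=auc_test,
        roc_points=points,
        scores=pd.Series(test_scores, index=sample_ids[idx_test]),
        train_samples=list(sample_ids[idx_train]),
        test_samples=list(sample_ids[idx_test]),
    )
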