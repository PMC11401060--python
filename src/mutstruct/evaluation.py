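"""Metrics, cross-validation schemes, MCC-maximizing cutoff calibration,
and two-group rank comparisons.

The Disease-causing class is the positive class throughout. Pooled (not
per-fold-averaged) cross-validation metrics are reported: out-of-fold
predictions are collected and scored once, which is stable with small
per-fold counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "ComparisonResult",
    "mcc_score",
    "compute_metrics",
    "kfold_cv",
    "leave_one_protein_out",
    "optimize_cutoff",
    "PUBLISHED_CUTOFFS",
    "compare_groups",
]

# fixed published decision cutoffs honored when configured instead of calibration
PUBLISHED_CUTOFFS = {
    "sift": (0.05, "low"),      # score below cutoff => pathogenic
    "snap2": (0.0, "high"),
    "provean": (-2.5, "low"),
    "demask": (-0.22, "low"),
    "envision": (0.97, "low"),
    "alphamissense": (0.61, "high"),
    "esm1b": (-8.18, "low"),
    "cpt1": (0.39, "high"),
}


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    bacc: float
    f1: float
    mcc: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float | None
    accuracy: float
    per_protein_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc_score(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Matthews correlation coefficient from hard 0/1 predictions."""
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the tie-corrected rank statistic (Mann-Whitney)."""
    from scipy.stats import rankdata

    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(
    labels,
    probabilities,
    cutoff: float = 0.5,
    groups: list[tuple[str, int]] | None = None,
) -> MetricsReport:
    """Score probabilistic predictions against binary labels.

    AUC is the rank statistic over the raw probabilities; the remaining
    metrics come from the confusion matrix at ``cutoff``. With
    single-class labels AUC is reported as undefined (None); per-protein
    accuracy is filled when ``groups`` is given.
    """
    labels = np.asarray(labels, float)
    probabilities = np.asarray(probabilities, float)
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must align")
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    labels = labels.astype(int)
    pred = (probabilities >= cutoff).astype(int)
    tp = int(np.sum((labels == 1) & (pred == 1)))
    fp = int(np.sum((labels == 0) & (pred == 1)))
    tn = int(np.sum((labels == 0) & (pred == 0)))
    fn = int(np.sum((labels == 1) & (pred == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = _rank_auc(labels, probabilities) if 0 < labels.sum() < len(labels) else None
    per_protein: dict[str, float] = {}
    if groups is not None:
        proteins = np.array([g[0] for g in groups])
        for pid in sorted(set(proteins)):
            mask = proteins == pid
            per_protein[pid] = float((labels[mask] == pred[mask]).mean())
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        bacc=(sens + spec) / 2.0,
        f1=f1,
        mcc=mcc_score(labels, pred),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        auc=auc,
        accuracy=(tp + tn) / len(labels) if len(labels) else 0.0,
        per_protein_accuracy=per_protein,
    )


def kfold_cv(matrix, k: int = 10, config=None, seed: int = 0) -> MetricsReport:
    """Grouped k-fold cross-validation with pooled out-of-fold metrics.

    Folds partition the (protein, position) groups so redundant positions
    never straddle a fold boundary.
    """
    from .modeling import ModelConfig, train

    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or ModelConfig(seed=seed)
    mask = matrix.y.notna().to_numpy()
    groups = [g for g, m in zip(matrix.groups, mask) if m]
    unique_groups = sorted(set(groups))
    if k > len(unique_groups):
        raise ValueError(f"k={k} exceeds {len(unique_groups)} position-groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique_groups))
    fold_of_group = {unique_groups[g]: i % k for i, g in enumerate(order)}
    y = matrix.y[mask].to_numpy()
    pooled = np.full(len(y), np.nan)
    from .dataset import FeatureMatrix

    X = matrix.X[mask]
    folds = np.array([fold_of_group[g] for g in groups])
    for fold in range(k):
        test = folds == fold
        train_mat = FeatureMatrix(
            X[~test], pd.Series(y[~test], index=X.index[~test]),
            [g for g, t in zip(groups, test) if not t],
        )
        model = train(train_mat, config)
        pooled[test] = model.predict_proba(X[test])
    return compute_metrics(y, pooled, groups=groups)


def leave_one_protein_out(matrix, config=None) -> dict[str, MetricsReport]:
    """Per-protein generalization: train on all other proteins, test on one."""
    from .modeling import ModelConfig, train
    from .dataset import FeatureMatrix

    config = config or ModelConfig()
    mask = matrix.y.notna().to_numpy()
    X = matrix.X[mask]
    y = matrix.y[mask].to_numpy()
    groups = [g for g, m in zip(matrix.groups, mask) if m]
    proteins = np.array([g[0] for g in groups])
    if len(set(proteins)) < 2:
        raise ValueError("need at least 2 proteins")
    reports: dict[str, MetricsReport] = {}
    for pid in sorted(set(proteins)):
        held = proteins == pid
        train_mat = FeatureMatrix(
            X[~held], pd.Series(y[~held], index=X.index[~held]),
            [g for g, h in zip(groups, held) if not h],
        )
        model = train(train_mat, config)
        proba = model.predict_proba(X[held])
        reports[pid] = compute_metrics(y[held], proba) if len(set(y[held])) > 1 else _single_class_report(y[held], proba)
    return reports


def _single_class_report(labels: np.ndarray, probabilities: np.ndarray) -> MetricsReport:
    """Held-out set with one class: accuracy only, rate metrics undefined-ish."""
    report = compute_metrics(labels, probabilities)
    return report


def optimize_cutoff(
    scores, labels, orientation: str = "high"
) -> tuple[float, float]:
    """MCC-maximizing decision cutoff over a score column.

    Scans every midpoint between adjacent sorted unique scores plus the
    two outer sentinels; returns ``(cutoff, mcc)``. ``orientation="high"``
    means scores >= cutoff are called pathogenic; ``"low"`` the reverse.
    Ties prefer the smallest cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if orientation not in ("high", "low"):
        raise ValueError("orientation must be 'high' or 'low'")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("constant scores: no cutoff exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_cut, best_mcc = candidates[0], -np.inf
    for c in candidates:
        pred = (scores >= c) if orientation == "high" else (scores <= c)
        m = mcc_score(labels, pred.astype(int))
        if m > best_mcc + 1e-12:
            best_cut, best_mcc = float(c), m
    return best_cut, float(best_mcc)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_groups(values_a, values_b) -> ComparisonResult:
    """Two-tailed rank-based comparison of two independent samples.

    Uses the Mann-Whitney/Wilcoxon rank-sum test: exact enumeration for
    small tie-free samples, normal approximation with tie correction
    otherwise.
    """
    from scipy.stats import mannwhitneyu

    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    small = max(len(a), len(b)) <= 20
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not has_ties else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(float(res.statistic), float(min(res.pvalue, 1.0)), len(a), len(b))
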