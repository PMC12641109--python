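"""Experiment harness: repeated stratified 5-fold cross-validation,
AUC/precision/recall/accuracy with SEM, Wilcoxon rank-sum comparisons,
decision-curve analysis, and external-cohort evaluation.

The protocol is 4 repetitions of stratified 5-fold CV (20 fold-level metric
values per model); SEM is the sample standard deviation over folds divided
by sqrt(#folds). Pairwise model comparisons apply the Wilcoxon rank-sum test
to the two 20-vectors of fold metrics.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .features import Cohort

__all__ = [
    "SplitPlan", "FoldMetrics", "CVReport", "DCACurve",
    "make_split_plan", "compute_auc", "compute_precision_recall",
    "compute_accuracy", "compute_sem", "run_cross_validation",
    "evaluate_external", "wilcoxon_rank_sum", "decision_curve",
]


@dataclass
class SplitPlan:
    """Test-set assignments for repeated k-fold CV.

    ``assignments[r][f]`` is the array of test indices of fold f in
    repetition r; within one repetition the folds partition the cohort, so
    each subject is tested exactly ``repetitions`` times overall.
    """

    assignments: list[list[np.ndarray]]
    subject_ids: list[str]
    k: int = 5
    repetitions: int = 4
    stratified: bool = True
    seed: int = 0

    def folds(self):
        """Yield (repetition, fold, train_idx, test_idx) over all 20 folds."""
        n = len(self.subject_ids)
        all_idx = np.arange(n)
        for r, rep in enumerate(self.assignments):
            for f, test_idx in enumerate(rep):
                train_idx = np.setdiff1d(all_idx, test_idx)
                yield r, f, train_idx, test_idx

    @property
    def n_folds(self) -> int:
        return self.k * self.repetitions

    def plan_hash(self) -> str:
        """Digest identifying the exact assignment (for paired-design checks)."""
        h = hashlib.sha256()
        h.update(json.dumps(self.subject_ids).encode())
        for rep in self.assignments:
            for test in rep:
                h.update(np.asarray(test, dtype=np.int64).tobytes())
        return h.hexdigest()


def make_split_plan(cohort_or_labels, k: int = 5, repetitions: int = 4,
                    stratified: bool = True, seed: int = 0) -> SplitPlan:
    """Build the repeated (stratified) k-fold plan for a labeled cohort.

    Stratification keeps the per-fold prevalence within one subject of the
    cohort prevalence; it requires at least k members per class.
    """
    if isinstance(cohort_or_labels, Cohort):
        y = cohort_or_labels.y
        if y is None:
            raise ValueError("cohort has no labels")
        ids = list(cohort_or_labels.subject_ids)
    else:
        y = np.asarray(cohort_or_labels)
        ids = [str(i) for i in range(len(y))]
    n = len(y)
    if stratified:
        counts = np.bincount(y.astype(int))
        if counts[counts > 0].min() < k:
            raise ValueError(f"stratified {k}-fold requires >= {k} members "
                             "per class")
    assignments = []
    for r in range(repetitions):
        rep_seed = (seed * 1009 + r) % (2 ** 31)  # distinct shuffle per rep
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=rep_seed)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        assignments.append([test for _, test in splitter.split(np.zeros(n), y)])
    return SplitPlan(assignments, ids, k, repetitions, stratified, seed)


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney pair-counting statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def compute_precision_recall(scores, labels, threshold: float = 0.5):
    """Precision and recall at a probability threshold (positive = 1).

    With no predicted positives precision is undefined; it is returned as
    None (and excluded from fold averaging) with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp + fp == 0:
        warnings.warn("no predicted positives: precision undefined",
                      RuntimeWarning, stacklevel=2)
        precision = None
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def compute_accuracy(scores, labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    return float(np.mean((scores >= threshold).astype(int) == labels))


def compute_sem(values) -> float:
    """Standard error of the mean: sample sd (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("SEM requires at least 2 values")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


@dataclass
class FoldMetrics:
    auc: float
    precision: float | None
    recall: float
    accuracy: float
    n_test: int
    repetition: int = 0
    fold: int = 0


@dataclass
class CVReport:
    """Fold-level metrics for one model under one split plan."""

    folds: list[FoldMetrics]
    plan_hash: str = ""
    model_label: str = ""
    mean_attention: np.ndarray | None = None       # (n_folds, n_branches)
    mean: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric in ("auc", "precision", "recall", "accuracy"):
            vals = [getattr(f, metric) for f in self.folds]
            vals = [v for v in vals if v is not None]
            self.mean[metric] = float(np.mean(vals)) if vals else math.nan
            self.sem[metric] = compute_sem(vals) if len(vals) > 1 else math.nan

    def metric_values(self, metric: str = "auc") -> np.ndarray:
        vals = [getattr(f, metric) for f in self.folds]
        return np.asarray([v for v in vals if v is not None], dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "plan_hash": self.plan_hash,
            "mean": self.mean,
            "sem": self.sem,
            "folds": [vars(f) for f in self.folds],
        }


def _fold_metrics(scores, labels, r, f, threshold=0.5) -> FoldMetrics:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        precision, recall = compute_precision_recall(scores, labels, threshold)
    return FoldMetrics(auc=compute_auc(scores, labels), precision=precision,
                       recall=recall,
                       accuracy=compute_accuracy(scores, labels, threshold),
                       n_test=len(labels), repetition=r, fold=f)


def run_cross_validation(cohort: Cohort, estimator, plan: SplitPlan,
                         return_models: bool = False,
                         model_label: str = "") -> CVReport:
    """Fit/score the estimator on every fold of the plan.

    The estimator is cloned per fold with a fold-specific ``random_state``
    derived from the plan seed (deterministic given the plan). Per-fold mean
    attention vectors are retained when the estimator exposes
    ``attention_weights``. With ``return_models=True`` the fitted per-fold
    models and their test indices are attached (``report.models_``), which
    external validation and inference-masking studies reuse.
    """
    if cohort.y is None:
        raise ValueError("cohort has no labels")
    folds, attn_rows, models = [], [], []
    for r, f, train_idx, test_idx in plan.folds():
        est = clone(estimator)
        if "random_state" in est.get_params():
            est.set_params(random_state=(plan.seed * 10007 + r * 101 + f) % (2 ** 31))
        est.fit(cohort.X[train_idx], cohort.y[train_idx])
        scores = est.predict_proba(cohort.X[test_idx])[:, 1]
        folds.append(_fold_metrics(scores, cohort.y[test_idx], r, f))
        if hasattr(est, "attention_weights"):
            attn_rows.append(est.attention_weights(cohort.X[test_idx]).mean(axis=0))
        if return_models:
            models.append((est, test_idx))
    report = CVReport(folds, plan.plan_hash(), model_label,
                      np.asarray(attn_rows) if attn_rows else None)
    if return_models:
        report.models_ = models
    return report


def evaluate_external(models: list, external: Cohort,
                      model_label: str = "external") -> CVReport:
    """Score per-fold internally trained models on an external cohort.

    No refitting: each of the fold models predicts the full external cohort,
    giving one metric row per internal fold (train-internal/test-external).
    """
    if external.y is None:
        raise ValueError("external cohort has no labels")
    folds, attn_rows = [], []
    for i, entry in enumerate(models):
        est = entry[0] if isinstance(entry, tuple) else entry
        scores = est.predict_proba(external.X)[:, 1]
        folds.append(_fold_metrics(scores, external.y, i // 5, i % 5))
        if hasattr(est, "attention_weights"):
            attn_rows.append(est.attention_weights(external.X).mean(axis=0))
    return CVReport(folds, "", model_label,
                    np.asarray(attn_rows) if attn_rows else None)


# -- Wilcoxon rank-sum -------------------------------------------------------

def _rank_sum_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[: len(a)].sum())


def _exact_p_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all assignments of pooled midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(a)
    obs = float(ranks[:n].sum())
    mean = ranks.sum() * n / len(ranks)
    obs_dev = abs(obs - mean)
    count = total = 0
    for combo in combinations(range(len(ranks)), n):
        w = float(ranks[list(combo)].sum())
        total += 1
        if abs(w - mean) >= obs_dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Small samples use the exact null distribution — full enumeration over
    rank assignments when feasible (handles ties exactly), otherwise scipy's
    exact recursion (tie-free) — falling back to the tie-corrected normal
    approximation for large samples. Returns (rank-sum statistic of ``a``,
    two-sided p).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    n, m = len(a), len(b)
    w = _rank_sum_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(np.unique(pooled)) == 1:
        return w, 1.0  # all values identical: no evidence whatsoever
    if n * m <= 400:
        if math.comb(n + m, min(n, m)) <= 200_000:
            return w, _exact_p_enumeration(a, b)
        if not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
            return w, float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return w, float(res.pvalue)


# -- decision-curve analysis -------------------------------------------------

@dataclass
class DCACurve:
    """Net-benefit curves for a model vs treat-all / treat-none policies."""

    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_treat_all: np.ndarray
    net_benefit_treat_none: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "threshold": self.thresholds,
            "net_benefit_model": self.net_benefit_model,
            "net_benefit_treat_all": self.net_benefit_treat_all,
            "net_benefit_treat_none": self.net_benefit_treat_none,
        })


def net_benefit(probs, labels, threshold: float) -> float:
    """NB(t) = TP/n - (FP/n) * t/(1-t), positives = prob >= t."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    pred = probs >= threshold
    tp = np.sum(pred & (labels == 1))
    fp = np.sum(pred & (labels == 0))
    return float(tp / n - (fp / n) * threshold / (1.0 - threshold))


def decision_curve(probs, labels, thresholds=None) -> DCACurve:
    """Decision-curve analysis over a threshold grid (default 0.01..0.99)."""
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any((thresholds <= 0.0) | (thresholds >= 1.0)):
        raise ValueError("thresholds must lie in (0, 1)")
    labels = np.asarray(labels).astype(int)
    prevalence = labels.mean()
    nb_model = np.array([net_benefit(probs, labels, t) for t in thresholds])
    nb_all = np.array([prevalence - (1.0 - prevalence) * t / (1.0 - t)
                       for t in thresholds])
    nb_none = np.zeros_like(thresholds)
    return DCACurve(thresholds, nb_model, nb_all, nb_none)
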