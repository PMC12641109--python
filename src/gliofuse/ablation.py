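"""Ablation studies and feature-reproducibility machinery.

Covers the four ablation classes around the fusion model — per-modality
bias, modality dropout (both retrained leave-one-out models and
inference-time masking), extractor-network integration, and the delta-T1
branch — plus Lin's concordance correlation coefficient (CCC) used to
quantify how reproducible a feature is across extractor networks.

All conditions of one study run under a single split plan (identical folds,
asserted by plan hash) so fold-wise comparisons are paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone

from .evaluation import (CVReport, SplitPlan, _fold_metrics,
                         run_cross_validation, wilcoxon_rank_sum)
from .features import BRANCHES, Cohort

__all__ = [
    "lin_ccc", "pearson_r", "feature_table_ccc", "CCCReport",
    "AblationResult", "run_modality_ablation", "run_network_integration",
    "run_delta_ablation",
]


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2) with
    population (1/n) moments. Unlike Pearson's r it penalizes location and
    scale shifts, so ccc(a x + b, x) < 1 whenever (a, b) != (1, 0). When both
    inputs are constant with equal means the ratio is 0/0; identical inputs
    are defined as perfectly concordant (1), anything else as 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1D with >= 2 values")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()           # population (1/n) moments
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        if np.array_equal(x, y):
            return 1.0
        warnings.warn("degenerate CCC denominator; returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(2.0 * cov / denom)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation (errors on constant input)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CCCReport:
    """Per-feature concordance between two extractors' feature tables."""

    per_feature_ccc: np.ndarray
    pair: tuple[str, str] = ("A", "B")
    mean_ccc: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_feature_ccc = np.asarray(self.per_feature_ccc, dtype=np.float64)
        self.mean_ccc = float(self.per_feature_ccc.mean())


def feature_table_ccc(table_a: np.ndarray, table_b: np.ndarray,
                      pair: tuple[str, str] = ("A", "B")) -> CCCReport:
    """CCC of every feature column across subjects, plus the pair mean.

    Both tables must cover the same subjects in the same order and have the
    same feature count.
    """
    a = np.asarray(table_a, dtype=np.float64)
    b = np.asarray(table_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"subject/feature mismatch: {a.shape} vs {b.shape}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ccc = np.array([lin_ccc(a[:, j], b[:, j]) for j in range(a.shape[1])])
    return CCCReport(ccc, pair)


@dataclass
class AblationResult:
    """CV reports per condition, all under one (hash-identical) split plan."""

    reports: dict[str, CVReport]
    plan_hash: str
    comparisons: dict[str, dict] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        hashes = {r.plan_hash for r in self.reports.values() if r.plan_hash}
        if hashes and hashes != {self.plan_hash}:
            raise ValueError("ablation conditions ran under different split plans")

    def to_frame(self):
        import pandas as pd

        rows = []
        for label, rep in self.reports.items():
            row = {"condition": label}
            for metric in ("auc", "precision", "recall", "accuracy"):
                row[metric] = rep.mean[metric]
                row[f"{metric}_sem"] = rep.sem[metric]
            row.update(self.comparisons.get(label, {}))
            rows.append(row)
        return pd.DataFrame(rows)


def _single_branch_cohort(cohort: Cohort, branch: str) -> tuple[Cohort, int]:
    b = BRANCHES.index(branch)
    return cohort, b


def _branch_subset_estimator(estimator, branches: list[int]):
    """Clone the fusion estimator for a reduced branch set."""
    est = clone(estimator)
    est.set_params(n_branches=len(branches))
    return est


def _subset_X(cohort: Cohort, branches: list[int]) -> Cohort:
    return Cohort(list(cohort.subject_ids), cohort.X[:, branches, :], cohort.y,
                  cohort.name, cohort.extractor_id)


def run_modality_ablation(cohort: Cohort, estimator, plan: SplitPlan,
                          include_masking: bool = True) -> AblationResult:
    """Per-modality bias and modality-dropout study.

    Conditions, all on the identical split plan:

    - ``only_<branch>``: single-branch model retrained on that branch alone;
    - ``dropout_<branch>``: leave-one-out model retrained without the branch;
    - ``all``: the full five-branch model;
    - ``masked_<branch>`` (optional): the full model with the branch masked
      at inference only, reusing the ``all`` condition's fold models.

    Also reports the Pearson r between the single-branch AUC vector and the
    leave-one-out AUC vector (complementarity: strongly negative when each
    modality's solo value mirrors the cost of dropping it), and paired
    Wilcoxon p-values of every condition against ``all``.
    """
    reports: dict[str, CVReport] = {}
    all_report = run_cross_validation(cohort, estimator, plan,
                                      return_models=include_masking,
                                      model_label="all")
    reports["all"] = all_report
    for b, branch in enumerate(BRANCHES):
        est = _branch_subset_estimator(estimator, [b])
        reports[f"only_{branch}"] = run_cross_validation(
            _subset_X(cohort, [b]), est, plan, model_label=f"only_{branch}")
        keep = [i for i in range(len(BRANCHES)) if i != b]
        est = _branch_subset_estimator(estimator, keep)
        reports[f"dropout_{branch}"] = run_cross_validation(
            _subset_X(cohort, keep), est, plan, model_label=f"dropout_{branch}")
    if include_masking:
        for b, branch in enumerate(BRANCHES):
            present = np.ones(len(BRANCHES), dtype=bool)
            present[b] = False
            folds = []
            for (est, test_idx), fm in zip(all_report.models_, all_report.folds):
                scores = est.predict_proba_missing(cohort.X[test_idx],
                                                   present)[:, 1]
                folds.append(_fold_metrics(scores, cohort.y[test_idx],
                                           fm.repetition, fm.fold))
            reports[f"masked_{branch}"] = CVReport(folds, plan.plan_hash(),
                                                   f"masked_{branch}")

    comparisons = {}
    base_auc = all_report.metric_values("auc")
    for label, rep in reports.items():
        if label == "all":
            continue
        _, p = wilcoxon_rank_sum(rep.metric_values("auc"), base_auc)
        comparisons[label] = {"p_auc_vs_all": p}
    solo = np.array([reports[f"only_{b}"].mean["auc"] for b in BRANCHES])
    loo = np.array([reports[f"dropout_{b}"].mean["auc"] for b in BRANCHES])
    try:
        r_solo_loo = pearson_r(solo, loo)
    except ValueError:
        r_solo_loo = float("nan")
    return AblationResult(reports, plan.plan_hash(), comparisons,
                          extras={"pearson_r_single_vs_dropout": r_solo_loo,
                                  "single_branch_auc": solo.tolist(),
                                  "leave_one_out_auc": loo.tolist()})


def run_network_integration(cohorts_by_extractor: dict[str, Cohort],
                            combos: list[tuple[str, ...]], estimator,
                            plan: SplitPlan) -> AblationResult:
    """Marginal effect of integrating features from several extractors.

    For each combination the per-branch inputs are the concatenation of the
    member extractors' feature vectors (the encoder input width scales with
    combo size). Reports per-combo CV plus, across multi-extractor combos,
    the Pearson r^2 between combo AUC and the mean pairwise per-feature CCC
    of its members — the performance-reproducibility relation.
    """
    ids = None
    for name, cohort in cohorts_by_extractor.items():
        if ids is None:
            ids = cohort.subject_ids
        elif cohort.subject_ids != ids:
            raise ValueError(f"subject misalignment in extractor {name!r}")
    reports: dict[str, CVReport] = {}
    mean_cccs: dict[str, float] = {}
    for combo in combos:
        label = "+".join(combo)
        members = [cohorts_by_extractor[c] for c in combo]
        X = np.concatenate([c.X for c in members], axis=2)
        combo_cohort = Cohort(list(ids), X, members[0].y, label, label)
        reports[label] = run_cross_validation(combo_cohort, estimator, plan,
                                              model_label=label)
        if len(combo) > 1:
            pair_cccs = []
            for i in range(len(combo)):
                for j in range(i + 1, len(combo)):
                    a = members[i].X.reshape(len(ids), -1)
                    b = members[j].X.reshape(len(ids), -1)
                    pair_cccs.append(feature_table_ccc(a, b).mean_ccc)
            mean_cccs[label] = float(np.mean(pair_cccs))
    extras = {"mean_pairwise_ccc": mean_cccs}
    multi = [lab for lab in mean_cccs]
    if len(multi) >= 2:
        aucs = np.array([reports[lab].mean["auc"] for lab in multi])
        cccs = np.array([mean_cccs[lab] for lab in multi])
        try:
            r = pearson_r(aucs, cccs)
            extras["r2_auc_vs_ccc"] = r * r
        except ValueError:
            extras["r2_auc_vs_ccc"] = float("nan")
    return AblationResult(reports, plan.plan_hash(), extras=extras)


def run_delta_ablation(cohort: Cohort, estimator, plan: SplitPlan) -> AblationResult:
    """Paired with/without-delta-branch comparison on one split plan.

    The without condition removes the delta branch entirely (a retrained
    4-branch model). Emits paired Wilcoxon p-values per metric.
    """
    delta_idx = BRANCHES.index("delta_t1")
    with_rep = run_cross_validation(cohort, estimator, plan,
                                    model_label="with_delta")
    keep = [i for i in range(len(BRANCHES)) if i != delta_idx]
    est4 = _branch_subset_estimator(estimator, keep)
    without_rep = run_cross_validation(_subset_X(cohort, keep), est4, plan,
                                       model_label="without_delta")
    comparisons = {"with_delta": {}}
    pvals = {}
    for metric in ("auc", "precision", "recall"):
        _, p = wilcoxon_rank_sum(with_rep.metric_values(metric),
                                 without_rep.metric_values(metric))
        pvals[f"p_{metric}"] = p
    comparisons["without_delta"] = pvals
    return AblationResult({"with_delta": with_rep, "without_delta": without_rep},
                          plan.plan_hash(), comparisons)
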