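"""CV plans, metrics, Wilcoxon rank-sum, SEM, decision curves."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from gliofuse import (compute_auc, compute_precision_recall, compute_sem,
                      decision_curve, make_split_plan, net_benefit,
                      wilcoxon_rank_sum)


def auc_pair_counting(scores, labels):
    """Brute-force Mann-Whitney statistic over all positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def rank_sum_permutation_p(a, b):
    """Independent oracle: enumerate every split of the pooled data."""
    pooled = np.concatenate([a, b])
    n = len(a)
    obs_dev = None
    devs = []
    mean = None
    for combo in itertools.combinations(range(len(pooled)), n):
        ranks = rankdata(pooled)
        w = ranks[list(combo)].sum()
        devs.append(w)
    devs = np.array(devs)
    mean = rankdata(pooled).sum() * n / len(pooled)
    obs = rankdata(pooled)[:n].sum()
    return np.mean(np.abs(devs - mean) >= abs(obs - mean) - 1e-9)


class TestAUC:
    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(200):
            n = rng.integers(4, 30)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert compute_auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12)

    def test_worked_example(self):
        assert compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert compute_auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.2], [1, 1])


class TestPrecisionRecall:
    def test_counting_example(self):
        # TP=3, FP=1, FN=2
        scores = [0.9, 0.8, 0.7, 0.6, 0.2, 0.1, 0.3]
        labels = [1, 1, 1, 0, 1, 1, 0]
        precision, recall = compute_precision_recall(scores, labels)
        assert precision == 0.75
        assert recall == pytest.approx(0.6)

    def test_threshold_zero_recalls_everything(self):
        scores = [0.3, 0.6, 0.1, 0.9]
        labels = [0, 1, 0, 1]
        precision, recall = compute_precision_recall(scores, labels,
                                                     threshold=0.0)
        assert recall == 1.0
        assert precision == 0.5  # prevalence

    def test_no_predicted_positives_returns_missing(self):
        with pytest.warns(RuntimeWarning, match="precision undefined"):
            precision, recall = compute_precision_recall([0.1, 0.2], [1, 0],
                                                         threshold=0.9)
        assert precision is None
        assert recall == 0.0


class TestSEM:
    def test_worked_examples(self):
        assert compute_sem([0.6, 0.7, 0.8]) == pytest.approx(0.1 / math.sqrt(3))
        assert compute_sem([0.4, 0.4, 0.4]) == pytest.approx(0.0, abs=1e-15)
        a, b = 0.3, 0.7
        assert compute_sem([a, b]) == pytest.approx(abs(a - b) / 2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_sem([0.5])


class TestSplitPlan:
    def test_each_subject_tested_exactly_repetitions_times(self, rng):
        y = rng.integers(0, 2, 585)
        plan = make_split_plan(y, seed=1)
        assert plan.n_folds == 20
        counts = np.zeros(585, dtype=int)
        for rep in plan.assignments:
            concat = np.concatenate(rep)
            assert sorted(concat) == list(range(585))  # partition
            counts[concat] += 1
        assert (counts == 4).all()

    def test_stratification_keeps_fold_prevalence_close(self, rng):
        y = np.array([1] * 100 + [0] * 300)
        plan = make_split_plan(y, seed=2)
        for _, _, _, test_idx in plan.folds():
            assert abs(y[test_idx].mean() - 0.25) <= 1.0 / len(test_idx)

    def test_tiny_cohort_folds_of_two(self):
        y = np.array([0, 1] * 5)
        plan = make_split_plan(y, k=5, repetitions=1, seed=0)
        for rep in plan.assignments:
            assert all(len(t) == 2 for t in rep)

    def test_same_seed_identical_plan_and_hash(self, rng):
        y = rng.integers(0, 2, 60)
        p1 = make_split_plan(y, seed=7)
        p2 = make_split_plan(y, seed=7)
        assert p1.plan_hash() == p2.plan_hash()
        p3 = make_split_plan(y, seed=8)
        assert p1.plan_hash() != p3.plan_hash()

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            make_split_plan(y, k=5, seed=0)


class TestExternalEvaluation:
    def test_fold_models_score_external_cohort_without_refit(self, rng):
        from gliofuse import (FeatureCohortConfig, MLPBaselineClassifier,
                              evaluate_external, generate_feature_cohort,
                              run_cross_validation)

        cfg = FeatureCohortConfig(n_subjects=80, n_features=30,
                                  effect_size=(0, 0, 0, 2.5, 0),
                                  informative_fraction=0.3, seed=61)
        internal = generate_feature_cohort(cfg)
        ext_cfg = FeatureCohortConfig(n_subjects=40, n_features=30,
                                      prevalence_methylated=0.75,
                                      effect_size=(0, 0, 0, 2.5, 0),
                                      informative_fraction=0.3, seed=62)
        external = generate_feature_cohort(ext_cfg)
        plan = make_split_plan(internal, k=5, repetitions=1, seed=2)
        est = MLPBaselineClassifier(random_state=0, max_epochs=30,
                                    min_epochs=10, patience=10, n_restarts=1)
        rep = run_cross_validation(internal, est, plan, return_models=True)
        ext = evaluate_external(rep.models_, external)
        assert len(ext.folds) == 5
        assert all(f.n_test == 40 for f in ext.folds)
        assert ext.mean["auc"] > 0.6  # signal transfers across prevalence


class TestWilcoxon:
    def test_worked_exact_example(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert p == 1.0

    def test_exact_branch_matches_permutation_oracle(self, rng):
        for n, m in [(2, 3), (3, 3), (4, 5), (5, 2), (6, 6), (8, 8)]:
            a = np.round(rng.random(n), 1)
            b = np.round(rng.random(m), 1)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(rank_sum_permutation_p(a, b), abs=1e-12)

    def test_large_sample_uses_normal_tail(self, rng):
        a = rng.standard_normal(25)
        b = rng.standard_normal(25) + 2.0
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestDecisionCurve:
    def test_worked_net_benefit_value(self):
        probs = np.concatenate([np.full(30, 0.9), np.full(10, 0.9),
                                np.full(60, 0.1)])
        labels = np.concatenate([np.ones(30), np.zeros(10), np.zeros(60)])
        assert net_benefit(probs, labels, 0.25) == pytest.approx(0.30 - 0.10 / 3,
                                                                 abs=1e-12)

    def test_perfect_classifier_attains_prevalence_everywhere(self):
        labels = np.array([1] * 30 + [0] * 70)
        probs = labels.astype(float)
        curve = decision_curve(probs, labels)
        assert np.allclose(curve.net_benefit_model, 0.3)

    def test_treat_none_is_zero_and_treat_all_limit(self):
        labels = np.array([1] * 25 + [0] * 75)
        curve = decision_curve(np.linspace(0, 1, 100), labels)
        assert not curve.net_benefit_treat_none.any()
        assert curve.net_benefit_treat_all[0] == pytest.approx(
            0.25 - 0.75 * 0.01 / 0.99)

    def test_model_curve_never_exceeds_prevalence(self, rng):
        labels = rng.integers(0, 2, 200)
        probs = rng.random(200)
        curve = decision_curve(probs, labels)
        assert (curve.net_benefit_model <= labels.mean() + 1e-12).all()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            net_benefit([0.5], [1], 1.0)
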