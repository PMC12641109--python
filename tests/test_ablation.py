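"""Lin's CCC, feature reproducibility, and the ablation study harness."""

import numpy as np
import pytest

from gliofuse import (AttentionFusionClassifier, Cohort, FeatureCohortConfig,
                      feature_table_ccc, generate_feature_cohort, lin_ccc,
                      make_split_plan, pearson_r, run_delta_ablation,
                      run_modality_ablation, run_network_integration)

FAST = dict(max_epochs=30, min_epochs=10, patience=10, n_restarts=1)


def ccc_brute_force(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


class TestLinCCC:
    def test_identity_is_one(self):
        assert lin_ccc([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_unit_shift_worked_example(self):
        assert lin_ccc([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(
            2 * 1.25 / (1.25 + 1.25 + 1), abs=1e-12)

    def test_reversal_is_minus_one(self):
        assert lin_ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_moment_formula_on_random_pairs(self, rng):
        for _ in range(100):
            n = rng.integers(2, 40)
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + rng.normal() * x
            assert lin_ccc(x, y) == pytest.approx(ccc_brute_force(x, y),
                                                  abs=1e-12)

    def test_symmetric_and_self_concordant(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(y, x), abs=1e-15)
        assert lin_ccc(x, x) == 1.0

    def test_penalizes_scale_and_location_unlike_pearson(self, rng):
        x = rng.standard_normal(30)
        for a, b in [(2.0, 0.0), (1.0, 1.5), (0.5, -2.0)]:
            y = a * x + b
            assert lin_ccc(y, x) < 1.0
            assert lin_ccc(y, x) < pearson_r(y, x)

    def test_degenerate_identical_constants_are_concordant(self):
        assert lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0


class TestPearson:
    def test_affine_and_reversed(self, rng):
        x = rng.standard_normal(15)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])


class TestFeatureTableCCC:
    def test_identical_tables_all_one(self, rng):
        a = rng.standard_normal((30, 12))
        report = feature_table_ccc(a, a.copy())
        assert np.allclose(report.per_feature_ccc, 1.0)
        assert report.mean_ccc == pytest.approx(1.0)

    def test_generator_contract_recovered(self):
        cfg = FeatureCohortConfig(n_subjects=585, n_features=400,
                                  cross_network_ccc=0.15, seed=12)
        from gliofuse import generate_paired_network_tables

        a, b = generate_paired_network_tables(cfg)
        assert feature_table_ccc(a, b).mean_ccc == pytest.approx(0.15, abs=0.05)

    def test_independent_tables_near_zero(self, rng):
        a = rng.standard_normal((585, 100))
        b = rng.standard_normal((585, 100))
        assert feature_table_ccc(a, b).mean_ccc == pytest.approx(0.0, abs=0.05)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            feature_table_ccc(rng.standard_normal((10, 4)),
                              rng.standard_normal((10, 5)))


@pytest.fixture(scope="module")
def ablation_setup():
    cfg = FeatureCohortConfig(n_subjects=100, n_features=30,
                              effect_size=(0, 0, 0, 2.5, 0),
                              informative_fraction=0.3, seed=21)
    cohort = generate_feature_cohort(cfg)
    plan = make_split_plan(cohort, k=5, repetitions=1, seed=3)
    est = AttentionFusionClassifier(random_state=0, **FAST)
    return cohort, plan, est


class TestModalityAblation:
    def test_grid_structure_and_informative_branch_dominates(self, ablation_setup):
        cohort, plan, est = ablation_setup
        result = run_modality_ablation(cohort, est, plan)
        labels = set(result.reports)
        assert "all" in labels
        assert sum(lbl.startswith("only_") for lbl in labels) == 5
        assert sum(lbl.startswith("dropout_") for lbl in labels) == 5
        assert sum(lbl.startswith("masked_") for lbl in labels) == 5
        solo = {b: result.reports[f"only_{b}"].mean["auc"]
                for b in ("flair", "t1", "t2", "t1wce", "delta_t1")}
        assert max(solo, key=solo.get) == "t1wce"
        loo = {b: result.reports[f"dropout_{b}"].mean["auc"]
               for b in ("flair", "t1", "t2", "t1wce", "delta_t1")}
        assert min(loo, key=loo.get) == "t1wce"

    def test_paired_design_shares_one_plan(self, ablation_setup):
        cohort, plan, est = ablation_setup
        result = run_modality_ablation(cohort, est, plan,
                                       include_masking=False)
        for rep in result.reports.values():
            assert rep.plan_hash == plan.plan_hash()
        assert "pearson_r_single_vs_dropout" in result.extras

    def test_all_conditions_have_complete_fold_grids(self, ablation_setup):
        cohort, plan, est = ablation_setup
        result = run_modality_ablation(cohort, est, plan,
                                       include_masking=False)
        for rep in result.reports.values():
            assert len(rep.folds) == plan.n_folds
        frame = result.to_frame()
        assert set(frame["condition"]) == set(result.reports)
        assert {"auc", "auc_sem", "precision", "recall"} <= set(frame.columns)


class TestNetworkIntegration:
    def test_single_extractor_combo_reproduces_plain_model(self, ablation_setup):
        cohort, plan, est = ablation_setup
        result = run_network_integration({"netA": cohort}, [("netA",)], est,
                                         plan)
        plain = __import__("gliofuse").run_cross_validation(cohort, est, plan)
        combo = result.reports["netA"]
        assert np.allclose(combo.metric_values("auc"),
                           plain.metric_values("auc"))

    def test_noise_table_integration_does_not_help(self, ablation_setup, rng):
        cohort, plan, est = ablation_setup
        noise = Cohort(list(cohort.subject_ids),
                       rng.standard_normal(cohort.X.shape), cohort.y,
                       "noise", "noise")
        result = run_network_integration(
            {"netA": cohort, "noise": noise},
            [("netA",), ("netA", "noise")], est, plan)
        a = result.reports["netA"].mean["auc"]
        both = result.reports["netA+noise"].mean["auc"]
        assert both <= a + 0.02
        assert "netA+noise" in result.extras["mean_pairwise_ccc"]

    def test_subject_misalignment_rejected(self, ablation_setup):
        cohort, plan, est = ablation_setup
        other = Cohort([f"x{i}" for i in range(len(cohort))], cohort.X,
                       cohort.y, "other", "other")
        with pytest.raises(ValueError, match="misalignment"):
            run_network_integration({"a": cohort, "b": other},
                                    [("a", "b")], est, plan)


class TestDeltaAblation:
    def test_delta_signal_detected_by_paired_comparison(self):
        cfg = FeatureCohortConfig(n_subjects=100, n_features=30,
                                  effect_size=(0, 0, 0, 0, 2.5),
                                  informative_fraction=0.3, seed=22)
        cohort = generate_feature_cohort(cfg)
        plan = make_split_plan(cohort, k=5, repetitions=1, seed=4)
        est = AttentionFusionClassifier(random_state=0, **FAST)
        result = run_delta_ablation(cohort, est, plan)
        gain = result.reports["with_delta"].mean["auc"] \
            - result.reports["without_delta"].mean["auc"]
        assert gain >= 0.1
        assert set(result.comparisons["without_delta"]) == {"p_auc",
                                                            "p_precision",
                                                            "p_recall"}

    def test_pure_noise_delta_branch_is_harmless(self, ablation_setup):
        cohort, plan, est = ablation_setup  # delta branch carries no signal
        result = run_delta_ablation(cohort, est, plan)
        diff = abs(result.reports["with_delta"].mean["auc"]
                   - result.reports["without_delta"].mean["auc"])
        assert diff < 0.1
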