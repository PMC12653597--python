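"""Fold planning, metrics, Wilcoxon comparison and the experiment driver."""

import numpy as np
import pytest
from scipy import stats

from silistage import (
    QUICK_GRIDS,
    ClassifierSpec,
    ConfusionCounts,
    SimulationConfig,
    aggregate_folds,
    confusion_metrics,
    filter_markers_by_missingness,
    generate_cohort,
    nested_grid_search,
    plan_folds,
    plan_group_folds,
    rank_auc,
    run_experiment,
    wilcoxon_paired_auc,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFoldPlanning:
    def test_balanced_patients_give_one_per_class_per_fold(self):
        pids = np.array([f"P{i}" for i in range(10)], dtype=object)
        labels = np.array([0] * 5 + [1] * 5)
        assignments, stratified = plan_group_folds(pids, labels, k=5, seed=0)
        assert stratified
        per_fold = {f: [] for f in range(5)}
        for p, f in assignments.items():
            per_fold[f].append(labels[list(pids).index(p)])
        for members in per_fold.values():
            assert sorted(members) == [0, 1]

    def test_no_patient_overlap_between_train_and_test(self, small_cohort):
        cohort, _ = small_cohort
        plan = plan_folds(cohort, k=5, seed=1)
        pids = cohort.patient_ids
        for tr, te in plan.splits(pids):
            assert not (set(pids[tr]) & set(pids[te]))

    def test_feasible_case_stratifies_infeasible_falls_back(self):
        # 6 + 6 patients per class, k=5 -> stratified
        pids = np.array([f"P{i}" for i in range(12)], dtype=object)
        labels = np.array([0] * 6 + [1] * 6)
        _, stratified = plan_group_folds(pids, labels, k=5, seed=0)
        assert stratified
        # 4 patients of one class with k=5 -> plain group K-fold fallback
        pids = np.array([f"P{i}" for i in range(9)], dtype=object)
        labels = np.array([0] * 4 + [1] * 5)
        assignments, stratified = plan_group_folds(pids, labels, k=5, seed=0)
        assert not stratified
        assert sorted(set(assignments.values())) == list(range(5))

    def test_fewer_patients_than_folds_errors(self):
        pids = np.array(["A", "B", "C"], dtype=object)
        with pytest.raises(ValueError, match="at least k"):
            plan_group_folds(pids, np.array([0, 1, 0]), k=5)

    def test_zero_leakage_across_seeds_and_modes(self):
        # mixed-label longitudinal cohorts, many seeds, both split modes
        for seed in range(30):
            cfg = SimulationConfig(n_patients=14, progression_prob=0.5,
                                   feature_dim=4, seed=seed)
            cohort, _ = generate_cohort(cfg)
            plan = plan_folds(cohort, k=5, seed=seed)
            pids = cohort.patient_ids
            for tr, te in plan.splits(pids):
                assert not (set(pids[tr]) & set(pids[te]))


class TestConfusionMetrics:
    def test_worked_example(self):
        acc, prec, rec, f1 = confusion_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=1))
        assert acc == pytest.approx(5 / 7)
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.75)
        assert f1 == pytest.approx(0.75)

    def test_perfect_prediction_gives_all_ones(self):
        assert confusion_metrics(ConfusionCounts(3, 4, 0, 0)) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_precision_convention(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            acc, prec, rec, f1 = confusion_metrics(ConfusionCounts(0, 3, 0, 2))
        assert (prec, rec, f1) == (0.0, 0.0, 0.0)
        assert acc == pytest.approx(0.6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_agrees_with_brute_force_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            counts = ConfusionCounts.from_predictions(y, pred)
            assert counts.total == n
            tp = sum(1 for a, b in zip(y, pred) if a == 1 and b == 1)
            fn = sum(1 for a, b in zip(y, pred) if a == 1 and b == 0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, rec, _ = confusion_metrics(counts)
            expected = 0.0 if tp + fn == 0 else tp / (tp + fn)
            assert rec == pytest.approx(expected)


class TestRankAuc:
    def test_perfect_ranking(self):
        assert rank_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_complete_ties_give_half(self):
        assert rank_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pairwise_example(self):
        assert rank_auc([0.7, 0.4, 0.6, 0.3], [1, 0, 1, 0]) == 1.0
        # swapping the scores of one (pos, neg) pair flips 1 of 4 pairs
        assert rank_auc([0.7, 0.6, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rank_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert rank_auc(s, y) == pytest.approx(brute_force_auc(s, y))


class TestAggregateFolds:
    def test_zero_variance_ci_collapses(self):
        t = aggregate_folds({"auc": np.array([0.8, 0.8, 0.8])})
        assert t.mean["auc"] == pytest.approx(0.8)
        assert t.ci_lower["auc"] == pytest.approx(0.8)
        assert t.ci_upper["auc"] == pytest.approx(0.8)

    def test_two_fold_closed_form(self):
        t = aggregate_folds({"auc": np.array([0.8, 0.9])})
        half = stats.t.ppf(0.975, 1) * np.std([0.8, 0.9], ddof=1) / np.sqrt(2)
        assert t.mean["auc"] == pytest.approx(0.85)
        assert t.ci_upper["auc"] == pytest.approx(min(1.0, 0.85 + half))
        assert t.ci_lower["auc"] == pytest.approx(max(0.0, 0.85 - half))

    def test_ordering_invariant(self, rng):
        t = aggregate_folds({"m": rng.random(5)})
        assert t.ci_lower["m"] <= t.mean["m"] <= t.ci_upper["m"]

    def test_single_fold_has_no_ci(self):
        t = aggregate_folds({"auc": np.array([0.7])})
        assert not t.ci_available
        assert np.isnan(t.ci_lower["auc"])


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            r = wilcoxon_paired_auc([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert r.p_value == 1.0
        assert not r.significant

    def test_all_positive_n5_exact(self):
        a = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        b = a - np.array([0.1, 0.2, 0.1, 0.3, 0.2])
        r = wilcoxon_paired_auc(a, b)
        assert r.p_value == pytest.approx(2 / 32)

    def test_two_sided_symmetry(self, rng):
        a, b = rng.random(6), rng.random(6)
        assert wilcoxon_paired_auc(a, b).p_value == pytest.approx(
            wilcoxon_paired_auc(b, a).p_value
        )

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            a, b = rng.random(n), rng.random(n)
            expected = stats.wilcoxon(a, b, zero_method="wilcox", mode="exact").pvalue
            assert wilcoxon_paired_auc(a, b).p_value == pytest.approx(expected)

    def test_pairedness_guard(self, small_cohort):
        cohort, _ = small_cohort
        plan_a = plan_folds(cohort, k=5, seed=0)
        plan_b = plan_folds(cohort, k=5, seed=99)
        with pytest.raises(ValueError, match="identical fold plan"):
            wilcoxon_paired_auc([0.1, 0.2], [0.3, 0.4], plan_a=plan_a, plan_b=plan_b)


class TestNestedGridSearch:
    def _grouped(self, rng, n_patients=30, reps=2):
        pids = np.repeat([f"P{i}" for i in range(n_patients)], reps).astype(object)
        y = np.repeat((rng.random(n_patients) > 0.5).astype(int), reps)
        return pids, y

    def test_size_one_grid_returned_unchanged(self, rng):
        pids, y = self._grouped(rng)
        X = rng.standard_normal((len(y), 3))
        spec = ClassifierSpec("svm", grid={"C": [1], "kernel": ["linear"]}, seed=0)
        assert nested_grid_search(X, y, pids, spec) == {"C": 1, "kernel": "linear"}

    def test_duplicate_entries_tie_break_to_first(self, rng):
        pids, y = self._grouped(rng)
        X = rng.standard_normal((len(y), 3))
        spec = ClassifierSpec("svm", grid={"C": [1, 1.0], "kernel": ["linear"]}, seed=0)
        assert nested_grid_search(X, y, pids, spec)["C"] == 1

    def test_planted_optimum_selected(self):
        # XOR structure: a depth-1 stump cannot rank it, a deep forest can
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pids = np.repeat([f"P{i}" for i in range(40)], 3).astype(object)
            X = rng.standard_normal((120, 2))
            y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
            spec = ClassifierSpec(
                "rf", grid={"max_depth": [1, None], "n_estimators": [50]}, seed=seed
            )
            best = nested_grid_search(X, y, pids, spec, seed=seed)
            wins += best["max_depth"] is None
        assert wins >= 18

    def test_too_few_patients_for_inner_split(self, rng):
        pids = np.array(["A", "A", "B", "B"], dtype=object)
        y = np.array([0, 1, 0, 1])
        spec = ClassifierSpec("svm", grid={"C": [1], "kernel": ["linear"]}, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            nested_grid_search(rng.standard_normal((4, 2)), y, pids, spec, inner_k=3)


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = SimulationConfig(n_patients=24, image_effect=1.2, biomarker_effect=0.8,
                               feature_dim=16, seed=5)
        cohort, gt = generate_cohort(cfg)
        cohort, _ = filter_markers_by_missingness(cohort)
        spec = ClassifierSpec("svm", grid=QUICK_GRIDS["svm"], seed=2)
        return cohort, gt, spec

    def test_reproducible_for_fixed_seed(self, setup):
        cohort, gt, spec = setup
        r1 = run_experiment(cohort, gt.features, "late", spec, seed=3)
        r2 = run_experiment(cohort, gt.features, "late", spec, seed=3)
        assert r1.metrics.mean == r2.metrics.mean
        np.testing.assert_array_equal(r1.fold_aucs, r2.fold_aucs)

    def test_shared_plan_enables_paired_comparison(self, setup):
        cohort, gt, spec = setup
        plan = plan_folds(cohort, k=5, seed=1)
        ra = run_experiment(cohort, gt.features, "image_only", spec, seed=3, fold_plan=plan)
        rb = run_experiment(cohort, gt.features, "early", spec, seed=3, fold_plan=plan)
        cmp = wilcoxon_paired_auc(ra.fold_aucs, rb.fold_aucs,
                                  plan_a=ra.fold_plan, plan_b=rb.fold_plan)
        assert 0 <= cmp.p_value <= 1

    def test_fusion_weights_logged_and_valid(self, setup):
        cohort, gt, spec = setup
        r = run_experiment(cohort, gt.features, "late", spec, seed=4)
        for rec in r.fold_records:
            wi, wb = rec["weights"]
            assert wi >= 0 and wb >= 0
            assert wi + wb == pytest.approx(1.0)

    def test_hybrid_schemes_both_run(self, setup):
        cohort, gt, spec = setup
        for scheme in ("mean", "auc_proportional"):
            r = run_experiment(cohort, gt.features, "hybrid", spec, seed=4,
                               hybrid_scheme=scheme)
            assert 0 <= r.metrics.mean["auc"] <= 1

    def test_unknown_strategy_rejected(self, setup):
        cohort, gt, spec = setup
        with pytest.raises(ValueError, match="strategy"):
            run_experiment(cohort, gt.features, "stacking", spec)
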