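import numpy as np
import pytest

from connectopred.augment import AugmentationConfig
from connectopred.connectome import Cohort, Connectome, Subject
from connectopred.evaluation import (
    CVConfig,
    LeakageError,
    _audit_no_leakage,
    compute_classification_metrics,
    compute_regression_metrics,
    percentile_ci,
    permute_roi_order,
    run_repeated_cv,
    split_folds,
    train_val_split,
)
from connectopred.models import build_model
from connectopred.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort80():
    return generate_cohort(GeneratorConfig(n=80, effect_edges=((10, 60, 0.8),),
                                           seed=17))


class TestFoldSplitting:
    def test_80_subjects_give_five_folds_of_16(self, cohort80):
        folds = split_folds(cohort80, CVConfig(seed=0))
        assert [len(f) for f in folds] == [16] * 5

    def test_folds_partition_the_cohort(self, cohort80):
        folds = split_folds(cohort80, CVConfig(seed=1))
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(80))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not set(folds[i]) & set(folds[j])

    def test_stratification_spreads_the_minority_class(self, cohort80):
        labels = cohort80.labels
        folds = split_folds(cohort80, CVConfig(seed=2, stratified=True))
        counts = [labels[f].sum() for f in folds]
        assert max(counts) - min(counts) <= 1

    def test_same_seed_same_assignment(self, cohort80):
        a = split_folds(cohort80, CVConfig(seed=3))
        b = split_folds(cohort80, CVConfig(seed=3))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_cohort_smaller_than_folds_rejected(self, cohort80):
        with pytest.raises(ValueError):
            split_folds(cohort80.subset(range(3)), CVConfig(folds=5))

    def test_train_val_split_fractions(self, cohort80):
        fit, val = train_val_split(cohort80, 0.7, seed=0)
        assert len(fit) + len(val) == 80
        assert abs(len(fit) - 56) <= 1
        assert not set(fit.ids) & set(val.ids)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        m = compute_classification_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["balanced_accuracy"] == 100.0
        assert m["auc"] == 1.0

    def test_hand_computed_confusion_matrix(self):
        # TP=7, FN=3, TN=8, FP=2
        p = [0.9] * 7 + [0.1] * 3 + [0.1] * 8 + [0.9] * 2
        y = [1] * 10 + [0] * 10
        m = compute_classification_metrics(p, y)
        assert m["sensitivity"] == pytest.approx(70.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["balanced_accuracy"] == pytest.approx(75.0)

    def test_antiperfect_ranking_has_zero_auc(self):
        m = compute_classification_metrics([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert m["auc"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_classification_metrics([0.5, 0.6], [1, 1])

    def test_auc_matches_pairwise_oracle(self):
        def auc_oracle(p, y):
            """O(n^2) pairwise comparisons, ties counted 1/2."""
            pos = [pi for pi, yi in zip(p, y) if yi == 1]
            neg = [pi for pi, yi in zip(p, y) if yi == 0]
            wins = sum(
                1.0 if pp > pn else 0.5 if pp == pn else 0.0
                for pp in pos for pn in neg
            )
            return wins / (len(pos) * len(neg))

        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)  # rounding forces ties
            m = compute_classification_metrics(p, y)
            assert m["auc"] == pytest.approx(auc_oracle(p, y), abs=1e-12)


class TestRegressionMetrics:
    def test_exact_predictions(self):
        m = compute_regression_metrics([100, 90, 110], [100, 90, 110])
        assert m["pearson_r"] == pytest.approx(1.0)
        assert m["mae"] == 0.0
        assert m["std_ae"] == 0.0

    def test_hand_computed_mae(self):
        m = compute_regression_metrics([98, 94, 108, 100], [100, 90, 110, 95])
        assert m["mae"] == pytest.approx((2 + 4 + 2 + 5) / 4)

    def test_anticorrelation(self):
        y = np.array([100.0, 90.0, 110.0, 95.0])
        m = compute_regression_metrics(-y + 200, y)
        assert m["pearson_r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_regression_metrics([100, 100], [90, 95])


class TestRepeatedCV:
    def test_each_subject_tested_once_per_repeat(self, cohort80):
        spec = build_model("lr")
        res = run_repeated_cv(cohort80, spec, CVConfig(repeats=1, seed=0))
        assert res.n_models_trained == 5
        assert res.per_repeat_predictions.shape == (1, 80)
        assert np.all(np.isfinite(res.per_repeat_predictions))

    def test_null_cohort_auc_is_chance_level(self):
        null = generate_cohort(GeneratorConfig(n=60, seed=31))
        res = run_repeated_cv(null, build_model("lr"),
                              CVConfig(repeats=4, seed=1))
        aucs = res.record.values("auc")
        se = aucs.std(ddof=1) / np.sqrt(len(aucs)) + 1e-9
        assert abs(aucs.mean() - 0.5) < max(3 * se, 0.15)

    def test_augmentation_inside_folds_passes_leakage_audit(self, cohort80):
        aug = AugmentationConfig(expansion_factor=1.5, seed=5)
        res = run_repeated_cv(cohort80.subset(range(40)), build_model("lr"),
                              CVConfig(repeats=1, seed=2), aug=aug)
        assert res.record.per_repeat  # completed without LeakageError

    def test_leakage_audit_catches_contaminated_sample(self, cohort80):
        bad = Subject("synbad", cohort80[0].connectome, 95.0,
                      contributors=("S0001", "S0007"))
        fit = Cohort((*cohort80.subset(range(10, 20)).subjects, bad),
                     provenance="augmented")
        with pytest.raises(LeakageError, match="S0007"):
            _audit_no_leakage(fit, {"S0007"})

    def test_summary_reports_all_metrics_with_ci(self, cohort80):
        res = run_repeated_cv(cohort80, build_model("lr"),
                              CVConfig(repeats=2, seed=3))
        text = res.summary()
        for name in ("balanced_accuracy", "sensitivity", "specificity", "auc"):
            assert name in text
            lo, hi = res.record.ci(name)
            assert lo <= res.record.mean(name) <= hi

    def test_regression_task_metrics(self, cohort80):
        res = run_repeated_cv(cohort80, build_model("lr", task="regression"),
                              CVConfig(repeats=1, seed=4))
        rec = res.record.per_repeat[0]
        assert set(rec) == {"pearson_r", "p_value", "mae", "std_ae"}


class TestConfidenceIntervals:
    def test_percentile_ci_brackets_the_mean(self):
        rng = np.random.default_rng(5)
        v = rng.normal(70, 3, 50)
        lo, hi = percentile_ci(v)
        assert lo <= v.mean() <= hi

    def test_percentile_interval_stays_inside_population_interval(self):
        # on a fixed sampling distribution the empirical (2.5, 97.5)
        # percentile interval converges to the population interval from
        # the inside: its expected width never exceeds the population
        # width, at 5 or at 50 repeats (checked at 3 standard errors)
        rng = np.random.default_rng(6)
        pop_width = 2 * 1.959964  # N(0,1) central 95% interval
        for repeats in (5, 50):
            widths = []
            for _ in range(200):
                lo, hi = percentile_ci(rng.normal(0, 1, repeats))
                widths.append(hi - lo)
            se = np.std(widths) / np.sqrt(len(widths))
            assert np.mean(widths) <= pop_width + 3 * se


class TestROIPermutation:
    def test_permuted_matrices_keep_entry_multiset(self, cohort80):
        permuted, perm = permute_roi_order(cohort80.subset(range(5)), seed=8)
        for orig, new in zip(cohort80.subset(range(5)), permuted):
            a, b = orig.connectome.matrix, new.connectome.matrix
            assert np.array_equal(b, b.T)
            assert not np.diag(b).any()
            assert np.array_equal(np.sort(a, axis=None), np.sort(b, axis=None))
            assert orig.score == new.score

    def test_inverse_permutation_restores_original(self, cohort80):
        sub = cohort80.subset(range(3))
        permuted, perm = permute_roi_order(sub, seed=9)
        inv = np.argsort(perm)
        for orig, new in zip(sub, permuted):
            restored = new.connectome.matrix[np.ix_(inv, inv)]
            assert np.array_equal(restored, orig.connectome.matrix)

    def test_edge_identity_tracked_correlations_invariant(self, cohort80):
        from connectopred.interpretation import edge_outcome_correlation

        r_before = edge_outcome_correlation(cohort80, [(10, 60)])[(10, 60)]
        permuted, perm = permute_roi_order(cohort80, seed=10)
        # region with old index i (1-based) now sits at position of perm
        new_pos = {int(old) + 1: new + 1 for new, old in enumerate(perm)}
        i, j = sorted((new_pos[10], new_pos[60]))
        r_after = edge_outcome_correlation(permuted, [(i, j)])[(i, j)]
        assert r_after == pytest.approx(r_before, abs=1e-12)
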