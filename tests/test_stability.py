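"""LOSO cross-validation, tuning, importance stability, and the learner contract."""

import numpy as np
import pandas as pd
import pytest

from taxomark.consensus import pair_auc
from taxomark.ensemble import ReferenceRandomForest
from taxomark.stability import (
    FoldModel,
    cv_performance,
    importance_stability,
    loso_fit,
    run_stability_analysis,
    sample_params,
    tune_hyperparameters,
)
from taxomark.synthetic import SyntheticSpec, generate_cohort
from taxomark.io import filter_and_renormalize

from conftest import make_meta, make_table, spiked_spec

FAST = {"n_estimators": 30, "max_features": "sqrt"}


@pytest.fixture(scope="module")
def small_cohort():
    """20-sample spiked cohort, filtered; fast enough for repeated LOSO."""
    spec, idx = spiked_spec(seed=2, n_taxa=80, n_recurrence=8, n_non_recurrence=12)
    table, meta = generate_cohort(spec)
    return filter_and_renormalize(table), meta, table.taxon_ids[idx]


class TestLosoFit:
    def test_partition_property(self, small_cohort):
        table, meta, _ = small_cohort
        folds = loso_fit(table, meta, FAST, seed=5)
        assert len(folds) == 20
        left_out = [f.left_out_sample for f in folds]
        assert sorted(left_out) == sorted(table.sample_ids)
        assert all(f.n_training == 19 for f in folds)

    def test_importances_normalized(self, small_cohort):
        table, meta, _ = small_cohort
        folds = loso_fit(table, meta, FAST, seed=5)
        for f in folds:
            assert f.importance.shape == (table.shape[1],)
            assert f.importance.sum() == pytest.approx(1.0, abs=1e-6)
            assert (f.importance >= 0).all()

    def test_determinism(self, small_cohort):
        table, meta, _ = small_cohort
        a = loso_fit(table, meta, FAST, seed=11)
        b = loso_fit(table, meta, FAST, seed=11)
        assert [f.oof_probability for f in a] == [f.oof_probability for f in b]
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.importance, fb.importance)

    def test_column_order_invariance(self, small_cohort):
        table, meta, _ = small_cohort
        shuffled = table.values.sample(frac=1.0, axis=1, random_state=0)
        from taxomark.io import TaxonTable

        permuted = TaxonTable(shuffled, table.lineages, table.level)
        a = loso_fit(table, meta, FAST, seed=11)
        b = loso_fit(permuted, meta, FAST, seed=11)
        for fa, fb in zip(a, b):
            assert fa.taxa == fb.taxa
            np.testing.assert_array_equal(fa.importance, fb.importance)

    def test_single_class_training_fold_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        a = 50 + 20 * rng.random(5)
        table = make_table(np.column_stack([a, 100 - a]))
        meta = make_meta(["recurrence"] + ["non_recurrence"] * 4)
        folds = loso_fit(table, meta, FAST, seed=1)
        degenerate = [f for f in folds if f.degenerate]
        assert len(degenerate) == 1
        assert degenerate[0].left_out_sample == "S0"
        assert degenerate[0].oof_probability == 0.0  # training-class rate
        assert degenerate[0].importance.sum() == 0.0

    def test_too_few_samples(self):
        table = make_table([[100.0], [100.0]])
        meta = make_meta(["recurrence", "non_recurrence"])
        with pytest.raises(ValueError, match=">=3"):
            loso_fit(table, meta, FAST, seed=0)


def _fold(i, prob, imp, taxa, sample=None):
    imp = np.asarray(imp, dtype=float)
    return FoldModel(sample or f"S{i}", prob, imp, i, taxa, n_training=len(taxa))


class TestCVPerformance:
    taxa = ("g__A", "g__B")

    def test_perfect_classifier(self):
        meta = make_meta(["recurrence", "recurrence", "non_recurrence", "non_recurrence"])
        folds = [_fold(i, p, [0.5, 0.5], self.taxa)
                 for i, p in enumerate([1.0, 1.0, 0.0, 0.0])]
        perf = cv_performance(folds, meta)
        assert perf.accuracy == perf.sensitivity == perf.specificity == perf.auc == 1.0

    def test_uninformative_scores_auc_half(self):
        meta = make_meta(["recurrence", "non_recurrence", "recurrence", "non_recurrence"])
        folds = [_fold(i, 0.5, [1.0, 0.0], self.taxa) for i in range(4)]
        assert cv_performance(folds, meta).auc == pytest.approx(0.5)

    def test_auc_matches_pair_counting_oracle(self):
        # labels [0,0,1,1], probs [0.1,0.4,0.35,0.8]: of the 4 pos-neg pairs
        # 3 are concordant and 1 discordant -> AUC 0.75
        meta = make_meta(["non_recurrence", "non_recurrence", "recurrence", "recurrence"])
        probs = [0.1, 0.4, 0.35, 0.8]
        folds = [_fold(i, p, [1.0, 0.0], self.taxa) for i, p in enumerate(probs)]
        assert cv_performance(folds, meta).auc == pytest.approx(0.75)

    def test_missing_fold_is_an_error(self):
        meta = make_meta(["recurrence", "non_recurrence", "non_recurrence"])
        folds = [_fold(0, 1.0, [1.0, 0.0], self.taxa)]
        with pytest.raises(ValueError, match="missing folds"):
            cv_performance(folds, meta)


class TestTuning:
    def test_single_trial_is_that_config(self, small_cohort):
        table, meta, _ = small_cohort
        tuned = tune_hyperparameters(table, meta, n_trials=1, seed=3)
        assert len(tuned.trials) == 1
        assert tuned.objective == tuned.trials["objective"].iloc[0]

    def test_objective_is_max_over_trials(self, small_cohort):
        table, meta, _ = small_cohort
        tuned = tune_hyperparameters(table, meta, n_trials=3, seed=3)
        assert tuned.objective == pytest.approx(tuned.trials["objective"].max())

    def test_determinism(self, small_cohort):
        table, meta, _ = small_cohort
        a = tune_hyperparameters(table, meta, n_trials=2, seed=9)
        b = tune_hyperparameters(table, meta, n_trials=2, seed=9)
        assert a.params == b.params
        assert a.objective == b.objective

    def test_zero_trials_is_an_error(self, small_cohort):
        table, meta, _ = small_cohort
        with pytest.raises(ValueError, match="n_trials"):
            tune_hyperparameters(table, meta, n_trials=0, seed=0)

    def test_sampled_params_stay_in_space(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = sample_params(rng, "desk")
            assert 30 <= p["n_estimators"] <= 100
            assert p["max_depth"] is None or 2 <= p["max_depth"] <= 20
            assert p["min_samples_leaf"] in range(1, 9)
            assert p["class_weight"] in (None, "balanced")


class TestImportanceStability:
    taxa = tuple(f"g__T{j:02d}" for j in range(15))

    def _repeats(self, n_models=6, n_repeats=4, hero=0):
        """Synthetic folds where taxon `hero` always tops the importances."""
        rng = np.random.default_rng(7)
        repeats = []
        for _ in range(n_repeats):
            folds = []
            for i in range(n_models):
                imp = rng.dirichlet(np.ones(len(self.taxa)))
                imp[hero] = imp.max() + 1.0
                imp /= imp.sum()
                folds.append(_fold(i, 0.5, imp, self.taxa))
            repeats.append(folds)
        return repeats

    def test_ever_present_taxon_gets_maximum_total(self):
        reps = self._repeats(n_models=6, n_repeats=4)
        ranking = importance_stability(reps, k=10)
        assert ranking["total"].iloc[0] == 24  # 6 models x 4 repeats
        assert ranking.index[0] == self.taxa[0]
        assert ranking["final_rank"].iloc[0] == 1

    def test_counts_per_repeat_sum_to_k_times_folds(self):
        reps = self._repeats(n_models=6, n_repeats=4)
        ranking = importance_stability(reps, k=10)
        for r in range(1, 5):
            assert ranking[f"count_repeat_{r}"].sum() == 10 * 6

    def test_absent_taxon_total_zero(self):
        # two taxa, k=1: the non-hero taxon never enters a top-1
        taxa = ("g__A", "g__B")
        reps = [[_fold(i, 0.5, [0.9, 0.1], taxa) for i in range(3)]]
        ranking = importance_stability(reps, k=1)
        assert ranking.at["g__B", "total"] == 0

    def test_mismatched_taxa_is_an_error(self):
        a = [_fold(0, 0.5, [1.0, 0.0], ("g__A", "g__B"))]
        b = [_fold(0, 0.5, [1.0, 0.0], ("g__A", "g__C"))]
        with pytest.raises(ValueError, match="mismatched"):
            importance_stability([a, b])

    def test_tie_break_by_name_makes_topk_strict(self):
        taxa = ("g__C", "g__A", "g__B")
        reps = [[_fold(0, 0.5, [1 / 3, 1 / 3, 1 / 3], taxa)]]
        ranking = importance_stability(reps, k=2)
        counted = set(ranking.index[ranking["total"] == 1])
        assert counted == {"g__A", "g__B"}


class TestRunStabilityAnalysis:
    def test_duplicate_seeds_rejected(self, small_cohort):
        table, meta, _ = small_cohort
        with pytest.raises(ValueError, match="distinct"):
            run_stability_analysis(table, meta, FAST, seeds=[1, 1, 2, 3])

    def test_counts_shape_and_spike_recovery(self, small_cohort):
        table, meta, spike = small_cohort
        ranking, perfs = run_stability_analysis(
            table, meta, FAST, seeds=[1, 2, 3, 4], k=10
        )
        assert len(perfs) == 4
        count_cols = [c for c in ranking.columns if c.startswith("count_repeat_")]
        assert len(count_cols) == 4
        for c in count_cols:
            assert ranking[c].sum() == 10 * 20
        assert ranking.index[0] == spike


class TestLearnerContract:
    """Both the production learner and the plain-numpy reference satisfy the
    randomized-tree-ensemble contract on a separable problem."""

    @staticmethod
    def _toy(n=60, p=8, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.random((n, p))
        X[:, 2] += y * 0.8  # informative feature
        return X, y

    @pytest.mark.parametrize("learner_cls", [ReferenceRandomForest])
    def test_reference_forest_contract(self, learner_cls):
        X, y = self._toy()
        clf = learner_cls(n_estimators=30, max_features="sqrt", random_state=0)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert clf.feature_importances_.sum() == pytest.approx(1.0)
        assert int(np.argmax(clf.feature_importances_)) == 2
        assert pair_auc(proba[:, 1], y) > 0.9

    def test_reference_forest_backs_loso(self):
        spec, idx = spiked_spec(seed=3, n_taxa=30, n_recurrence=6, n_non_recurrence=9,
                                fold=8.0)
        table, meta = generate_cohort(spec)
        filt = filter_and_renormalize(table)
        folds = loso_fit(
            filt, meta, {"n_estimators": 15},
            seed=0,
            learner_factory=lambda **kw: ReferenceRandomForest(
                max_features="sqrt", **kw
            ),
        )
        assert len(folds) == 15
        for f in folds:
            assert 0.0 <= f.oof_probability <= 1.0
            assert f.importance.sum() == pytest.approx(1.0, abs=1e-6)
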