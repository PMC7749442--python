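"""PTB classification: AUROC, selection, integration, LOOCV, controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from momics import AnalysisConfig, GeneratorConfig, generate_dataset
from momics.datatypes import ValidationError
from momics.ptb import (
    PTBPredictionResult,
    auroc,
    auroc_with_ci,
    baseline_comparison,
    cohort_restricted_feature_selection,
    covariate_confounding_screen,
    integrate_predictions,
    loocv_predict,
    random_label_control,
)


def _pairwise_auroc(scores, labels):
    """All-pairs enumeration oracle."""
    cases = [s for s, l in zip(scores, labels) if l]
    controls = [s for s, l in zip(scores, labels) if not l]
    total = wins = 0
    for c in cases:
        for k in controls:
            total += 1
            wins += (c > k) + 0.5 * (c == k)
    return wins / total


class TestAUROC:
    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_and_all_ties(self):
        assert auroc([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert auroc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = np.zeros(n, dtype=bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            return
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        assert auroc(scores, labels) == pytest.approx(
            _pairwise_auroc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([0.1, 0.2], [1, 1])

    def test_bootstrap_ci_contains_point_and_narrows_with_n(self):
        rng = np.random.default_rng(1)
        cfg = AnalysisConfig(seed=1, n_bootstrap=400)
        widths = []
        for n in (40, 160):
            labels = np.arange(n) % 2 == 0
            scores = labels + rng.normal(0, 1.0, n)
            a, lo, hi = auroc_with_ci(scores, labels, cfg)
            assert lo <= a <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestFeatureSelection:
    def _toy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        y = np.arange(20) % 2 == 0
        cohorts = np.repeat(["A", "B"], 10)
        X[:, 3] = np.where(y, 5.0, -5.0)  # perfect separator everywhere
        return X, y, cohorts

    def test_perfect_separator_ranks_first(self):
        X, y, cohorts = self._toy()
        sel, pooled = cohort_restricted_feature_selection(X, y, cohorts, "A", 3)
        assert sel[0] == 3
        assert not pooled

    def test_k_top_one_returns_single_feature(self):
        X, y, cohorts = self._toy()
        sel, _ = cohort_restricted_feature_selection(X, y, cohorts, "B", 1)
        assert sel == [3]

    def test_tie_break_is_deterministic(self):
        X = np.zeros((8, 4))
        X[:, 2] = [0, 1, 0, 1, 0, 1, 0, 1]
        X[:, 0] = X[:, 2]  # identical -> identical p and effect, id breaks tie
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=bool)
        cohorts = np.array(["A"] * 8)
        fids = ["f0", "f1", "f2", "f3"]
        runs = [
            cohort_restricted_feature_selection(X, y, cohorts, None, 4, fids)[0]
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]
        assert runs[0][:2] == [0, 2]  # tied pair ordered by feature id

    def test_sparse_cohort_falls_back_to_pooled(self):
        X, y, cohorts = self._toy()
        cohorts = np.array(["A"] * 19 + ["B"])  # cohort B has one member
        sel, pooled = cohort_restricted_feature_selection(X, y, cohorts, "B", 3)
        assert pooled

    def test_invalid_k_rejected(self):
        X, y, cohorts = self._toy()
        with pytest.raises(ValidationError):
            cohort_restricted_feature_selection(X, y, cohorts, "A", 0)


class TestIntegration:
    def test_oracle_modality_dominates(self):
        rng = np.random.default_rng(3)
        y = np.arange(40) % 2 == 0
        P = np.column_stack(
            [np.where(y, 0.9, 0.1), rng.random(40), rng.random(40)]
        )
        cohorts = np.repeat(["A", "B"], 20)
        out = integrate_predictions(P, y, cohorts)
        assert auroc(out, y) > 0.95

    def test_identical_modalities_preserve_ordering_within_cohort(self):
        # with per-cohort intercepts the output is a per-cohort monotone
        # recalibration of the (shared) input probability
        rng = np.random.default_rng(4)
        y = np.arange(30) % 2 == 0
        p = rng.random(30)
        P = np.column_stack([p, p, p])
        cohorts = np.repeat(["A", "B", "C"], 10)
        out = integrate_predictions(P, y, cohorts)
        for c in "ABC":
            mask = cohorts == c
            order = np.argsort(p[mask])
            assert np.all(np.diff(out[mask][order]) >= -1e-12)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValidationError):
            integrate_predictions(
                np.array([[1.2, 0.5]]), np.array([True]), np.array(["A"])
            )


class TestLOOCV:
    def test_toy_dataset_yields_one_prediction_per_subject(self):
        cfg = GeneratorConfig(
            n_subjects=6, n_ptb=3, n_cohorts=2,
            dims={"transcriptomics": 10, "proteomics": 8, "metabolomics": 9},
            latent_rank={"transcriptomics": 2, "proteomics": 2, "metabolomics": 2},
            ga_informative=2, ptb_informative=2, seed=6,
        )
        ds, _ = generate_dataset(cfg)
        res = loocv_predict(
            ds, AnalysisConfig(seed=6, k_top=4, stacking_folds=2, inner_folds=2),
            with_ci=False,
        )
        assert len(res.predictions) == 6
        assert res.predictions["integrated"].between(0, 1).all()
        assert all(v <= 4 for v in res.median_selected.values())

    def test_held_out_label_mutation_never_changes_own_prediction(self, small_dataset):
        ds, _ = small_dataset
        cfg = AnalysisConfig(seed=7, k_top=8, stacking_folds=3, inner_folds=3)
        y = ds.subjects.ptb.copy()
        base = loocv_predict(ds, cfg, labels=y, with_ci=False)
        for i in (0, 5):
            y2 = y.copy()
            y2[i] = ~y2[i]
            mutated = loocv_predict(ds, cfg, labels=y2, with_ci=False)
            for col in [*ds.modalities, "integrated"]:
                assert base.predictions[col][i] == pytest.approx(
                    mutated.predictions[col][i], abs=1e-9
                )

    def test_random_label_control_shape(self, small_dataset):
        ds, _ = small_dataset
        cfg = AnalysisConfig(seed=8, k_top=6, stacking_folds=2, inner_folds=2)
        res = random_label_control(ds, n_reps=1, config=cfg)
        assert len(res.per_rep) == 4  # three modalities + integrated
        res2 = random_label_control(ds, n_reps=2, config=cfg)
        reps = res2.per_rep.groupby("rep")["auroc"].mean()
        assert len(reps) == 2


def test_baseline_comparison_covers_all_strategies(small_dataset):
    ds, _ = small_dataset
    cfg = AnalysisConfig(
        seed=9, k_top=6, stacking_folds=2, inner_folds=2, rf_trees=30
    )
    table = baseline_comparison(ds, cfg)
    assert set(table["strategy"]) == {
        "merging", "random_forest", "lasso",
        "stacked_generalization", "cohort_adjusted_integration",
    }
    assert table["auroc"].between(0, 1).all()


class TestCovariateScreen:
    def _result(self, prob, subjects):
        df = pd.DataFrame(
            {"subject_id": subjects.subject_ids, "integrated": prob,
             "label": subjects.ptb}
        )
        return PTBPredictionResult(
            predictions=df, performance=pd.DataFrame(),
            selected_features=pd.DataFrame(), median_selected={},
            n_pooled_fallback=0, mean_weights=np.zeros(3),
        )

    def test_identical_covariate_has_correlation_one(self, small_dataset):
        ds, _ = small_dataset
        rng = np.random.default_rng(10)
        prob = rng.random(len(ds.subjects))
        subjects = ds.subjects.subset(ds.subjects.subject_ids)
        subjects.df["mirror"] = prob
        out = covariate_confounding_screen(self._result(prob, subjects), subjects)
        row = out.set_index("covariate").loc["mirror"]
        assert row["rho"] == pytest.approx(1.0)

    def test_outcome_tracking_probability_flags_birthweight(self, small_dataset):
        ds, _ = small_dataset
        # probability that mirrors the true label: delivery GA and birthweight
        # are constructed from it, so both must light up
        prob = np.where(ds.subjects.ptb, 0.9, 0.1)
        out = covariate_confounding_screen(self._result(prob, ds.subjects), ds.subjects)
        out = out.set_index("covariate")
        assert out.loc["ga_delivery_weeks", "p_adj"] < 0.05
        assert out.loc["birthweight_g", "p_adj"] < 0.05
        assert abs(out.loc["ga_delivery_weeks", "rho"]) > 0.5

    def test_independent_noise_not_flagged(self, small_dataset):
        ds, _ = small_dataset
        rng = np.random.default_rng(11)
        prob = np.where(ds.subjects.ptb, 0.9, 0.1)
        subjects = ds.subjects.subset(ds.subjects.subject_ids)
        subjects.df["noise_cov"] = rng.normal(size=len(ds.subjects))
        out = covariate_confounding_screen(self._result(prob, subjects), subjects)
        assert out.set_index("covariate").loc["noise_cov", "p_adj"] > 0.05
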