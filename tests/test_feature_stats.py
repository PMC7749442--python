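"""Mixed-effect screening, Wilcoxon tests, modules, and enrichment."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from momics.datatypes import PathwayCollection, ValidationError
from momics.feature_stats import (
    detect_modules,
    enrich,
    mixed_effect_feature_test,
    rank_ptb_features,
    wilcoxon_feature_test,
)

from conftest import make_dataset


def _sim_random_intercept(seed, n_per=40, n_cohorts=5, effect=0.8, cohort_sd=1.0):
    rng = np.random.default_rng(seed)
    cohorts = np.repeat([f"c{i}" for i in range(n_cohorts)], n_per)
    shift = rng.normal(0, cohort_sd, n_cohorts)
    ptb = rng.random(n_per * n_cohorts) < 0.5
    values = (
        effect * ptb
        + shift[np.repeat(np.arange(n_cohorts), n_per)]
        + rng.normal(0, 1, n_per * n_cohorts)
    )
    return values, ptb, cohorts


class TestMixedModel:
    def test_reduces_to_ols_without_cohort_variance(self):
        values, ptb, cohorts = _sim_random_intercept(0, cohort_sd=0.0)
        mt = mixed_effect_feature_test(values, ptb, cohorts, standardize=False)
        ols = sm.OLS(values, sm.add_constant(ptb.astype(float))).fit()
        assert mt.coefficient == pytest.approx(float(ols.params[1]), abs=1e-6)

    def test_recovers_planted_effect(self):
        coefs = [
            mixed_effect_feature_test(
                *_sim_random_intercept(s), standardize=False
            ).coefficient
            for s in range(20)
        ]
        assert abs(np.mean(coefs) - 0.8) < 0.15

    def test_null_pvalues_are_uniform(self):
        pvals = [
            mixed_effect_feature_test(
                *_sim_random_intercept(s, effect=0.0), standardize=False
            ).p
            for s in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.05

    def test_requires_two_cohorts_and_both_classes(self):
        with pytest.raises(ValidationError):
            mixed_effect_feature_test(
                np.arange(10.0), np.arange(10) % 2 == 0, np.array(["A"] * 10)
            )
        with pytest.raises(ValidationError):
            mixed_effect_feature_test(
                np.arange(10.0), np.ones(10, dtype=bool), np.array(["A", "B"] * 5)
            )


class TestWilcoxon:
    def test_exact_textbook_example(self):
        # {1,2,3} vs {4,5,6}: 2 of the C(6,3)=20 assignments are as extreme
        p = wilcoxon_feature_test(
            np.array([1.0, 2, 3, 4, 5, 6]),
            np.array([True, True, True, False, False, False]),
        )
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        p = wilcoxon_feature_test(
            np.array([1.0, 2, 3, 1, 2, 3]),
            np.array([True, True, True, False, False, False]),
        )
        assert p == pytest.approx(1.0)

    def test_exact_and_approximate_branches_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.normal(size=16)
            labels = np.array([True] * 8 + [False] * 8)
            exact = stats.mannwhitneyu(
                vals[labels], vals[~labels], alternative="two-sided", method="exact"
            ).pvalue
            approx = stats.mannwhitneyu(
                vals[labels], vals[~labels], alternative="two-sided",
                method="asymptotic",
            ).pvalue
            assert abs(exact - approx) < 0.02
            assert wilcoxon_feature_test(vals, labels) == pytest.approx(exact)


class TestRankPTB:
    def test_ordering_deterministic_and_bh_monotone(self, small_dataset):
        ds, _ = small_dataset
        a = rank_ptb_features(ds)
        b = rank_ptb_features(ds)
        assert a["feature_id"].tolist() == b["feature_id"].tolist()
        assert (a["p_adj"] >= a["p_mixed"] - 1e-15).all()
        assert a["p_mixed"].is_monotonic_increasing

    def test_planted_features_enriched_at_top(self):
        # shared-effect regime with a strong planted difference: the screen
        # must put most planted features inside the top-2x window
        from momics import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(
            n_subjects=40, n_ptb=19, n_cohorts=4,
            dims={"transcriptomics": 40, "proteomics": 25, "metabolomics": 30},
            latent_rank={"transcriptomics": 2, "proteomics": 3, "metabolomics": 4},
            ga_informative=5, ptb_informative=6, ptb_effect=1.0,
            cohort_heterogeneity=0.0, seed=21,
        )
        ds, truth = generate_dataset(cfg)
        scores = rank_ptb_features(ds)
        hits = total = 0
        for mod in ds.modalities:
            planted = set(truth.ptb_features[mod])
            sub = scores[scores["modality"] == mod]
            window = set(sub.head(2 * len(planted))["feature_id"])
            hits += len(planted & window)
            total += len(planted)
        assert hits / total > 0.7


class TestModules:
    def _block_ds(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 1))
        b = rng.normal(size=(20, 1))
        X = np.hstack(
            [a + 0.05 * rng.normal(size=(20, 3)),
             b + 0.05 * rng.normal(size=(20, 3)),
             rng.normal(size=(20, 4))]
        )
        return make_dataset(
            {"proteomics": X}, ["A", "B"] * 10,
            np.full(20, 12.0), np.full(20, 40.0),
        )

    def test_two_planted_blocks_recovered(self):
        ds = self._block_ds()
        fids = ds.matrices["proteomics"].feature_ids
        modules = detect_modules(ds, fids, corr_threshold=0.8)
        ids = {modules[f] for f in fids[:3]} | {modules[f] for f in fids[3:6]}
        assert modules[fids[0]] == modules[fids[1]] == modules[fids[2]]
        assert modules[fids[3]] == modules[fids[4]] == modules[fids[5]]
        assert len(ids) == 2
        assert all(f not in modules for f in fids[6:])

    def test_impossible_threshold_yields_no_modules(self):
        ds = self._block_ds()
        assert detect_modules(ds, ds.matrices["proteomics"].feature_ids, 1.01) == {}

    def test_duplicated_features_share_a_module(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        X = np.column_stack([base, base, base + 0.01 * rng.normal(size=20),
                             rng.normal(size=20)])
        ds = make_dataset(
            {"proteomics": X}, ["A", "B"] * 10, np.full(20, 12.0), np.full(20, 40.0)
        )
        fids = ds.matrices["proteomics"].feature_ids
        modules = detect_modules(ds, fids, corr_threshold=0.99)
        assert modules[fids[0]] == modules[fids[1]] == modules[fids[2]]


class TestEnrichment:
    def _collection(self, universe, pathways):
        return PathwayCollection(
            pathways={pid: ("", frozenset(m)) for pid, m in pathways.items()},
            universe=frozenset(universe),
        )

    def test_hand_computed_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(20)]
        pw = self._collection(universe, {"pw": universe[:5]})
        module = set(universe[:4]) | set(universe[10:12])  # N=20, K=5, m=6, k=4
        res = enrich(module, pw)[0]
        assert res.overlap == 4
        assert res.p == pytest.approx(540 / 38760, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        pw = self._collection(universe, {"pw": universe[:4]})
        res = enrich(set(universe[4:8]), pw)[0]
        assert res.p == pytest.approx(1.0)

    def test_module_equal_pathway_equal_universe(self):
        universe = [f"g{i}" for i in range(8)]
        pw = self._collection(universe, {"pw": universe})
        assert enrich(set(universe), pw)[0].p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            N = int(rng.integers(10, 60))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            m = int(rng.integers(1, N))
            pathway = list(rng.choice(universe, K, replace=False))
            module = set(rng.choice(universe, m, replace=False))
            k = len(module & set(pathway))
            # brute-force tail: sum_{j>=k} C(K,j) C(N-K, m-j) / C(N,m)
            expected = sum(
                math.comb(K, j) * math.comb(N - K, m - j)
                for j in range(k, min(K, m) + 1)
                if m - j <= N - K
            ) / math.comb(N, m)
            res = enrich(module, self._collection(universe, {"pw": pathway}))[0]
            assert res.p == pytest.approx(expected, abs=1e-12)

    def test_empty_module_rejected(self):
        pw = self._collection(["a", "b"], {"pw": ["a"]})
        with pytest.raises(ValidationError):
            enrich(set(), pw)
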