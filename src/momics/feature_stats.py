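"""Univariate PTB feature statistics, correlation modules, and enrichment.

Each feature is compared between term and preterm pregnancies with a linear
mixed model in which the cohort enters as a random intercept — batch-level
shifts are absorbed by the random effect instead of inflating the PTB
contrast — alongside a distribution-free Wilcoxon rank-sum test. Top
features are grouped into correlated modules (connected components of a
thresholded |Spearman| graph) and modules are tested for pathway
over-representation with the one-sided Fisher exact (hypergeometric) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import logger
from .datatypes import MultiOmicsDataset, PathwayCollection, ValidationError


@dataclass
class MixedFeatureTest:
    coefficient: float
    p: float
    method: str  # "mixed" or the "ols" singular-fit fallback


def mixed_effect_feature_test(
    values: np.ndarray,
    ptb: np.ndarray,
    cohorts: np.ndarray,
    standardize: bool = True,
) -> MixedFeatureTest:
    """Linear mixed model value ~ ptb with a random intercept per cohort.

    Fit by REML; the Wald p-value of the PTB coefficient is reported. With
    ``standardize`` the response is z-scored first so the coefficient reads
    as a standardized mean difference. When the estimated cohort variance
    collapses to zero (singular fit) the model reduces to OLS, which is
    fitted instead and flagged.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(ptb, dtype=float)
    c = np.asarray(cohorts)
    if len(np.unique(c)) < 2:
        raise ValidationError("need at least 2 cohorts for a random intercept")
    if g.min() == g.max():
        raise ValidationError("both PTB classes must be present")
    if standardize:
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValidationError("constant feature")
        y = (y - y.mean()) / sd
    exog = sm.add_constant(g)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=c)
            fit = model.fit(reml=True)
        cov_re = float(np.asarray(fit.cov_re)[0, 0])
        singular = (not np.isfinite(cov_re)) or cov_re < 1e-8
        pval = float(np.asarray(fit.pvalues)[1])
        if not singular and np.isfinite(pval):
            return MixedFeatureTest(float(np.asarray(fit.params)[1]), pval, "mixed")
    except (np.linalg.LinAlgError, ValueError):
        pass
    ols = sm.OLS(y, exog).fit()
    return MixedFeatureTest(float(ols.params[1]), float(ols.pvalues[1]), "ols")


def wilcoxon_feature_test(values: np.ndarray, ptb: np.ndarray) -> float:
    """Two-sided rank-sum p for a PTB vs term difference in one feature.

    Exact enumeration when the smaller class has <= 8 subjects and there are
    no ties; otherwise the normal approximation with tie correction.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(ptb, dtype=bool)
    a, b = y[g], y[~g]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both classes need at least one subject")
    no_ties = len(np.unique(y)) == len(y)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def rank_ptb_features(dataset: MultiOmicsDataset) -> pd.DataFrame:
    """Mixed-model and Wilcoxon statistics for every feature.

    BH adjustment of the mixed-model p is done within each modality (the
    assays differ by orders of magnitude in width, so pooling would let the
    widest drown the narrowest). Sorted by mixed-model p, ties by feature id.
    """
    ptb = dataset.subjects.ptb
    cohorts = dataset.subjects.cohort
    frames = []
    for mod in dataset.modalities:
        mat = dataset.matrices[mod]
        X = mat.values
        rows = []
        for j, fid in enumerate(mat.feature_ids):
            col = X[:, j]
            if np.ptp(col) == 0:
                logger.info("rank_ptb_features: %s constant; skipped", fid)
                continue
            mt = mixed_effect_feature_test(col, ptb, cohorts)
            rows.append(
                {
                    "feature_id": fid,
                    "modality": mod,
                    "coefficient": mt.coefficient,
                    "p_mixed": mt.p,
                    "method": mt.method,
                    "p_wilcoxon": wilcoxon_feature_test(col, ptb),
                }
            )
        sub = pd.DataFrame(rows)
        sub["p_adj"] = multipletests(sub["p_mixed"], method="fdr_bh")[1]
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["p_mixed", "feature_id"]).reset_index(drop=True)


def detect_modules(
    dataset: MultiOmicsDataset,
    top_features: list[str],
    corr_threshold: float = 0.6,
) -> dict[str, str]:
    """Group top features into correlated modules.

    Edges join feature pairs with |Spearman rho| >= threshold; modules are
    connected components with at least 3 members (numbered by size, then by
    smallest member id). Smaller components stay unassigned.
    """
    if len(top_features) < 2:
        raise ValidationError("need at least 2 features to detect modules")
    X, fids, _ = dataset.concatenated()
    pos = {f: i for i, f in enumerate(fids)}
    missing = [f for f in top_features if f not in pos]
    if missing:
        raise ValidationError(f"unknown feature(s): {missing[:5]}")
    sub = X[:, [pos[f] for f in top_features]]
    ranks = stats.rankdata(sub, axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    G = nx.Graph()
    G.add_nodes_from(top_features)
    n = len(top_features)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) >= corr_threshold:
                G.add_edge(top_features[i], top_features[j])
    comps = [c for c in nx.connected_components(G) if len(c) >= 3]
    comps.sort(key=lambda c: (-len(c), min(c)))
    assignment: dict[str, str] = {}
    for k, comp in enumerate(comps, start=1):
        for f in comp:
            assignment[f] = f"M{k}"
    return assignment


@dataclass
class EnrichmentResult:
    pathway_id: str
    overlap: int      # k: module members in the pathway
    module_size: int  # m
    pathway_size: int  # K
    universe_size: int  # N
    p: float


def enrich(
    module_features: set[str], pathways: PathwayCollection
) -> list[EnrichmentResult]:
    """One-sided Fisher exact (hypergeometric upper tail) over-representation.

    p = sum_{j >= k} C(K, j) C(N-K, m-j) / C(N, m) for each pathway, where N
    is the universe size, K the pathway size, m the module size, and k the
    overlap. Results sorted by ascending p, ties by pathway id.
    """
    module = set(map(str, module_features))
    if not module:
        raise ValidationError("empty module")
    extra = module - pathways.universe
    if extra:
        raise ValidationError(
            f"module features outside the universe: {sorted(extra)[:5]}"
        )
    N = len(pathways.universe)
    m = len(module)
    results = []
    for pid, (_, members) in pathways.pathways.items():
        K = len(members)
        k = len(module & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        results.append(EnrichmentResult(pid, k, m, K, N, min(p, 1.0)))
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results
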