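"""Leave-one-out, cohort-adjusted, late-integrated preterm-birth classification.

For every held-out subject the pipeline (per modality) z-scores features
with training-set statistics computed within each cohort, restricts the
feature space to the top univariate (Wilcoxon rank-sum) discriminators in
the held-out subject's cohort, and fits an L2-regularized logistic model
whose penalty is chosen by an inner stratified cross-validation. A second
integration layer — a logistic model with non-negative modality weights and
per-cohort intercepts — combines the three modality probabilities; it is
trained on out-of-fold probabilities generated inside the training set only,
so a subject's own label can never influence its own prediction.

Also provides the permuted-label null control, simpler comparator
strategies (feature merging, plain stacking, random forest, lasso), and the
clinical-covariate confounding screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from ._logistic import RidgeLogistic, balanced_weights, fit_logistic_cv
from ._utils import child_seed, logger, spearman_test, zscore_apply, zscore_fit
from .datatypes import AnalysisConfig, MultiOmicsDataset, ValidationError


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _ranksum_screen(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Wilcoxon rank-sum over columns.

    Returns (normal-approximation two-sided p, rank-biserial effect). Used
    only to rank candidate features, so the cheap approximation (no
    continuity correction) is adequate; constant columns get p = 1.
    """
    n1 = int(y.sum())
    n2 = int((~y).sum())
    n = n1 + n2
    R = stats.rankdata(X, axis=0)
    U = R[y].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    with np.errstate(invalid="ignore"):
        z = (U - mu) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)
    rb = 2.0 * U / (n1 * n2) - 1.0
    return p, rb


def cohort_restricted_feature_selection(
    train_values: np.ndarray,
    labels: np.ndarray,
    cohorts: np.ndarray,
    test_cohort,
    k_top: int,
    feature_ids: list[str] | None = None,
) -> tuple[list[int], bool]:
    """Rank features by Wilcoxon rank-sum p within the held-out subject's cohort.

    Only training subjects from ``test_cohort`` enter the test; if that
    cohort lacks 2 members of either class (or ``test_cohort`` is None), the
    pooled training set is used instead and the fallback is flagged. Returns
    up to ``k_top`` column indices ordered by ascending p, ties broken by
    descending |rank-biserial effect| then feature id.
    """
    if k_top < 1:
        raise ValidationError("k_top must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    pooled = True
    rows = np.arange(len(labels))
    if test_cohort is not None:
        in_cohort = np.asarray(cohorts) == test_cohort
        if labels[in_cohort].sum() >= 2 and (~labels[in_cohort]).sum() >= 2:
            rows = np.where(in_cohort)[0]
            pooled = False
        else:
            logger.debug(
                "cohort %r lacks both classes in training; pooled selection", test_cohort
            )
    X = train_values[rows]
    y = labels[rows]
    p, rb = _ranksum_screen(X, y)
    if feature_ids is not None:
        fid_rank = np.argsort(np.argsort(np.asarray(feature_ids)))
    else:
        fid_rank = np.arange(X.shape[1])
    order = np.lexsort((fid_rank, -np.abs(rb), p))
    return list(order[:k_top]), pooled


# ---------------------------------------------------------------------------
# per-cohort standardization
# ---------------------------------------------------------------------------

def _cohort_zscore(
    X: np.ndarray, cohorts: np.ndarray, train_idx: np.ndarray
) -> np.ndarray:
    """Z-score every row with statistics from training subjects of its cohort.

    A cohort with fewer than 2 training members falls back to global
    training statistics.
    """
    Z = np.empty_like(X, dtype=float)
    g_mu, g_sd = zscore_fit(X[train_idx])
    train_set = np.zeros(len(X), dtype=bool)
    train_set[train_idx] = True
    for c in np.unique(cohorts):
        members = np.asarray(cohorts) == c
        tr_members = members & train_set
        if tr_members.sum() >= 2:
            mu, sd = zscore_fit(X[tr_members])
        else:
            mu, sd = g_mu, g_sd
        Z[members] = zscore_apply(X[members], mu, sd)
    return Z


def _global_zscore(X: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    mu, sd = zscore_fit(X[train_idx])
    return zscore_apply(X, mu, sd)


# ---------------------------------------------------------------------------
# integration layer
# ---------------------------------------------------------------------------

class Integrator:
    """Logistic stacker: non-negative modality weights, per-cohort intercepts."""

    ridge = 1e-2

    def __init__(self) -> None:
        self.weights: np.ndarray | None = None
        self.intercepts: dict = {}
        self.fallback = False

    def fit(self, probs: np.ndarray, labels: np.ndarray, cohorts: np.ndarray,
            per_cohort_intercepts: bool = True) -> "Integrator":
        P = np.asarray(probs, dtype=float)
        y = np.asarray(labels, dtype=float)
        if np.all(P.std(axis=0) <= 1e-12):
            logger.warning("integration inputs are constant; equal-weight fallback")
            self.fallback = True
            self.weights = np.full(P.shape[1], 1.0 / P.shape[1])
            self.intercepts = {"__mean__": 0.0}
            return self
        levels = sorted(map(str, np.unique(cohorts))) if per_cohort_intercepts else ["__all__"]
        idx = (
            {c: np.asarray(cohorts).astype(str) == c for c in levels}
            if per_cohort_intercepts
            else {"__all__": np.ones(len(y), dtype=bool)}
        )
        M, C = P.shape[1], len(levels)
        # Class balance within each intercept group: a cohort's intercept
        # must not track its leave-one-out class prevalence, or held-out
        # scores anti-correlate with their labels under the null.
        yb = np.asarray(labels, dtype=bool)
        sw = np.empty(len(yb))
        for c, members in idx.items():
            for cls in (True, False):
                cell = members & (yb == cls)
                if cell.any():
                    sw[cell] = members.sum() / (2.0 * cell.sum())
            if not (members & yb).any() or not (members & ~yb).any():
                sw[members] = balanced_weights(yb)[members]
        sw = sw / sw.sum()

        def loss(theta: np.ndarray) -> float:
            w, b = theta[:M], theta[M:]
            eta = P @ w
            for k, c in enumerate(levels):
                eta = eta + b[k] * idx[c]
            z = np.clip(eta, -30, 30)
            ll = sw @ (np.log1p(np.exp(-z)) + (1 - y) * z)
            return ll + self.ridge * (w @ w + b @ b)

        x0 = np.concatenate([np.ones(M), np.zeros(C)])
        bounds = [(0.0, None)] * M + [(None, None)] * C
        res = optimize.minimize(loss, x0, method="L-BFGS-B", bounds=bounds)
        self.weights = res.x[:M]
        self.intercepts = {c: float(b) for c, b in zip(levels, res.x[M:])}
        return self

    def predict(self, probs: np.ndarray, cohorts: np.ndarray) -> np.ndarray:
        P = np.asarray(probs, dtype=float)
        if self.fallback:
            return P.mean(axis=1)
        mean_b = float(np.mean(list(self.intercepts.values())))
        if "__all__" in self.intercepts:
            b = np.full(len(P), self.intercepts["__all__"])
        else:
            b = np.array(
                [self.intercepts.get(str(c), mean_b) for c in np.asarray(cohorts)]
            )
        eta = np.clip(P @ self.weights + b, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


def integrate_predictions(
    per_modality_probs: np.ndarray, labels: np.ndarray, cohorts: np.ndarray
) -> np.ndarray:
    """Fit the weighted integration layer and return its probabilities."""
    P = np.asarray(per_modality_probs, dtype=float)
    if P.min() < 0 or P.max() > 1:
        raise ValidationError("per-modality inputs must be probabilities in [0, 1]")
    return Integrator().fit(P, labels, cohorts).predict(P, cohorts)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(case score > control score) + 0.5 P(equal)."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auroc_with_ci(
    scores: np.ndarray, labels: np.ndarray, config: AnalysisConfig
) -> tuple[float, float, float]:
    """Point AUROC with a stratified-bootstrap percentile 95% CI."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    point = auroc(s, y)
    rng = np.random.default_rng(child_seed(config.seed, 4))
    case_idx, ctrl_idx = np.where(y)[0], np.where(~y)[0]
    boot = np.empty(config.n_bootstrap)
    for b in range(config.n_bootstrap):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ni = rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True)
        idx = np.concatenate([ci, ni])
        boot[b] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return point, float(lo), float(hi)


# ---------------------------------------------------------------------------
# LOOCV pipeline
# ---------------------------------------------------------------------------

@dataclass
class PTBPredictionResult:
    """Out-of-fold probabilities and performance of the PTB models."""

    predictions: pd.DataFrame      # subject_id, per-modality, integrated, label
    performance: pd.DataFrame      # model, auroc, ci_low, ci_high
    selected_features: pd.DataFrame  # subject_id (fold), modality, features
    median_selected: dict
    n_pooled_fallback: int
    mean_weights: np.ndarray


def _fit_l2_logistic(Xtr, ytr, config: AnalysisConfig, seed: int) -> RidgeLogistic:
    """Inner cross-validation picks the L2 penalty (second model layer)."""
    return fit_logistic_cv(Xtr, ytr, config.logistic_C_grid, config.inner_folds, seed)


def _stack_training_probs(
    dataset: MultiOmicsDataset,
    train: np.ndarray,
    y: np.ndarray,
    cohorts: np.ndarray,
    config: AnalysisConfig,
    cohort_adjusted: bool,
    seed: int,
    C_by_modality: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-modality out-of-fold probabilities for the training subjects only.

    Each inner fit reuses the penalty the outer model chose for its modality
    so the stacking layer is trained on probabilities with the same
    calibration as the ones it will combine.
    """
    mods = dataset.modalities
    C_by_modality = C_by_modality or {}
    P = np.full((len(train), len(mods)), 0.5)
    folds = min(config.stacking_folds, int(min(y[train].sum(), (~y[train]).sum())))
    if folds < 2:
        return P
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    for itr, ite in skf.split(train, y[train]):
        g_tr, g_te = train[itr], train[ite]
        for j, mod in enumerate(mods):
            X = dataset.matrices[mod].values
            fids = dataset.matrices[mod].feature_ids
            if cohort_adjusted:
                Z = _cohort_zscore(X, cohorts, g_tr)
                for c in np.unique(np.asarray(cohorts)[g_te]):
                    sel, _ = cohort_restricted_feature_selection(
                        Z[g_tr], y[g_tr], cohorts[g_tr], c, config.k_top, fids
                    )
                    members = g_te[np.asarray(cohorts)[g_te] == c]
                    clf = RidgeLogistic(C=C_by_modality.get(mod, 1.0)).fit(
                        Z[g_tr][:, sel], y[g_tr], balanced_weights(y[g_tr])
                    )
                    probs = clf.predict_proba1(Z[members][:, sel])
                    for pos, m in enumerate(members):
                        P[np.where(train == m)[0][0], j] = probs[pos]
            else:
                Z = _global_zscore(X, g_tr)
                sel, _ = cohort_restricted_feature_selection(
                    Z[g_tr], y[g_tr], cohorts[g_tr], None, config.k_top, fids
                )
                clf = RidgeLogistic(C=C_by_modality.get(mod, 1.0)).fit(
                    Z[g_tr][:, sel], y[g_tr], balanced_weights(y[g_tr])
                )
                probs = clf.predict_proba1(Z[g_te][:, sel])
                for pos, m in enumerate(g_te):
                    P[np.where(train == m)[0][0], j] = probs[pos]
    return P


def loocv_predict(
    dataset: MultiOmicsDataset,
    config: AnalysisConfig,
    labels: np.ndarray | None = None,
    cohort_adjusted: bool = True,
    with_ci: bool = True,
) -> PTBPredictionResult:
    """Leave-one-out cross-validated PTB probabilities, per modality and integrated.

    ``cohort_adjusted=False`` gives the plain stacked-generalization
    comparator: global z-scoring, pooled univariate selection, and a single
    intercept in the integration layer.
    """
    subjects = dataset.subjects
    y = np.asarray(labels if labels is not None else subjects.ptb, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    cohorts = subjects.cohort.astype(str)
    mods = dataset.modalities
    n = len(y)

    probs = {m: np.full(n, np.nan) for m in mods}
    probs["integrated"] = np.full(n, np.nan)
    sel_records = []
    n_pooled = 0
    weight_sum = np.zeros(len(mods))

    for i in range(n):
        train = np.delete(np.arange(n), i)
        seed_i = child_seed(config.seed, 5)
        row = np.zeros(len(mods))
        chosen_C: dict[str, float] = {}
        for j, mod in enumerate(mods):
            X = dataset.matrices[mod].values
            fids = dataset.matrices[mod].feature_ids
            if cohort_adjusted:
                Z = _cohort_zscore(X, cohorts, train)
                sel, pooled = cohort_restricted_feature_selection(
                    Z[train], y[train], cohorts[train], cohorts[i], config.k_top, fids
                )
            else:
                Z = _global_zscore(X, train)
                sel, pooled = cohort_restricted_feature_selection(
                    Z[train], y[train], cohorts[train], None, config.k_top, fids
                )
                pooled = False
            n_pooled += int(pooled and cohort_adjusted)
            clf = _fit_l2_logistic(Z[train][:, sel], y[train], config, seed_i)
            chosen_C[mod] = clf.C
            row[j] = float(clf.predict_proba1(Z[i][sel].reshape(1, -1))[0])
            probs[mod][i] = row[j]
            sel_records.append(
                {
                    "subject_id": subjects.subject_ids[i],
                    "modality": mod,
                    "n_selected": len(sel),
                    "features": ";".join(fids[k] for k in sel),
                }
            )
        P_train = _stack_training_probs(
            dataset, train, y, cohorts, config, cohort_adjusted, seed_i, chosen_C
        )
        integ = Integrator().fit(
            P_train, y[train], cohorts[train], per_cohort_intercepts=cohort_adjusted
        )
        probs["integrated"][i] = integ.predict(row.reshape(1, -1), [cohorts[i]])[0]
        weight_sum += integ.weights

    perf_rows = []
    for name in [*mods, "integrated"]:
        if with_ci:
            a, lo, hi = auroc_with_ci(probs[name], y, config)
        else:
            a, lo, hi = auroc(probs[name], y), np.nan, np.nan
        perf_rows.append({"model": name, "auroc": a, "ci_low": lo, "ci_high": hi})

    sel_df = pd.DataFrame(sel_records)
    median_selected = {
        m: float(sel_df.loc[sel_df["modality"] == m, "n_selected"].median())
        for m in mods
    }
    predictions = pd.DataFrame(
        {"subject_id": subjects.subject_ids, **probs, "label": y}
    )
    return PTBPredictionResult(
        predictions=predictions,
        performance=pd.DataFrame(perf_rows),
        selected_features=sel_df,
        median_selected=median_selected,
        n_pooled_fallback=n_pooled,
        mean_weights=weight_sum / n,
    )


# ---------------------------------------------------------------------------
# null control, baselines, confounding screen
# ---------------------------------------------------------------------------

@dataclass
class RandomLabelResult:
    per_rep: pd.DataFrame    # rep, model, auroc
    summary: pd.DataFrame    # model, mean_auroc, sd_auroc


def random_label_control(
    dataset: MultiOmicsDataset, n_reps: int, config: AnalysisConfig
) -> RandomLabelResult:
    """Run the full LOOCV + integration pipeline on permuted labels.

    Class sizes are preserved (labels are shuffled, not redrawn); the mean
    integrated AUROC should sit at chance if the pipeline does not overfit.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    y = dataset.subjects.ptb
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(child_seed(config.seed, 10 + rep))
        y_perm = rng.permutation(y)
        res = loocv_predict(
            dataset, config.with_seed(child_seed(config.seed, 10 + rep)),
            labels=y_perm, with_ci=False,
        )
        for _, r in res.performance.iterrows():
            rows.append({"rep": rep, "model": r["model"], "auroc": r["auroc"]})
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("model", sort=False)["auroc"]
        .agg(mean_auroc="mean", sd_auroc="std")
        .reset_index()
    )
    return RandomLabelResult(per_rep, summary)


def _loocv_merged(
    dataset: MultiOmicsDataset, y: np.ndarray, config: AnalysisConfig, learner: str
) -> np.ndarray:
    X, _, _ = dataset.concatenated()
    n = len(y)
    oof = np.empty(n)
    seed = child_seed(config.seed, 6)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Z = _global_zscore(X, train)
        if learner == "logistic":
            clf = _fit_l2_logistic(Z[train], y[train], config, seed)
            oof[i] = float(clf.predict_proba1(Z[i].reshape(1, -1))[0])
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if learner == "lasso":
                clf = LogisticRegressionCV(
                    Cs=list(config.logistic_C_grid),
                    cv=StratifiedKFold(config.inner_folds, shuffle=True, random_state=seed),
                    penalty="l1", solver="liblinear", scoring="neg_log_loss",
                    random_state=seed,
                )
                clf.fit(Z[train], y[train])
            elif learner == "random_forest":
                clf = RandomForestClassifier(
                    n_estimators=config.rf_trees, random_state=seed, n_jobs=1
                )
                clf.fit(Z[train], y[train])
            else:  # pragma: no cover
                raise ValueError(learner)
            oof[i] = clf.predict_proba(Z[i].reshape(1, -1))[0, 1]
    return oof


def baseline_comparison(
    dataset: MultiOmicsDataset, config: AnalysisConfig
) -> pd.DataFrame:
    """AUROC of comparator strategies under the same LOOCV protocol.

    Strategies: feature merging (one model on concatenated features), plain
    stacked generalization (no cohort adjustment), single-learner baselines
    (random forest, lasso) on merged features, and the full cohort-adjusted
    integration.
    """
    y = dataset.subjects.ptb
    rows = []
    for name, learner in [
        ("merging", "logistic"),
        ("random_forest", "random_forest"),
        ("lasso", "lasso"),
    ]:
        oof = _loocv_merged(dataset, y, config, learner)
        rows.append({"strategy": name, "auroc": auroc(oof, y)})
    plain = loocv_predict(dataset, config, cohort_adjusted=False, with_ci=False)
    rows.append(
        {
            "strategy": "stacked_generalization",
            "auroc": float(
                plain.performance.set_index("model").loc["integrated", "auroc"]
            ),
        }
    )
    adjusted = loocv_predict(dataset, config, cohort_adjusted=True, with_ci=False)
    rows.append(
        {
            "strategy": "cohort_adjusted_integration",
            "auroc": float(
                adjusted.performance.set_index("model").loc["integrated", "auroc"]
            ),
        }
    )
    return pd.DataFrame(rows)


def covariate_confounding_screen(
    result: PTBPredictionResult, subjects
) -> pd.DataFrame:
    """Spearman correlation of the integrated probability with each covariate.

    Categorical covariates are expanded one-vs-rest. Benjamini-Hochberg
    adjustment across all screened covariates; constant covariates skipped.
    """
    prob = result.predictions["integrated"].to_numpy(dtype=float)
    df = subjects.df
    rows = []
    skip = {"subject_id", "ptb"}
    candidates = [c for c in df.columns if c not in skip]
    if len(candidates) < 3:
        raise ValidationError("need at least 3 covariates to screen")
    for col in candidates:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            x = series.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                logger.info("covariate %s constant; skipped", col)
                continue
            rho, p = spearman_test(prob, x)
            rows.append({"covariate": col, "rho": rho, "p": p})
        else:
            for level in sorted(series.astype(str).unique()):
                ind = (series.astype(str) == level).to_numpy(dtype=float)
                if np.ptp(ind) == 0:
                    continue
                rho, p = spearman_test(prob, ind)
                rows.append({"covariate": f"{col}={level}", "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p").reset_index(drop=True)
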