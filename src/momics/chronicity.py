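"""Gestational-age (chronicity) estimation by stacked per-modality models.

Each modality gets its own L1-regularized linear model of GA at sampling;
an integration layer combines the three per-modality estimates with
non-negative least squares. Everything is evaluated under a two-layer
cross-validation: an outer K-fold producing out-of-fold estimates for unseen
subjects, and inner folds (penalty selection, and stacking-layer training
predictions) confined to each outer training set so no subject's own outcome
can reach its own estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from ._utils import (
    child_seed,
    logger,
    permutation_pvalue,
    spearman_matrix,
    spearman_test,
    zscore_apply,
    zscore_fit,
)
from .datatypes import AnalysisConfig, FeatureMatrix, MultiOmicsDataset, ValidationError

N_MODELS_TESTED = 4  # three modalities + the integrated model (Bonferroni factor)


@dataclass
class GAPredictionResult:
    """Out-of-fold GA estimates and their correlation with the truth."""

    predictions: pd.DataFrame   # subject_id, per-modality, integrated, truth
    performance: pd.DataFrame   # model, rho, p_raw, p_bonferroni
    weights: pd.DataFrame       # per outer fold: NNLS weight per modality


def _fit_lasso(Xtr, ytr, config: AnalysisConfig, seed: int) -> LassoCV:
    model = LassoCV(
        alphas=config.lasso_n_alphas,  # size of the automatic penalty path
        cv=KFold(min(config.inner_folds, len(ytr)), shuffle=True, random_state=seed),
        random_state=seed,
        max_iter=5000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xtr, ytr)
    return model


def _nnls_with_intercept(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||A w + b - y|| subject to w >= 0, b free."""
    Ac = A - A.mean(axis=0)
    yc = y - y.mean()
    if not np.any(Ac.std(axis=0) > 0):
        w = np.zeros(A.shape[1])
    else:
        w, _ = nnls(Ac, yc)
    b = float(y.mean() - A.mean(axis=0) @ w)
    return w, b


def predict_ga_cv(dataset: MultiOmicsDataset, config: AnalysisConfig) -> GAPredictionResult:
    """Two-layer cross-validated GA estimation.

    Outer K-fold (default 10) over subjects. Within each outer training set:
    per modality, a LassoCV model (inner folds pick the penalty) predicts the
    outer test fold; the integration weights come from non-negative least
    squares on per-modality predictions generated by a second K-fold inside
    the training set, so the stacking layer never sees its own training
    optimism, and no held-out subject influences any model that scores it.
    """
    subjects = dataset.subjects
    y = subjects.ga_sampling_weeks
    n = len(y)
    mods = dataset.modalities
    outer_k = config.outer_folds
    if n < 2 * outer_k:
        outer_k = max(2, n // 2)
        logger.warning("reducing outer folds to %d for n=%d", outer_k, n)

    oof = {m: np.full(n, np.nan) for m in mods}
    oof["integrated"] = np.full(n, np.nan)
    fold_weights = []

    outer = KFold(outer_k, shuffle=True, random_state=config.seed)
    for fold, (tr, te) in enumerate(outer.split(np.arange(n))):
        test_preds = np.zeros((len(te), len(mods)))
        for j, mod in enumerate(mods):
            X = dataset.matrices[mod].values
            mu, sd = zscore_fit(X[tr])
            model = _fit_lasso(
                zscore_apply(X[tr], mu, sd), y[tr], config, child_seed(config.seed, fold)
            )
            pred = model.predict(zscore_apply(X[te], mu, sd))
            oof[mod][te] = pred
            test_preds[:, j] = pred

        # Stacking-layer training data: inner out-of-fold per-modality estimates.
        inner_k = min(config.stacking_folds, len(tr) // 2)
        A = np.zeros((len(tr), len(mods)))
        inner = KFold(inner_k, shuffle=True, random_state=child_seed(config.seed, fold))
        for itr, ite in inner.split(tr):
            g_tr, g_te = tr[itr], tr[ite]
            for j, mod in enumerate(mods):
                X = dataset.matrices[mod].values
                mu, sd = zscore_fit(X[g_tr])
                model = _fit_lasso(
                    zscore_apply(X[g_tr], mu, sd), y[g_tr], config,
                    child_seed(config.seed, fold),
                )
                A[ite, j] = model.predict(zscore_apply(X[g_te], mu, sd))
        w, b = _nnls_with_intercept(A, y[tr])
        oof["integrated"][te] = test_preds @ w + b
        fold_weights.append([fold, *w])

    rows = []
    for name in [*mods, "integrated"]:
        rho, p = spearman_test(oof[name], y)
        rows.append(
            {
                "model": name,
                "rho": rho,
                "p_raw": p,
                "p_bonferroni": min(1.0, N_MODELS_TESTED * p),
            }
        )
    predictions = pd.DataFrame(
        {"subject_id": subjects.subject_ids, **oof, "truth": y}
    )
    weights = pd.DataFrame(fold_weights, columns=["fold", *mods])
    return GAPredictionResult(predictions, pd.DataFrame(rows), weights)


def rank_ga_features(dataset: MultiOmicsDataset) -> pd.DataFrame:
    """Per-feature Spearman correlation with GA at sampling, across modalities.

    Constant features are excluded (logged). Sorted by |rho| descending,
    ties broken by feature id; features with p < 0.05 are flagged.
    """
    if dataset.n_subjects < 5:
        raise ValidationError("need at least 5 subjects to rank GA features")
    y = dataset.subjects.ga_sampling_weeks
    frames = []
    for mod in dataset.modalities:
        mat = dataset.matrices[mod]
        X = mat.values
        keep = X.std(axis=0) > 0
        if (~keep).any():
            logger.info(
                "rank_ga_features: excluded %d constant feature(s) in %s",
                int((~keep).sum()), mod,
            )
        rho, p = spearman_matrix(X[:, keep], y)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": np.array(mat.feature_ids)[keep],
                    "modality": mod,
                    "rho": rho,
                    "p": p,
                    "significant": p < 0.05,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["abs_rho"] = out["rho"].abs()
    out = (
        out.sort_values(["abs_rho", "feature_id"], ascending=[False, True])
        .drop(columns="abs_rho")
        .reset_index(drop=True)
    )
    return out


@dataclass
class SurrogateResult:
    """Urine-metabolome surrogate for a plasma protein (random-forest CV)."""

    oof_predictions: np.ndarray
    spearman_r: float
    p: float


def surrogate_model(
    metabolome: FeatureMatrix, target: np.ndarray, config: AnalysisConfig
) -> SurrogateResult:
    """Cross-validated random-forest regression of a plasma target (e.g. PGF)
    on urine metabolite features, with a permutation p for the Spearman
    correlation of out-of-fold predictions with the truth."""
    y = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("target contains non-finite values")
    if np.ptp(y) == 0:
        raise ValidationError("constant target")
    X = metabolome.values
    folds = min(5, len(y))

    def run(yv: np.ndarray) -> tuple[np.ndarray, float]:
        kf = KFold(folds, shuffle=True, random_state=config.seed)
        oof = np.empty_like(yv)
        for tr, te in kf.split(X):
            reg = RandomForestRegressor(
                n_estimators=config.rf_trees, random_state=config.seed, n_jobs=1
            )
            reg.fit(X[tr], yv[tr])
            oof[te] = reg.predict(X[te])
        rho, _ = spearman_test(oof, yv)
        return oof, rho

    oof, rho = run(y)
    rng = np.random.default_rng(child_seed(config.seed, 3))
    null = np.array([run(rng.permutation(y))[1] for _ in range(config.n_permutations)])
    return SurrogateResult(oof, rho, permutation_pvalue(rho, null))
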