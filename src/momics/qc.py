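"""Structural quality control of the multiomics feature tables.

Covers four questions asked of the data before any outcome modelling:
how internally redundant each assay is (principal components to 90%
variance), whether cohort membership is visible in the data (unsupervised
PCA vs supervised LDA vs cross-validated random-forest prediction of the
cohort label), whether sample storage time leaks into the measurements, and
a global t-SNE layout of the feature correlation network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.manifold import TSNE
from sklearn.model_selection import KFold, StratifiedKFold

from ._utils import child_seed, logger, permutation_pvalue, spearman_test, standardize
from .datatypes import AnalysisConfig, FeatureMatrix, MultiOmicsDataset, ValidationError


def _drop_zero_variance(X: np.ndarray, label: str = "") -> np.ndarray:
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d zero-variance feature(s) %s", dropped, label)
    return X[:, keep]


def modality_complexity(matrix: FeatureMatrix, variance_fraction: float = 0.9) -> int:
    """Smallest number of principal components reaching the variance fraction.

    Features are standardized internally; the spectrum comes from the SVD of
    the standardized subject x feature table (equivalently the eigenvalues of
    the subject-level covariance).
    """
    if matrix.n_subjects < 2:
        raise ValidationError("modality_complexity needs at least 2 subjects")
    if not 0 < variance_fraction <= 1:
        raise ValidationError("variance_fraction must be in (0, 1]")
    X = _drop_zero_variance(matrix.values, f"in {matrix.modality}")
    if X.shape[1] == 0:
        raise ValidationError("all features have zero variance")
    Z = standardize(X)
    s = np.linalg.svd(Z - Z.mean(axis=0), compute_uv=False)
    eig = s**2
    ratios = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(ratios, variance_fraction - 1e-12) + 1)


def _signed_pca(Z: np.ndarray, n_components: int = 2):
    """PCA scores with the sign convention: largest-|loading| entry positive."""
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
            Vt[k] *= -1.0
    return scores, Vt[:n_components]


def pca_embedding(
    dataset: MultiOmicsDataset, modalities: list[str] | None = None
) -> pd.DataFrame:
    """First two principal-component scores of the standardized concatenation."""
    if dataset.n_subjects < 3:
        raise ValidationError("pca_embedding needs at least 3 subjects")
    mods = modalities or dataset.modalities
    blocks = [
        standardize(_drop_zero_variance(dataset.matrices[m].values, f"in {m}"))
        for m in mods
    ]
    Z = np.hstack(blocks)
    scores, _ = _signed_pca(Z, n_components=2)
    return pd.DataFrame(
        scores, columns=["pc1", "pc2"],
        index=pd.Index(dataset.subjects.subject_ids, name="subject_id"),
    )


def lda_embedding(
    dataset: MultiOmicsDataset,
    labels: np.ndarray | None = None,
    shrinkage: float = 0.1,
) -> pd.DataFrame:
    """First two linear discriminants separating the given classes (cohorts).

    The within-class scatter is shrunk toward the identity (features greatly
    outnumber subjects, so the raw scatter is singular).
    """
    y = np.asarray(labels if labels is not None else dataset.subjects.cohort)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 subjects for LDA")
    if len(classes) < 3:
        raise ValidationError("need >=3 classes for a 2-axis LDA embedding")
    Z, _, _ = dataset.concatenated()
    Z = standardize(_drop_zero_variance(Z, "before LDA"))
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage, n_components=2)
    coords = lda.fit_transform(Z, y)
    return pd.DataFrame(
        coords, columns=["ld1", "ld2"],
        index=pd.Index(dataset.subjects.subject_ids, name="subject_id"),
    )


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, trees: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def cohort_predictability(
    matrix: FeatureMatrix, labels: np.ndarray, config: AnalysisConfig
) -> tuple[float, float]:
    """Cross-validated random-forest accuracy at predicting the cohort label.

    Returns (accuracy, permutation p) where the null distribution refits the
    whole cross-validation on label permutations and p uses the add-one rule
    p = (1 + #{perm >= obs}) / (1 + B).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 cohorts")
    folds = 5
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        logger.warning("reducing CV folds to %d (smallest cohort)", folds)
    X = _drop_zero_variance(matrix.values, f"in {matrix.modality}")
    acc = _cv_accuracy(X, y, folds, config.rf_trees, config.seed)
    rng = np.random.default_rng(child_seed(config.seed, 1))
    null = np.array(
        [
            _cv_accuracy(X, rng.permutation(y), folds, config.rf_trees, config.seed)
            for _ in range(config.n_permutations)
        ]
    )
    return acc, permutation_pvalue(acc, null)


def _cv_regression_spearman(
    X: np.ndarray, y: np.ndarray, folds: int, trees: int, seed: int
) -> tuple[np.ndarray, float]:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty_like(y, dtype=float)
    for tr, te in kf.split(X):
        reg = RandomForestRegressor(n_estimators=trees, random_state=seed, n_jobs=1)
        reg.fit(X[tr], y[tr])
        oof[te] = reg.predict(X[te])
    rho, _ = spearman_test(oof, y)
    return oof, rho


def storage_time_predictability(
    matrix: FeatureMatrix, storage_days: np.ndarray, config: AnalysisConfig
) -> tuple[float, float]:
    """Spearman correlation of out-of-fold RF predictions with storage time.

    A significant correlation flags a storage/degradation confound in the
    modality. The permutation null refits the cross-validation on shuffled
    storage times.
    """
    y = np.asarray(storage_days, dtype=float)
    if len(np.unique(y)) < 3:
        raise ValidationError("storage_days needs at least 3 distinct values")
    X = _drop_zero_variance(matrix.values, f"in {matrix.modality}")
    folds = min(5, len(y))
    _, rho = _cv_regression_spearman(X, y, folds, config.rf_trees, config.seed)
    rng = np.random.default_rng(child_seed(config.seed, 2))
    null = np.array(
        [
            _cv_regression_spearman(
                X, rng.permutation(y), folds, config.rf_trees, config.seed
            )[1]
            for _ in range(config.n_permutations)
        ]
    )
    return rho, permutation_pvalue(rho, null)


def correlation_network_embedding(
    dataset: MultiOmicsDataset, config: AnalysisConfig
) -> pd.DataFrame:
    """t-SNE layout of all features from their Spearman correlation network.

    Features are placed in 2-D from the distance 1 - |rho| so internally
    correlated blocks (within or across modalities) land together. The
    layout is deterministic given the seed.
    """
    if dataset.n_subjects < 4:
        raise ValidationError("need at least 4 subjects for a correlation network")
    X, fids, tags = dataset.concatenated()
    keep = X.std(axis=0) > 0
    X, fids, tags = X[:, keep], list(np.array(fids)[keep]), list(np.array(tags)[keep])
    if X.shape[1] < 10:
        raise ValidationError("need at least 10 variable features")
    ranks = stats.rankdata(X, axis=0)
    corr = np.corrcoef(ranks, rowvar=False)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    perplexity = min(config.tsne_perplexity, (dist.shape[0] - 1) / 3)
    tsne = TSNE(
        n_components=2, metric="precomputed", init="random",
        random_state=config.seed, perplexity=perplexity, max_iter=1000,
    )
    coords = tsne.fit_transform(dist)
    return pd.DataFrame(
        {"feature_id": fids, "modality": tags, "x": coords[:, 0], "y": coords[:, 1]}
    )
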