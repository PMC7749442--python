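"""Shared numerical helpers: seeding, standardization, correlation tests."""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
from scipy import stats

logger = logging.getLogger("momics")

MODALITIES = ("transcriptomics", "proteomics", "metabolomics")


def child_seed(seed: int, index: int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % (2**31 - 1))


def zscore_fit(X: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sds; zero sds replaced by 1 so constant columns map to 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof) if X.shape[0] > ddof else np.ones(X.shape[1])
    sd = np.where(sd <= 0, 1.0, sd)
    return mu, sd


def zscore_apply(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mu) / sd


def standardize(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu, sd = zscore_fit(X, ddof=ddof)
    return zscore_apply(X, mu, sd)


def spearman_test(x: np.ndarray, y: np.ndarray, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Uses the large-sample t approximation; below ``exact_below`` observations
    the p-value comes from exact enumeration of all pairings. Degenerate
    (constant) inputs return (0.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rho = float(stats.spearmanr(x, y).statistic)
    if not np.isfinite(rho):
        return 0.0, 1.0
    if n < exact_below:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(_rank_corr(rx, ry))
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= obs - 1e-12:
                count += 1
        return rho, count / total
    # t approximation
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return rho, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0:
        return 0.0
    return float(rxc @ ryc) / denom


def spearman_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho and t-approximation p for each column of X vs y."""
    n = X.shape[0]
    RX = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    RXc = RX - RX.mean(axis=0)
    ryc = ry - ry.mean()
    num = RXc.T @ ryc
    denom = np.sqrt((RXc**2).sum(axis=0) * float(ryc @ ryc))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, num / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, np.minimum(p, 1.0)


def permutation_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + B)."""
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))
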