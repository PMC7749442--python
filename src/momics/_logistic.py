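"""Minimal L2-regularized logistic regression.

The LOOCV pipeline fits tens of thousands of small (n < 100, p <= 50)
logistic models; this direct L-BFGS implementation with an analytic gradient
keeps that affordable. The objective matches the usual parameterization:
mean log-loss + ||w||^2 / (2 C n), intercept unpenalized.
"""

from __future__ import annotations

import numpy as np
from scipy import special


class RidgeLogistic:
    """Binary logistic regression with an L2 penalty on the weights."""

    def __init__(self, C: float = 1.0) -> None:
        self.C = float(C)
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(
        self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> "RidgeLogistic":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        lam = 1.0 / (self.C * n)
        sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        sw = sw / sw.sum()
        Xa = np.hstack([X, np.ones((n, 1))])
        pen = np.full(p + 1, lam)
        pen[p] = 0.0  # intercept unpenalized
        theta = np.zeros(p + 1)

        def loss(th: np.ndarray) -> float:
            z = Xa @ th
            return float(
                sw @ (np.logaddexp(0.0, z) - y * z) + 0.5 * lam * (th[:p] @ th[:p])
            )

        cur = loss(theta)
        for _ in range(30):  # Newton with backtracking; ridge keeps H positive definite
            z = Xa @ theta
            s = special.expit(z)
            grad = Xa.T @ (sw * (s - y)) + pen * theta
            if np.max(np.abs(grad)) < 1e-8:
                break
            w_diag = np.clip(s * (1.0 - s), 1e-6, None) * sw
            H = (Xa * w_diag[:, None]).T @ Xa
            H[np.diag_indices_from(H)] += pen
            step = np.linalg.solve(H, grad)
            t = 1.0
            for _ in range(20):
                cand = theta - t * step
                new = loss(cand)
                if new <= cur + 1e-12:
                    theta, cur = cand, new
                    break
                t *= 0.5
            else:
                break
        self.coef_ = theta[:p]
        self.intercept_ = float(theta[p])
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class."""
        return special.expit(np.asarray(X, dtype=float) @ self.coef_ + self.intercept_)


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights giving both classes equal total weight.

    Keeps leave-one-out estimates free of the base-rate artifact: removing a
    case would otherwise tilt every training fit slightly toward controls
    (and vice versa), anti-correlating held-out scores with their labels.
    """
    y = np.asarray(y, dtype=bool)
    w = np.empty(len(y))
    w[y] = 0.5 / max(int(y.sum()), 1)
    w[~y] = 0.5 / max(int((~y).sum()), 1)
    return w * len(y)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Index folds with class proportions preserved."""
    y = np.asarray(y, dtype=bool)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.where(y == cls)[0]
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def fit_logistic_cv(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: tuple[float, ...],
    folds: int,
    seed: int,
) -> RidgeLogistic:
    """Pick the penalty by stratified K-fold mean log-loss, then refit on all.

    Falls back to C = 1.0 without cross-validation when a class is too small
    to stratify.
    """
    y = np.asarray(y, dtype=bool)
    k = min(folds, int(min(y.sum(), (~y).sum())))
    if k < 2 or len(C_grid) == 1:
        C = C_grid[0] if len(C_grid) == 1 else 1.0
        return RidgeLogistic(C).fit(X, y, balanced_weights(y))
    rng = np.random.default_rng(seed)
    fold_idx = _stratified_folds(y, k, rng)
    losses = np.zeros(len(C_grid))
    eps = 1e-12
    for te in fold_idx:
        tr = np.setdiff1d(np.arange(len(y)), te)
        if y[tr].all() or not y[tr].any():
            continue
        for ci, C in enumerate(C_grid):
            model = RidgeLogistic(C).fit(X[tr], y[tr], balanced_weights(y[tr]))
            prob = np.clip(model.predict_proba1(X[te]), eps, 1 - eps)
            losses[ci] += -np.mean(
                y[te] * np.log(prob) + (~y[te]) * np.log(1 - prob)
            )
    best = C_grid[int(np.argmin(losses))]
    return RidgeLogistic(best).fit(X, y, balanced_weights(y))
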