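"""Three-step survival-feature selection.

1. Spearman redundancy filter: greedy scan in the deterministic feature-key
   order; a feature is dropped when |rho| with any already-retained feature
   exceeds the threshold (default 0.90).  Constant columns are dropped first.
2. L1-penalized logistic regression (LASSO) over a descending lambda grid,
   tuned by repeated stratified 4-fold cross-validation (default 100
   repeats) minimizing mean held-out binomial deviance.
3. Signature assembly under the events-per-variable cap: fewer than
   ``max_features`` (default 11, the 10:1 rule for ~114 patients) non-zero
   terms; if the deviance-optimal lambda keeps too many features, lambda is
   increased along the path to the first point satisfying the cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

__all__ = ["SelectionConfig", "SelectionResult", "spearman_filter", "lasso_select"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    spearman_threshold: float = 0.90
    folds: int = 4
    repeats: int = 100
    max_features: int = 11  # exclusive cap: selected count must be < this
    n_lambdas: int = 30
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.spearman_threshold <= 1:
            raise ValueError("spearman_threshold must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_features < 1:
            raise ValueError("max_features cap must be >= 1")


@dataclass
class SelectionResult:
    intercept: float
    coefficients: dict[str, float]  # feature column -> coefficient, original scale
    lambda_path: np.ndarray
    cv_deviance: np.ndarray  # mean held-out deviance per lambda
    cv_deviance_sd: np.ndarray
    selected_lambda: float
    drop_log: dict[str, str] = field(default_factory=dict)


def spearman_filter(matrix: pd.DataFrame, threshold: float = 0.90
                    ) -> tuple[list[str], dict[str, str]]:
    """Greedy redundancy filter on a patients x features matrix.

    Columns are scanned in their (deterministic layout) order; a column is
    dropped when |Spearman rho| with any retained column exceeds the
    threshold.  Returns (retained column names, drop -> culprit log).
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 patients")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    cols = list(matrix.columns)
    drop_log: dict[str, str] = {}
    constant = X.std(axis=0) == 0
    for idx in np.flatnonzero(constant):
        drop_log[cols[idx]] = "constant column (Spearman rho undefined)"
    live = np.flatnonzero(~constant)
    ranks = np.empty_like(X)
    ranks[:, live] = rankdata(X[:, live], axis=0)
    ranks[:, live] -= ranks[:, live].mean(axis=0)
    norms = np.linalg.norm(ranks[:, live], axis=0)
    ranks[:, live] /= norms
    # |rho| = |corr of ranks|; full matrix in one product
    rho = np.abs(ranks[:, live].T @ ranks[:, live])
    retained_local: list[int] = []
    for j in range(len(live)):
        if retained_local and rho[j, retained_local].max() > threshold:
            culprit = retained_local[int(np.argmax(rho[j, retained_local]))]
            drop_log[cols[live[j]]] = cols[live[culprit]]
        else:
            retained_local.append(j)
    retained = [cols[live[j]] for j in retained_local]
    return retained, drop_log


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, config: SelectionConfig) -> np.ndarray:
    n = len(y)
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    # liblinear objective: C * sum(logloss) + |beta|_1  =>  lam = 1 / (C * n)
    n = len(y)
    # intercept_scaling keeps liblinear's intercept penalty negligible
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear", max_iter=2000,
        tol=1e-7, intercept_scaling=1000.0, random_state=0,
    )
    clf.fit(Xs, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # mean binomial deviance (2 x mean negative log-likelihood), natural log
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    return float(-2.0 * np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def lasso_select(X: pd.DataFrame, y: np.ndarray, config: SelectionConfig
                 ) -> SelectionResult:
    """Repeated-CV LASSO logistic selection with the feature-count cap.

    Columns are standardized internally; returned coefficients are mapped
    back to the original feature scale.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is degenerate (single class)")
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd

    lambdas = _lambda_grid(Xs, y, config)
    rng = np.random.default_rng(config.seed)
    n = len(y)
    dev = np.zeros((config.repeats * config.folds, len(lambdas)))
    row = 0
    for _ in range(config.repeats):
        folds = _stratified_folds(y, config.folds, rng)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            for k, lam in enumerate(lambdas):
                try:
                    b0, beta = _fit_l1(Xs[train_idx], y[train_idx], lam)
                except Exception as exc:  # non-convergence at this lambda
                    log.warning("lambda %.3g skipped in CV fold: %s", lam, exc)
                    dev[row, k] = np.nan
                    continue
                dev[row, k] = _deviance(y[test_idx], b0 + Xs[test_idx] @ beta)
            row += 1
    mean_dev = np.nanmean(dev, axis=0)
    sd_dev = np.nanstd(dev, axis=0)

    best_k = int(np.nanargmin(mean_dev))
    # Enforce the cap: lambdas descend, so walk from the deviance optimum
    # toward larger lambda (smaller index) until < max_features non-zeros.
    chosen = None
    for k in range(best_k, -1, -1):
        b0, beta = _fit_l1(Xs, y, lambdas[k])
        if np.count_nonzero(beta) < config.max_features:
            chosen = (k, b0, beta)
            break
    if chosen is None:
        raise RuntimeError("no lambda on the path satisfies the feature cap")
    k, b0, beta = chosen

    beta_orig = beta / sd
    intercept = b0 - float((beta_orig * mu).sum())
    coefficients = {
        cols[j]: float(beta_orig[j]) for j in np.flatnonzero(beta != 0)
    }
    return SelectionResult(
        intercept=float(intercept),
        coefficients=coefficients,
        lambda_path=lambdas,
        cv_deviance=mean_dev,
        cv_deviance_sd=sd_dev,
        selected_lambda=float(lambdas[k]),
    )


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index folds preserving class balance, shuffled by ``rng``."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, v in enumerate(idx):
            folds[i % k].append(int(v))
    return [np.sort(np.array(f)) for f in folds]
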