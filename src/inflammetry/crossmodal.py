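"""First-level shrinkage-regularized regression of connectivity on loadings.

Whole-brain connectivity (subject x connection) is mapped onto the selected
inflammation component's loadings with a multiple linear regression whose
covariance is the analytic well-conditioned (Ledoit-Wolf) shrinkage estimate
``(1 - rho) * S + rho * mu * I``. The fit yields per-connection weights,
per-subject *brain scores* (the fitted linear combination of connections),
*structure coefficients* (Pearson correlation of each connection with the
brain scores), a repeated k-fold cross-validated R distribution, and
permutation-based model and per-connection significance.

The CV and permutation machinery exploits the fact that for a fixed
connectivity matrix the fitted prediction is linear in the response: per
(repeat, fold) a single prediction operator is formed once and reused for
every permuted response, which makes 1,000 repeats x thousands of label
shuffles tractable on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """Cross-validation and shrinkage settings.

    ``shrinkage`` is ``"analytic"`` (Ledoit-Wolf optimal intensity) or a
    fixed value in [0, 1].
    """

    k_folds: int = 5
    n_repeats: int = 1000
    seed: int = 0
    shrinkage: str | float = "analytic"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not isinstance(self.shrinkage, str):
            if not 0.0 <= float(self.shrinkage) <= 1.0:
                raise ValueError("fixed shrinkage must lie in [0, 1]")
        elif self.shrinkage != "analytic":
            raise ValueError("shrinkage must be 'analytic' or a value in [0, 1]")


@dataclass
class CrossModalResult:
    """Outputs of the first-level model."""

    coefficients: np.ndarray
    structure_coefficients: np.ndarray
    brain_scores: np.ndarray
    insample_r: float
    shrinkage: float
    cv_r_distribution: np.ndarray | None = None
    cv_r_median: float | None = None
    model_p: float | None = None
    connection_p: np.ndarray | None = None
    connection_p_fdr: np.ndarray | None = None
    significant_connections: np.ndarray | None = None
    kept_columns: np.ndarray = field(default=None)  # type: ignore[assignment]


def shrinkage_covariance(
    X: np.ndarray, shrinkage: str | float = "analytic"
) -> tuple[np.ndarray, float]:
    """Well-conditioned covariance ``(1 - rho) S + rho mu I``.

    ``S`` is the maximum-likelihood sample covariance and ``mu`` the mean of
    its diagonal. With ``shrinkage="analytic"`` the optimal intensity is the
    Ledoit-Wolf estimate; a float fixes rho directly. The result is symmetric
    positive definite for rho > 0 and its condition number never exceeds that
    of S.
    """
    from sklearn.covariance import ledoit_wolf, shrunk_covariance

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be subject x connection with >= 2 subjects")
    if shrinkage == "analytic":
        cov, rho = ledoit_wolf(X, assume_centered=False)
        return cov, float(rho)
    rho = float(shrinkage)
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / X.shape[0]
    return shrunk_covariance(S, shrinkage=rho), rho


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_shrinkage_mlr(
    fc: np.ndarray,
    loadings: np.ndarray,
    config: CVConfig | None = None,
) -> CrossModalResult:
    """Full-sample shrinkage MLR of loadings on standardized connectivity.

    Weights solve ``Sigma_shrunk w = cov(X, y)`` on z-scored connections;
    brain scores are ``X_std @ w``; the structure coefficient of connection j
    is the Pearson correlation of ``X_j`` with the brain scores. Constant
    connection columns are dropped with a log message (``kept_columns``
    records the surviving indices).
    """
    config = config or CVConfig()
    X = np.asarray(fc, dtype=float)
    y = np.asarray(loadings, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("fc rows must match loadings length")
    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.info("dropping %d constant connection columns", (~keep).sum())
    X = X[:, keep]
    n = X.shape[0]

    Xs, _, _ = _standardize_train(X)
    Sigma, rho = shrinkage_covariance(Xs, config.shrinkage)
    c = Xs.T @ (y - y.mean()) / n
    w = np.linalg.solve(Sigma, c)
    scores = Xs @ w
    structure = _columnwise_corr(Xs, scores)
    insample_r = _pearson(scores, y)
    return CrossModalResult(
        coefficients=w,
        structure_coefficients=structure,
        brain_scores=scores,
        insample_r=insample_r,
        shrinkage=rho,
        kept_columns=np.nonzero(keep)[0],
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def _columnwise_corr(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sc = s - s.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (sc @ sc))
    denom = np.where(denom == 0, 1.0, denom)
    return (Xc.T @ sc) / denom


# ---------------------------------------------------------------------------
# repeated k-fold cross-validation
# ---------------------------------------------------------------------------

def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    for f in folds:
        if len(f) < 2:
            raise ValueError(
                f"{k}-fold split of {n} subjects leaves a fold with < 2 subjects"
            )
    return folds


def _prediction_operator(
    X: np.ndarray, folds: list[np.ndarray], shrinkage: str | float
) -> np.ndarray:
    """(n, n) linear operator C with pooled out-of-fold predictions ``C @ y``.

    Training-fold standardization, shrinkage covariance and the training-mean
    intercept depend only on X, so the whole fit is linear in y.
    """
    n = X.shape[0]
    C = np.zeros((n, n))
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        Xtr, mu, sd = _standardize_train(X[train])
        Xte = (X[test] - mu) / sd
        Sigma, _ = shrinkage_covariance(Xtr, shrinkage)
        ntr = len(train)
        # pred = mean(ytr) + Xte Sigma^-1 Xtr' (ytr - mean(ytr)) / ntr
        B = Xte @ np.linalg.solve(Sigma, Xtr.T) / ntr
        ones_m = np.full((len(test), ntr), 1.0 / ntr)
        C[np.ix_(test, train)] = ones_m + B - (B.sum(axis=1, keepdims=True) / ntr)
    return C


def _corr_rows_with(Y_pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of Y_pred with the matching column of y."""
    P = Y_pred - Y_pred.mean(axis=0)
    Yc = y - y.mean(axis=0)
    denom = np.sqrt((P ** 2).sum(axis=0) * (Yc ** 2).sum(axis=0))
    denom = np.where(denom == 0, 1.0, denom)
    return (P * Yc).sum(axis=0) / denom


def cross_validate(
    fc: np.ndarray,
    loadings: np.ndarray,
    config: CVConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Repeated k-fold CV: distribution of pooled out-of-fold R and its median.

    Per repetition the folds are randomly re-partitioned; standardization and
    shrinkage are learned on the training subjects only; R is the Pearson
    correlation between the pooled out-of-fold predictions and the observed
    loadings. Deterministic given ``config.seed``.
    """
    config = config or CVConfig()
    X = np.asarray(fc, dtype=float)
    y = np.asarray(loadings, dtype=float).ravel()
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    rng = np.random.default_rng(config.seed)
    rs = np.empty(config.n_repeats)
    for rep in range(config.n_repeats):
        folds = _fold_assignments(len(y), config.k_folds, rng)
        C = _prediction_operator(X, folds, config.shrinkage)
        pred = C @ y
        rs[rep] = _pearson(pred, y)
    return rs, float(np.median(rs))


def significance_and_thresholding(
    fc: np.ndarray,
    loadings: np.ndarray,
    config: CVConfig | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CrossModalResult:
    """Fit, cross-validate and permutation-test the first-level model.

    The model-level p-value compares the observed median cross-validated R
    against its distribution under ``n_perm`` label shuffles, using identical
    fold partitions for the observed and permuted statistics (one-sided:
    larger R). Per-connection p-values come from the permutation distribution
    of the structure coefficients (two-sided) with Benjamini-Hochberg FDR
    control at ``alpha`` across connections.
    """
    from statsmodels.stats.multitest import multipletests

    config = config or CVConfig()
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    X = np.asarray(fc, dtype=float)
    y = np.asarray(loadings, dtype=float).ravel()
    n = len(y)

    result = fit_shrinkage_mlr(X, y, config)
    X = X[:, result.kept_columns]

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n, n_perm)), axis=0)
    Yp = y[perms]  # n x n_perm permuted responses

    # --- model-level: median pooled-R over identical partitions -----------
    cv_rng = np.random.default_rng(config.seed)
    R_obs = np.empty(config.n_repeats)
    R_null = np.empty((config.n_repeats, n_perm))
    for rep in range(config.n_repeats):
        folds = _fold_assignments(n, config.k_folds, cv_rng)
        C = _prediction_operator(X, folds, config.shrinkage)
        R_obs[rep] = _pearson(C @ y, y)
        R_null[rep] = _corr_rows_with(C @ Yp, Yp)
    cv_r_distribution = R_obs
    cv_r_median = float(np.median(R_obs))
    null_medians = np.median(R_null, axis=0)
    model_p = float((1.0 + np.sum(null_medians >= cv_r_median)) / (n_perm + 1.0))

    # --- per-connection: permutation distribution of structure coefficients
    Xs, _, _ = _standardize_train(X)
    Sigma, _ = shrinkage_covariance(Xs, config.shrinkage)
    M = Xs @ np.linalg.solve(Sigma, Xs.T) / n  # scores = M @ (y - mean)
    S_obs = result.structure_coefficients
    Yc = Yp - Yp.mean(axis=0)
    scores_null = M @ Yc
    Z = scores_null - scores_null.mean(axis=0)
    Zn = Z / np.maximum(np.sqrt((Z ** 2).sum(axis=0)), 1e-300)
    Xc = Xs - Xs.mean(axis=0)
    Xn = Xc / np.maximum(np.sqrt((Xc ** 2).sum(axis=0)), 1e-300)[None, :]
    S_null = Xn.T @ Zn  # connection x n_perm
    exceed = (np.abs(S_null) >= np.abs(S_obs)[:, None]).sum(axis=1)
    connection_p = (1.0 + exceed) / (n_perm + 1.0)
    rej, p_fdr, _, _ = multipletests(connection_p, alpha=alpha, method="fdr_bh")

    result.cv_r_distribution = cv_r_distribution
    result.cv_r_median = cv_r_median
    result.model_p = model_p
    result.connection_p = connection_p
    result.connection_p_fdr = p_fdr
    result.significant_connections = np.nonzero(rej)[0]
    return result


def residualize(data: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``data`` on covariates (+ intercept).

    Used when covariates of no interest are removed before the first-level
    fit (``covariate_placement`` in the pipeline configuration).
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    Y = data.reshape(len(data), -1)
    Z = np.column_stack([np.ones(len(Y)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    return resid.ravel() if squeeze else resid


def grubbs_screen(loadings: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Subjects flagged as loading outliers (to exclude before the fit)."""
    from .sbi import grubbs_test

    return np.array(grubbs_test(loadings, alpha=alpha), dtype=int)
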