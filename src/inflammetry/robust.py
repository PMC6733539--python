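"""Huber-type robust simple regression, vectorized over many response vectors.

The permutation tests on ICA loadings need a robust two-sample fit for every
one of thousands of label shuffles; this module implements the Huber IRLS
estimator (MAD scale, H1 covariance) in closed form for a single predictor so
all permutations run as array operations. The estimator mirrors the
statsmodels RLM(HuberT) conventions and is cross-checked against it in the
test suite.
"""

from __future__ import annotations

import numpy as np

HUBER_C = 1.345
MAD_C = 0.6744897501960817  # Phi^{-1}(3/4)


def _huber_psi(z: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    return np.clip(z, -c, c)


def huber_line_fit(
    x: np.ndarray,
    y: np.ndarray,
    c: float = HUBER_C,
    maxiter: int = 50,
    tol: float = 1e-9,
) -> dict:
    """Robust fit of ``y = b0 + b1 x`` by Huber IRLS, vectorized over columns.

    Parameters
    ----------
    x : (n,) predictor (e.g. a 0/1 group indicator).
    y : (n,) or (n, m) responses; each column is fitted independently.

    Returns a dict with per-column arrays: ``slope``, ``intercept``, ``t``
    (slope / H1 robust SE), ``scale`` and ``weights``. Initialization is the
    least-squares fit and the MAD scale (centered at zero) is re-estimated at
    every iteration, as in statsmodels RLM.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, m)
    n, m = Y.shape
    if len(x) != n:
        raise ValueError("x and y lengths differ")
    if n < 3:
        raise ValueError("need at least 3 observations")

    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("constant predictor")

    # OLS initialization
    b1 = (xc @ Y) / sxx                        # (m,)
    b0 = Y.mean(axis=0) - b1 * x.mean()
    prev_dev = np.full(m, np.inf)

    for _ in range(maxiter):
        resid = Y - b0 - np.outer(x, b1)
        scale = np.median(np.abs(resid), axis=0) / MAD_C
        scale = np.where(scale <= 0, 1e-12, scale)
        z = resid / scale
        w = np.where(np.abs(z) <= c, 1.0, c / np.maximum(np.abs(z), 1e-300))
        # weighted least squares, closed form for [1, x]
        s0 = w.sum(axis=0)
        s1 = x @ w
        s2 = (x * x) @ w
        sy = (w * Y).sum(axis=0)
        sxy = x @ (w * Y)
        det = s0 * s2 - s1 * s1
        b1 = (s0 * sxy - s1 * sy) / det
        b0 = (sy - b1 * s1) / s0
        # Huber deviance for convergence (un-normalized M-objective)
        az = np.abs(z)
        rho = np.where(az <= c, 0.5 * z * z, c * az - 0.5 * c * c)
        dev = rho.sum(axis=0)
        if np.all(np.abs(dev - prev_dev) <= tol * np.maximum(1.0, np.abs(dev))):
            break
        prev_dev = dev

    resid = Y - b0 - np.outer(x, b1)
    scale = np.median(np.abs(resid), axis=0) / MAD_C
    degenerate = scale <= 0
    scale = np.where(degenerate, 1e-12, scale)
    z = resid / scale
    psi = _huber_psi(z, c)
    psi_deriv = (np.abs(z) <= c).astype(float)
    mpd = psi_deriv.mean(axis=0)
    var_pd = psi_deriv.var(axis=0)
    p = 2  # intercept + slope
    k = 1.0 + (p / n) * var_pd / np.maximum(mpd, 1e-12) ** 2
    df_resid = n - p
    s_psi2 = (psi ** 2).sum(axis=0) * scale ** 2 / df_resid
    # (X'X)^{-1}[1,1] for X = [1, x]
    xtx_inv_11 = 1.0 / sxx
    var_slope = k ** 2 * s_psi2 / np.maximum(mpd, 1e-12) ** 2 * xtx_inv_11
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b1 / np.sqrt(var_slope)
    t = np.where(degenerate | ~np.isfinite(t), 0.0, t)

    out = {
        "slope": b1, "intercept": b0, "t": t, "scale": scale, "weights": w,
    }
    if np.ndim(y) == 1:
        out = {
            "slope": float(b1[0]), "intercept": float(b0[0]), "t": float(t[0]),
            "scale": float(scale[0]), "weights": w[:, 0],
        }
    return out


def permutation_group_test(
    values: np.ndarray,
    group_indicator: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sample permutation test of a robust group effect.

    Fits ``values ~ group`` by Huber IRLS and compares the robust t for the
    group coefficient against its distribution under ``n_perm`` random label
    shuffles (two-sided). Returns ``(t_observed, p_perm)`` with the add-one
    permutation p-value.
    """
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    g = np.asarray(group_indicator, dtype=float)
    if np.ptp(values) == 0:
        return 0.0, 1.0
    obs = huber_line_fit(g, values)
    t_obs = float(obs["t"])
    # permute the responses (equivalent to shuffling labels)
    idx = np.argsort(rng.random((len(values), n_perm)), axis=0)
    Y = values[idx]
    t_null = huber_line_fit(g, Y)["t"]
    p = (1.0 + np.sum(np.abs(t_null) >= abs(t_obs))) / (n_perm + 1.0)
    return t_obs, float(p)
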