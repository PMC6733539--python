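"""Node time-series cleaning and pairwise functional connectivity.

Cleaning follows the simultaneous-GLM convention: one least-squares
regression per node whose design stacks an intercept, a linear trend, a
24-parameter motion expansion (6 realignment parameters, their first
differences, and the squares of those 12), white-matter and CSF mean signals
with their differences and squares, and a discrete cosine transform set whose
frequencies fall *outside* the 0.0078-0.1 Hz passband — so nuisance
regression and bandpass filtering happen in a single projection and the
residuals are orthogonal to every retained regressor.

Connectivity is the Pearson correlation between cleaned node series, stored
as the upper triangle in fixed lexicographic pair order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConnectivityVector, GridMeta, NodeTimeSeries, connection_pairs

logger = logging.getLogger(__name__)

DEFAULT_PASSBAND = (0.0078, 0.1)
SPHERE_RADIUS_MM = 8.0
TISSUE_PROB_THRESHOLD = 0.7
ROTATION_RADIUS_MM = 50.0


@dataclass
class NuisanceDesign:
    """Time x regressor nuisance matrix with per-column labels."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("labels must match regressor columns")
        if self.labels.count("intercept") != 1:
            raise ValueError("design must contain exactly one intercept")

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]


def extract_node_series(
    voxel_series: np.ndarray,
    node_center_mm: np.ndarray,
    grid: GridMeta,
    radius_mm: float = SPHERE_RADIUS_MM,
    node_name: str = "node",
) -> np.ndarray:
    """First principal component of the voxels in a sphere around a node.

    ``voxel_series`` is voxel x time over the full grid (Fortran voxel
    order). The component is sign-oriented to correlate positively with the
    sphere's mean signal and standardized to unit variance.
    """
    coords = grid.voxel_coordinates_mm()
    in_sphere = (
        np.sum((coords - np.asarray(node_center_mm)) ** 2, axis=1)
        <= radius_mm ** 2
    )
    if not in_sphere.any():
        raise ValueError(
            f"no voxels within {radius_mm} mm of node {node_name!r}"
        )
    M = np.asarray(voxel_series, dtype=float)[in_sphere]
    M = M - M.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    pc = vt[0]
    mean_sig = M.mean(axis=0)
    if mean_sig.std() > 0 and np.corrcoef(pc, mean_sig)[0, 1] < 0:
        pc = -pc
    return standardize(pc)


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance (sample SD, ddof=1) version of a series."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return (x - x.mean()) / sd


def dct_basis(n_timepoints: int, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """DCT-II basis columns (k = 1..T-1) and their frequencies in Hz.

    Column k has frequency ``k / (2 * T * TR)``; k=0 (the constant) is left
    to the explicit intercept.
    """
    t = np.arange(n_timepoints)
    k = np.arange(1, n_timepoints)
    basis = np.cos(np.pi * np.outer(2 * t + 1, k) / (2.0 * n_timepoints))
    freqs = k / (2.0 * n_timepoints * tr)
    return basis, freqs


def build_nuisance_design(
    motion_params: np.ndarray,
    wm_signal: np.ndarray,
    csf_signal: np.ndarray,
    tr: float,
    passband: tuple[float, float] = DEFAULT_PASSBAND,
) -> NuisanceDesign:
    """Assemble the simultaneous nuisance + bandpass design matrix.

    DCT columns whose frequencies lie below the low cut or above the high cut
    (up to Nyquist) act as the bandpass; constant nuisance columns (e.g. zero
    motion input) are dropped with a log message.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion_params must be time x 6")
    T = motion.shape[0]
    wm = np.asarray(wm_signal, dtype=float).ravel()
    csf = np.asarray(csf_signal, dtype=float).ravel()
    if len(wm) != T or len(csf) != T:
        raise ValueError("time lengths of motion and tissue signals disagree")
    low, high = passband
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"passband {passband} must satisfy 0 < low < high < Nyquist "
            f"({nyquist:.4f} Hz)"
        )

    cols: list[np.ndarray] = [np.ones(T)]
    labels: list[str] = ["intercept"]

    cols.append(np.linspace(-0.5, 0.5, T))
    labels.append("trend")

    d_motion = np.diff(motion, axis=0, prepend=motion[:1])
    for j in range(6):
        cols.append(motion[:, j]); labels.append(f"motion{j + 1}")
    for j in range(6):
        cols.append(d_motion[:, j]); labels.append(f"motion_derivative{j + 1}")
    for j in range(6):
        cols.append(motion[:, j] ** 2); labels.append(f"motion_quadratic{j + 1}")
    for j in range(6):
        cols.append(d_motion[:, j] ** 2)
        labels.append(f"motion_derivative_quadratic{j + 1}")

    d_wm = np.diff(wm, prepend=wm[:1])
    d_csf = np.diff(csf, prepend=csf[:1])
    tissue = [
        (wm, "wm"), (csf, "csf"),
        (d_wm, "tissue_derivative_wm"), (d_csf, "tissue_derivative_csf"),
        (wm ** 2, "tissue_quadratic_wm"), (csf ** 2, "tissue_quadratic_csf"),
        (d_wm ** 2, "tissue_quadratic_dwm"), (d_csf ** 2, "tissue_quadratic_dcsf"),
    ]
    for sig, lab in tissue:
        cols.append(sig); labels.append(lab)

    basis, freqs = dct_basis(T, tr)
    outside = (freqs < low) | (freqs > high)
    for idx in np.nonzero(outside)[0]:
        cols.append(basis[:, idx])
        labels.append(f"dct{idx + 1}")

    X = np.column_stack(cols)
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(1, X.shape[1]):  # never drop the intercept
        if np.ptp(X[:, j]) == 0:
            keep[j] = False
    dropped = [lab for lab, k in zip(labels, keep) if not k]
    if dropped:
        logger.info("dropping constant nuisance columns: %s", dropped)
    return NuisanceDesign(
        regressors=X[:, keep],
        labels=[lab for lab, k in zip(labels, keep) if k],
    )


def tissue_mean_signal(
    voxel_series: np.ndarray,
    tissue_prob: np.ndarray,
    threshold: float = TISSUE_PROB_THRESHOLD,
) -> np.ndarray:
    """Mean signal over voxels with tissue probability above ``threshold``."""
    sel = np.asarray(tissue_prob, dtype=float) > threshold
    if not sel.any():
        raise ValueError(f"no voxels with tissue probability > {threshold}")
    return np.asarray(voxel_series, dtype=float)[sel].mean(axis=0)


def _independent_columns(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    """Rank-reduce a design via pivoted QR, logging dropped labels."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [labels[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
    if dropped:
        logger.info("rank-deficient design; dropping columns: %s", dropped)
    return X[:, keep], [labels[j] for j in keep]


def clean_timeseries(ts: NodeTimeSeries, design: NuisanceDesign) -> NodeTimeSeries:
    """Residualize every node series against the full nuisance design.

    A single least-squares fit per node; residuals are orthogonal to every
    retained design column. Rank-deficient designs are reduced to an
    independent column subset first (dropped labels are logged).
    """
    if design.n_timepoints != ts.n_timepoints:
        raise ValueError("design rows must match the time-series length")
    X, _ = _independent_columns(design.regressors, design.labels)
    Y = ts.values.T  # time x node
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return NodeTimeSeries(values=resid.T, tr=ts.tr, node_names=list(ts.node_names))


def compute_fd_rms(motion_params: np.ndarray) -> float:
    """Root-mean-square volume-to-volume displacement, in mm.

    Translations are in mm and rotations in radians; rotations are converted
    to arc length on a 50 mm sphere. Each volume pair contributes the
    Euclidean norm of the six converted parameter increments; the RMS over
    pairs is returned.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion_params must be time x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    d = np.diff(motion, axis=0)
    d[:, 3:] *= ROTATION_RADIUS_MM
    disp = np.sqrt((d ** 2).sum(axis=1))
    return float(np.sqrt((disp ** 2).mean()))


def connectivity_vector(ts: NodeTimeSeries) -> ConnectivityVector:
    """Upper-triangle Pearson correlations in fixed lexicographic pair order."""
    sds = ts.values.std(axis=1)
    for name, sd in zip(ts.node_names, sds):
        if sd == 0:
            raise ValueError(f"node {name!r} has a constant series")
    R = np.corrcoef(ts.values)
    iu = np.triu_indices(ts.n_nodes, k=1)
    return ConnectivityVector(
        r=R[iu], pair_index=connection_pairs(list(ts.node_names))
    )


def group_connectivity_stats(
    vectors: list[ConnectivityVector] | np.ndarray,
    group_labels: np.ndarray,
    patient_label: str | int | None = None,
    pair_index: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-connection mean and two-sample group statistics.

    Correlations are Fisher z-transformed before the two-sample t-test;
    unadjusted and Benjamini-Hochberg FDR-adjusted p-values are reported.
    """
    from statsmodels.stats.multitest import multipletests

    if isinstance(vectors, np.ndarray):
        R = np.asarray(vectors, dtype=float)
        pairs = pair_index or [("?", "?")] * R.shape[1]
    else:
        pairs = vectors[0].pair_index
        for v in vectors:
            if v.pair_index != pairs:
                raise ValueError("connectivity vectors have mismatched pairs")
        R = np.vstack([v.r for v in vectors])
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(uniq)}")
    if patient_label is None:
        patient_label = uniq[0]
    in_a = labels == patient_label
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")

    Z = np.arctanh(np.clip(R, -0.999999, 0.999999))
    t, p = stats.ttest_ind(Z[in_a], Z[~in_a], axis=0)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    _, p_fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "connection": [f"{a}—{b}" for a, b in pairs],
        "mean_r": R.mean(axis=0),
        "t": t,
        "p": p,
        "p_fdr": p_fdr,
    })
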