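"""Source-based inflammetry: spatial ICA of subject PET binding maps.

The subject-by-voxel matrix of binding-potential values (restricted to a
group gray-matter mask) is decomposed into spatially independent source maps
and a mixing matrix of per-subject loadings. The model order is chosen by an
MDL criterion on the eigenspectrum of the subject-level covariance; the
group-differentiating, atrophy-associated component is then selected by (1) a
robust permutation test of patient-vs-control loading differences and (2) a
negative robust association between loadings and total gray matter within
the patient stratum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PKMapStack, SourceDecomposition
from .robust import huber_line_fit, permutation_group_test

logger = logging.getLogger(__name__)

MASK_THRESHOLD = 0.3
FALLBACK_SEED_OFFSETS = (101, 211, 307)


class NoSelectionError(RuntimeError):
    """No component met both selection criteria."""


class AmbiguousSelectionError(RuntimeError):
    """More than one component met both selection criteria."""

    def __init__(self, candidates: list[int]):
        self.candidates = candidates
        super().__init__(
            f"multiple components meet the selection criteria: {candidates}"
        )


def build_group_mask(
    gm_prob_maps: np.ndarray, threshold: float = MASK_THRESHOLD
) -> np.ndarray:
    """Voxels whose group-mean gray-matter probability exceeds ``threshold``.

    The inequality is strict; an empty mask raises.
    """
    probs = np.asarray(gm_prob_maps, dtype=float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("gray-matter probabilities must lie in [0, 1]")
    mask = probs.mean(axis=0) > threshold
    if not mask.any():
        raise ValueError(
            f"group gray-matter mask is empty at threshold {threshold}"
        )
    return mask


def apply_mask(stack: PKMapStack, mask: np.ndarray) -> PKMapStack:
    """Restrict a full-grid stack to ``mask`` (given over the full grid)."""
    if mask.shape[0] != stack.grid.n_voxels:
        raise ValueError("mask length must equal the full voxel count")
    if not stack.mask.all():
        raise ValueError("stack is already masked")
    return PKMapStack(
        maps=stack.maps[:, mask],
        mask=mask,
        grid=stack.grid,
        subject_ids=list(stack.subject_ids),
    )


def estimate_n_components(stack: PKMapStack) -> int:
    """MDL model order from the eigenspectrum of the subject covariance.

    Treats the masked voxels as samples of an n_subjects-dimensional vector;
    the minimum-description-length cost of retaining k components is
    evaluated for k = 1..n_subjects-1 and the argmin returned. A degenerate
    (flat) spectrum returns 1 with a warning.
    """
    X = stack.maps
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / m
    eig = np.linalg.eigvalsh(C)[::-1]
    # relative floor: numerically-zero tail eigenvalues are treated as equal
    eig = np.maximum(eig, max(eig.max(), np.finfo(float).tiny) * 1e-12)
    if np.allclose(eig, eig[0], rtol=1e-12):
        logger.warning("degenerate eigenspectrum; returning 1 component")
        return 1
    ks = np.arange(1, n)
    mdl = np.empty(len(ks))
    log_eig = np.log(eig)
    for i, k in enumerate(ks):
        rest = eig[k:]
        arith = rest.mean()
        geom = np.exp(log_eig[k:].mean())
        mdl[i] = -m * (n - k) * (np.log(geom) - np.log(arith)) \
            + 0.5 * k * (2 * n - k + 1) * np.log(m)
    return int(ks[np.argmin(mdl)])


def decompose(
    stack: PKMapStack, n_components: int, seed: int = 0
) -> SourceDecomposition:
    """Spatial ICA of the subject x voxel matrix.

    PCA whitening to ``n_components`` followed by a fixed-point ICA rotation
    (deflation). Sources are standardized to unit variance over masked voxels
    and sign-fixed to positive skewness (so higher loading means higher
    binding in the source's hot spots); scale and sign are absorbed into the
    loadings, leaving the reconstruction ``loadings @ sources + mean``
    unchanged. Components are ordered by explained variance. Deterministic
    given ``seed``; documented fallback seeds are tried on non-convergence.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    X = stack.maps
    n, m = X.shape
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < n_subjects")

    last_err: Exception | None = None
    for attempt, offset in enumerate((0,) + FALLBACK_SEED_OFFSETS):
        ica = FastICA(
            n_components=n_components,
            algorithm="deflation",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-6,
            random_state=seed + offset,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                S = ica.fit_transform(X.T).T  # component x voxel
            except Exception as err:  # pragma: no cover - numerical failure
                last_err = err
                continue
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning(
                "FastICA did not converge with seed %d; retrying", seed + offset
            )
            last_err = RuntimeError("FastICA did not converge")
            continue
        break
    else:
        raise RuntimeError(
            f"FastICA failed to converge with seed {seed} and fallbacks"
        ) from last_err

    A = ica.mixing_  # subject x component
    mean = ica.mean_  # per-subject mean over voxels

    # unit-variance sources, positive skewness; fold scale/sign into loadings
    sd = S.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    S = S / sd[:, None]
    A = A * sd[None, :]
    sign = np.where(stats.skew(S, axis=1) < 0, -1.0, 1.0)
    S = S * sign[:, None]
    A = A * sign[None, :]

    order = np.argsort(-(A ** 2).sum(axis=0))
    return SourceDecomposition(
        sources=S[order],
        loadings=A[:, order],
        n_components=n_components,
        mean=mean,
    )


def reconstruction(decomp: SourceDecomposition) -> np.ndarray:
    """Subject x voxel reconstruction ``loadings @ sources + mean``."""
    return decomp.loadings @ decomp.sources + decomp.mean[:, None]


def match_sources(
    estimated: np.ndarray, planted: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of estimated to planted sources on |spatial r|.

    Returns (assignment, matched |r| values): ``assignment[i]`` is the
    estimated component matched to planted source i.
    """
    from scipy.optimize import linear_sum_assignment

    k_p, k_e = planted.shape[0], estimated.shape[0]
    corr = np.empty((k_p, k_e))
    for i in range(k_p):
        for j in range(k_e):
            corr[i, j] = abs(np.corrcoef(planted[i], estimated[j])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


# ---------------------------------------------------------------------------
# component-level statistics and selection
# ---------------------------------------------------------------------------

@dataclass
class ComponentTests:
    """Per-component selection statistics.

    ``table`` holds one row per component with group and gray-matter fields;
    ``outlier_flags`` is subject x component (Grubbs on loadings).
    """

    table: pd.DataFrame
    outlier_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def merged(self, other: "ComponentTests") -> "ComponentTests":
        cols = [c for c in other.table.columns if c not in self.table.columns]
        table = pd.concat([self.table, other.table[cols]], axis=1)
        flags = self.outlier_flags if self.outlier_flags is not None \
            else other.outlier_flags
        return ComponentTests(table=table, outlier_flags=flags)


def test_loading_group_difference(
    decomp: SourceDecomposition,
    is_patient: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> ComponentTests:
    """Robust permutation test of patient-vs-control loading differences.

    Per component: Huber IRLS regression of loading on the patient indicator;
    the robust t for the group coefficient is compared against ``n_perm``
    label shuffles (two-sided). Constant loadings give p = 1 (logged).
    Also flags per-subject loading outliers with the iterative Grubbs test.
    """
    is_patient = np.asarray(is_patient, dtype=bool)
    if is_patient.sum() < 3 or (~is_patient).sum() < 3:
        raise ValueError("each group needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    flags = np.zeros(decomp.loadings.shape, dtype=bool)
    for c in range(decomp.n_components):
        lam = decomp.loadings[:, c]
        if np.ptp(lam) == 0:
            logger.warning("component %d has constant loadings; p = 1", c)
            rows.append({"component": c, "group_t": 0.0, "group_p_perm": 1.0})
            continue
        t, p = permutation_group_test(
            lam, is_patient.astype(float), n_perm=n_perm, rng=rng
        )
        rows.append({"component": c, "group_t": t, "group_p_perm": p})
        out_idx = grubbs_test(lam)
        flags[out_idx, c] = True
    return ComponentTests(table=pd.DataFrame(rows), outlier_flags=flags)


def _robust_association(loadings: np.ndarray, gm: np.ndarray) -> tuple[float, float]:
    """Robust slope test and weighted-r equivalent of loading ~ total GM."""
    fit = huber_line_fit(gm, loadings)
    w = fit["weights"]
    # weighted Pearson correlation with the final IRLS weights
    wm_ = lambda v: np.average(v, weights=w)
    cov = wm_((gm - wm_(gm)) * (loadings - wm_(loadings)))
    sx = np.sqrt(wm_((gm - wm_(gm)) ** 2))
    sy = np.sqrt(wm_((loadings - wm_(loadings)) ** 2))
    r = cov / (sx * sy) if sx > 0 and sy > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(fit["t"]), df=len(gm) - 2)
    return float(r), float(p)


def test_loading_gm_association(
    decomp: SourceDecomposition,
    total_gm: np.ndarray,
    is_patient: np.ndarray,
) -> ComponentTests:
    """Robust association of loadings with total gray matter, per stratum.

    Strata: all subjects, patients only, controls only. A stratum with fewer
    than 4 subjects or constant GM is skipped (NaN) with a log message.
    """
    total_gm = np.asarray(total_gm, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    if len(total_gm) != decomp.loadings.shape[0]:
        raise ValueError("one total-GM value per subject required")
    strata = {
        "all": np.ones(len(total_gm), dtype=bool),
        "patients": is_patient,
        "controls": ~is_patient,
    }
    rows = []
    for c in range(decomp.n_components):
        row: dict[str, float] = {"component": c}
        for name, sel in strata.items():
            if sel.sum() < 4:
                logger.info("stratum %s has < 4 subjects; skipped", name)
                row[f"gm_r_{name}"] = np.nan
                row[f"gm_p_{name}"] = np.nan
                continue
            gm_s = total_gm[sel]
            if np.ptp(gm_s) == 0:
                logger.info("stratum %s has constant GM; skipped", name)
                row[f"gm_r_{name}"] = np.nan
                row[f"gm_p_{name}"] = np.nan
                continue
            r, p = _robust_association(decomp.loadings[sel, c], gm_s)
            row[f"gm_r_{name}"] = r
            row[f"gm_p_{name}"] = p
        rows.append(row)
    return ComponentTests(table=pd.DataFrame(rows))


def select_component(tests: ComponentTests, alpha: float = 0.05) -> int:
    """The unique group-differentiating, atrophy-associated component.

    Requires group permutation p < alpha AND a significant *negative*
    GM association in the patient stratum. Raises :class:`NoSelectionError`
    or :class:`AmbiguousSelectionError` when zero or several qualify.
    """
    t = tests.table
    required = {"group_p_perm", "gm_p_patients", "gm_r_patients"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"tests table missing fields: {sorted(missing)}")
    qualify = (
        (t["group_p_perm"] < alpha)
        & (t["gm_p_patients"] < alpha)
        & (t["gm_r_patients"] < 0)
    )
    candidates = t.loc[qualify, "component"].astype(int).tolist()
    if not candidates:
        raise NoSelectionError(
            "no component is both group-differentiating and negatively "
            "associated with gray matter in patients"
        )
    if len(candidates) > 1:
        raise AmbiguousSelectionError(candidates)
    return candidates[0]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t quantile."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_test(values: np.ndarray, alpha: float = 0.05) -> list[int]:
    """Iterative two-sided Grubbs outlier test.

    At each round the point with the largest ``|x - mean| / sd`` is flagged
    if its G statistic exceeds the t-based critical value; the test repeats
    on the remaining points until nothing is flagged. Returns the indices of
    flagged points (original order). Zero variance returns an empty list
    (logged); n < 3 raises.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    if np.ptp(x) == 0:
        logger.info("constant sample; Grubbs test skipped")
        return []
    active = list(range(len(x)))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(np.argmax(dev))
        G = dev[i_max] / sd
        if G > grubbs_critical_value(len(sub), alpha):
            flagged.append(active.pop(i_max))
        else:
            break
    return sorted(flagged)
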