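"""Second-level brain-score x group analysis of cognition.

A cognitive composite (first principal component of z-scored MMSE, ACE-R and
RAVLT) is regressed on first-level brain scores, diagnostic group, their
interaction, and covariates of no interest (age, sex, motion, total gray
matter) with a Huber-type robust fit; post hoc Pearson correlations are
reported within each group. Also provides the amyloid SUVR positivity rule
and a Table-1-style cohort summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONTROL_LABEL, PATIENT_LABEL, CohortTable

logger = logging.getLogger(__name__)

COGNITIVE_TESTS = ["MMSE", "ACER", "RAVLT"]
SECOND_LEVEL_COVARIATES = ["age", "sex", "motion_rms", "total_gm"]


@dataclass
class CognitiveComposite:
    """First principal component of the z-scored cognitive tests.

    Sign is fixed so all three loadings are nonnegative: a higher composite
    means better cognition.
    """

    pc1_scores: np.ndarray
    loadings: np.ndarray
    variance_explained: float

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.norm(self.loadings), 1.0):
            raise ValueError("loadings must be unit-norm")
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValueError("variance_explained must lie in [0, 1]")


@dataclass
class SecondLevelResult:
    """Term-level coefficients/t/p plus within-group post hoc correlations."""

    terms: pd.DataFrame
    df_resid: int
    within_group: pd.DataFrame | None = None

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def cognitive_pca(scores: pd.DataFrame) -> CognitiveComposite:
    """PCA of the three z-scored cognitive tests; returns the composite.

    Raises on missing values, fewer than 4 subjects, or a constant test
    column (named in the error).
    """
    missing = [c for c in COGNITIVE_TESTS if c not in scores.columns]
    if missing:
        raise ValueError(f"missing cognitive tests: {missing}")
    M = scores[COGNITIVE_TESTS].to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("cognitive scores contain missing values")
    if M.shape[0] < 4:
        raise ValueError("need at least 4 subjects for the cognitive PCA")
    sds = M.std(axis=0, ddof=1)
    for test, sd in zip(COGNITIVE_TESTS, sds):
        if sd == 0:
            raise ValueError(f"cognitive test {test!r} is constant")
    Z = (M - M.mean(axis=0)) / sds

    from sklearn.decomposition import PCA

    pca = PCA(n_components=len(COGNITIVE_TESTS))
    scores_all = pca.fit_transform(Z)
    load = pca.components_[0]
    pc1 = scores_all[:, 0]
    if load.sum() < 0:  # orient: higher composite = better cognition
        load, pc1 = -load, -pc1
    return CognitiveComposite(
        pc1_scores=pc1,
        loadings=load,
        variance_explained=float(pca.explained_variance_ratio_[0]),
    )


def _robust_fit_pvalues(y, X, names, estimator="huber"):
    import statsmodels.api as sm

    if estimator == "huber":
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    elif estimator == "ols":
        fit = sm.OLS(y, X).fit()
    else:
        raise ValueError("estimator must be 'huber' or 'ols'")
    df_resid = X.shape[0] - X.shape[1]
    t = fit.params / fit.bse
    # t-distribution with residual df rather than the normal reference:
    # closer to nominal size in small samples
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid)
    terms = pd.DataFrame({
        "term": names, "coefficient": fit.params, "t": t, "p": p,
    }).reset_index(drop=True)
    return terms, df_resid


def fit_interaction_model(
    composite: np.ndarray,
    brain_scores: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    estimator: str = "huber",
) -> SecondLevelResult:
    """Robust fit of cognition on brain score, group, and their interaction.

    Brain scores are mean-centered before the interaction is formed (to
    decorrelate main effect and interaction); group is coded patients = 1,
    controls = 0. Covariates (age, sex as F=1, motion, total GM) enter as
    given. Perfect collinearity raises with the aliased terms named.
    """
    y = np.asarray(composite, dtype=float)
    bs = np.asarray(brain_scores, dtype=float)
    grp = np.asarray(group)
    g = (grp == PATIENT_LABEL).astype(float) if grp.dtype.kind in "UO" \
        else grp.astype(float)
    if not (0 < g.sum() < len(g)):
        raise ValueError("both groups must be represented")
    if len({len(y), len(bs), len(g)}) != 1:
        raise ValueError("inputs must have one value per subject")

    bs_c = bs - bs.mean()
    cols = [np.ones(len(y)), bs_c, g, bs_c * g]
    names = ["intercept", "brain_score", "group", "brain_score_x_group"]
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype.kind in "UO":
            cov["sex"] = (cov["sex"] == "F").astype(float)
        for name in cov.columns:
            cols.append(cov[name].to_numpy(dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_terms(X, names)
        raise ValueError(f"perfectly collinear design; aliased terms: {aliased}")
    terms, df_resid = _robust_fit_pvalues(y, X, names, estimator)
    return SecondLevelResult(terms=terms, df_resid=df_resid)


def _aliased_terms(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
        X, mode="economic", pivoting=True
    )
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def within_group_correlations(
    composite: np.ndarray,
    brain_scores: np.ndarray,
    group: np.ndarray,
) -> pd.DataFrame:
    """Post hoc Pearson r between composite and brain scores per group."""
    y = np.asarray(composite, dtype=float)
    bs = np.asarray(brain_scores, dtype=float)
    grp = np.asarray(group)
    rows = []
    for label in (PATIENT_LABEL, CONTROL_LABEL):
        sel = grp == label
        if sel.sum() < 4:
            raise ValueError(f"group {label} has fewer than 4 subjects")
        if np.ptp(y[sel]) == 0 or np.ptp(bs[sel]) == 0:
            logger.info("group %s has degenerate variance; skipped", label)
            rows.append({"group": label, "n": int(sel.sum()),
                         "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(bs[sel], y[sel])
        rows.append({"group": label, "n": int(sel.sum()),
                     "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def amyloid_status(roi_suvr: list[float] | np.ndarray) -> str:
    """Amyloid classification: positive iff mean cortical SUVR > 1.5 (strict)."""
    vals = np.asarray(roi_suvr, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one ROI SUVR value")
    if (vals <= 0).any():
        raise ValueError("SUVR values must be positive")
    return "positive" if vals.mean() > 1.5 else "negative"


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, two-sided p with n1+n2-2 df); the sign follows mean2 - mean1.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean2 - mean1) / se
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


def cohort_summary(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Table-1-style summary: per-group mean/SD/range + group tests.

    Continuous variables get a pooled-variance two-sample t; sex gets a
    chi-squared test on the 2x2 contingency table.
    """
    df = table.table if isinstance(table, CohortTable) else table
    pat = df["group"] == PATIENT_LABEL
    if pat.sum() < 2 or (~pat).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    continuous = [
        c for c in ("age", "education", "MMSE", "ACER", "RAVLT",
                    "motion_rms", "total_gm")
        if c in df.columns
    ]
    rows = []
    if "sex" in df.columns:
        ct = pd.crosstab(df["group"], df["sex"])
        chi2, p, _, _ = stats.chi2_contingency(ct)
        rows.append({
            "variable": "sex", "statistic": "chi2", "value": float(chi2),
            "p": float(p),
            "patients": "/".join(str(v) for v in ct.loc[PATIENT_LABEL]),
            "controls": "/".join(str(v) for v in ct.loc[CONTROL_LABEL]),
        })
    for var in continuous:
        a = df.loc[pat, var].to_numpy(dtype=float)
        b = df.loc[~pat, var].to_numpy(dtype=float)
        t, p = pooled_t(a.mean(), a.std(ddof=1), len(a),
                        b.mean(), b.std(ddof=1), len(b))
        rows.append({
            "variable": var, "statistic": "t", "value": t, "p": p,
            "patients": f"{a.mean():.1f} (±{a.std(ddof=1):.1f}, "
                        f"{a.min():.1f}–{a.max():.1f})",
            "controls": f"{b.mean():.1f} (±{b.std(ddof=1):.1f}, "
                        f"{b.min():.1f}–{b.max():.1f})",
        })
    return pd.DataFrame(rows)
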