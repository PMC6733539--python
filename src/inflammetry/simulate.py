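"""Synthetic multimodal cohort generator.

Emulates the data structure of a TSPO-PET + resting-state fMRI case-control
study: 28 patients on the AD/MCI+ spectrum and 14 healthy controls, each with

* a 3-D PET binding-potential map built from a small number of smooth,
  spatially independent sources mixed by per-subject loadings, with one
  "target" source whose loadings are shifted upward in patients;
* node-level resting-state time-series for 13 nodes (5 default-mode,
  4 frontoparietal, 4 subcortical) whose latent inter-node correlations are
  coupled to the subject's target loading on designated connections;
* three cognitive test scores (MMSE-, ACE-R- and RAVLT-like) driven by a
  single latent factor that carries a group deficit and a brain-score x group
  interaction; and
* a cohort table with demographics, a scalar head-motion summary and a total
  gray-matter volume that is negatively tied to the target loading in
  patients (the planted "atrophy" association).

Every planted parameter is recorded in a :class:`GroundTruth` so downstream
recovery can be tested, and all randomness flows from a single master seed
through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CANONICAL_NODES,
    CONTROL_LABEL,
    PATIENT_LABEL,
    CohortTable,
    GridMeta,
    NodeTimeSeries,
    PKMapStack,
    connection_pairs,
)

logger = logging.getLogger(__name__)

#: SD of the test-specific noise added to each cognitive test on the latent
#: scale. Calibrated so the first principal component of the three z-scored
#: tests carries ~80% of their variance at default settings.
TEST_NOISE_SD = 0.45

#: magnitude of the planted connection weights (correlation units per unit
#: of centered target loading at coupling=1)
CONNECTION_WEIGHT = 0.2

#: planted correlation between target loading and total GM in patients
GM_LOADING_R = -0.65

_SUBSTREAMS = (
    "sources", "loadings", "map_noise", "gm_maps", "timeseries",
    "cognition", "covariates",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the emulated study: 28 patients vs 14 controls, 5 spatial
    sources on a 20x20x20 grid, 13 nodes, 263 usable volumes at TR 2.43 s.
    ``group_effect`` shifts the patients' mean loading on the target source;
    ``coupling`` ties latent connectivity to the centered target loading;
    ``interaction_slope`` is the cognition change per brain-score unit in
    patients (negative: higher inflammation-linked connectivity, worse
    cognition).
    """

    n_patients: int = 28
    n_controls: int = 14
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    n_sources: int = 5
    group_effect: float = 1.0
    map_noise_sd: float = 0.1
    n_nodes: int = 13
    n_timepoints: int = 263
    tr_seconds: float = 2.43
    coupling: float = 0.5
    interaction_slope: float = -0.5
    cognition_noise_sd: float = 0.15
    cognition_group_gap: float = 1.2
    loading_sd: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients, "n_controls": self.n_controls,
            "n_sources": self.n_sources, "n_nodes": self.n_nodes,
            "n_timepoints": self.n_timepoints,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if len(self.grid_dims) != 3 or any(int(d) < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be three positive voxel counts")
        if self.n_sources > self.n_subjects:
            raise ValueError("n_sources cannot exceed the number of subjects")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("map_noise_sd", "cognition_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.grid_dims = tuple(int(d) for d in self.grid_dims)

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def group_labels(self) -> np.ndarray:
        return np.array(
            [PATIENT_LABEL] * self.n_patients + [CONTROL_LABEL] * self.n_controls
        )

    @property
    def is_patient(self) -> np.ndarray:
        return np.r_[np.ones(self.n_patients, bool), np.zeros(self.n_controls, bool)]

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the master seed."""
        if stream not in _SUBSTREAMS:
            raise KeyError(f"unknown substream {stream!r}")
        idx = _SUBSTREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))[idx]
        )


@dataclass
class GroundTruth:
    """Planted parameters, recorded for recovery tests."""

    true_sources: np.ndarray          # component x voxel (full grid, F-order)
    true_loadings: np.ndarray         # subject x component
    target_component: int
    true_connection_weights: np.ndarray  # per-connection slope vector
    true_interaction_slope: float

    def __post_init__(self) -> None:
        k = self.true_sources.shape[0]
        if not 0 <= self.target_component < k:
            raise ValueError("target_component out of range")
        if self.true_loadings.shape[1] != k:
            raise ValueError("loadings/sources component mismatch")

    @property
    def centered_target_loadings(self) -> np.ndarray:
        lam = self.true_loadings[:, self.target_component]
        return lam - lam.mean()


def node_table(n_nodes: int) -> pd.DataFrame:
    """Node names and network membership.

    The canonical 13-node set (DMN 5, FPN 4, subcortical 4) is used when
    ``n_nodes == 13``; otherwise nodes are split into three generic blocks of
    roughly the same proportions.
    """
    if n_nodes == 13:
        names = CANONICAL_NODES
        nets = (["DMN"] * 5) + (["FPN"] * 4) + (["SC"] * 4)
    else:
        n_a = max(1, round(n_nodes * 5 / 13))
        n_b = max(0, round(n_nodes * 4 / 13))
        n_c = n_nodes - n_a - n_b
        names = [f"node{i:02d}" for i in range(1, n_nodes + 1)]
        nets = ["DMN"] * n_a + ["FPN"] * n_b + ["SC"] * max(n_c, 0)
        nets = nets[:n_nodes]
    return pd.DataFrame({"node": names, "network": nets})


def base_correlation_matrix(n_nodes: int = 13) -> np.ndarray:
    """Baseline inter-node correlation structure shared by all subjects.

    Strong positive within-network coupling, moderate DMN-FPN coupling,
    weakly positive DMN-hippocampus and weakly negative DMN-putamen edges.
    """
    nodes = node_table(n_nodes)
    nets = nodes["network"].to_numpy()
    names = nodes["node"].to_numpy()
    R = np.full((n_nodes, n_nodes), 0.05)
    for i in range(n_nodes):
        for j in range(n_nodes):
            ni, nj = nets[i], nets[j]
            if ni == nj:
                if ni == "SC" and n_nodes == 13:
                    same_struct = names[i][1:] == names[j][1:]  # lPut/rPut etc.
                    R[i, j] = 0.5 if same_struct else 0.2
                else:
                    R[i, j] = 0.5
            elif {ni, nj} == {"DMN", "FPN"}:
                R[i, j] = 0.2
            elif {ni, nj} == {"DMN", "SC"}:
                is_hipp = "Hipp" in names[i] or "Hipp" in names[j]
                R[i, j] = 0.15 if is_hipp else -0.1
            elif {ni, nj} == {"FPN", "SC"}:
                R[i, j] = 0.05
    np.fill_diagonal(R, 1.0)
    return R


def connection_weights(n_nodes: int = 13) -> np.ndarray:
    """Planted per-connection slopes tying connectivity to the target loading.

    Positive on DMN-hippocampus connections and negative on within-DMN
    connections (higher inflammation loading: DMN-subcortical hyperconnectivity
    and within-DMN breakdown); zero elsewhere.
    """
    nodes = node_table(n_nodes)
    nets = dict(zip(nodes["node"], nodes["network"]))
    pairs = connection_pairs(list(nodes["node"]))
    w = np.zeros(len(pairs))
    sc_targets = {n for n in nodes["node"] if "Hipp" in n} or {
        n for n, net in nets.items() if net == "SC"
    }
    for k, (a, b) in enumerate(pairs):
        na, nb = nets[a], nets[b]
        if na == "DMN" and nb == "DMN":
            w[k] = -CONNECTION_WEIGHT
        elif {na, nb} == {"DMN", "SC"} and (a in sc_targets or b in sc_targets):
            w[k] = CONNECTION_WEIGHT
    return w


# ---------------------------------------------------------------------------
# sources and PET-like maps
# ---------------------------------------------------------------------------

def generate_sources(config: SimulationConfig) -> np.ndarray:
    """Smooth, compact, near-orthogonal nonnegative source maps.

    Each source is an isotropic 3-D Gaussian blob with unit maximum, placed
    at a random center; centers are kept at least four blob SDs apart so the
    pairwise spatial correlation between sources stays below 0.2.
    Raises ``ValueError`` when the grid cannot hold the requested number of
    well-separated blobs.
    """
    rng = config.rng("sources")
    dims = np.array(config.grid_dims)
    k = config.n_sources
    if k > int(np.prod(dims)):
        raise ValueError(
            f"grid {tuple(dims)} too small for {k} sources: "
            f"only {int(np.prod(dims))} voxels"
        )
    sigma = max(min(dims) / 10.0, 0.8)
    margin = 2.0 * sigma
    min_dist = 4.0 * sigma
    lo = np.minimum(margin, (dims - 1) / 2.0)
    hi = np.maximum(dims - 1 - margin, (dims - 1) / 2.0)

    centers = _place_centers(rng, k, lo, hi, min_dist)
    if centers is None:
        raise ValueError(
            f"grid {tuple(dims)} too small to place {k} sources "
            f"{min_dist:.1f} voxels apart"
        )

    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    # reorder voxels to Fortran raveling to match GridMeta conventions
    order = np.argsort(
        np.ravel_multi_index(coords.T, dims, order="F"), kind="stable"
    )
    coords = coords[order]

    sources = np.empty((k, int(np.prod(dims))))
    for s in range(k):
        d2 = ((coords - centers[s]) ** 2).sum(axis=1)
        sources[s] = np.exp(-d2 / (2.0 * sigma ** 2))
        sources[s] /= sources[s].max()
    return sources


def _place_centers(rng, k, lo, hi, min_dist, n_restarts=200, n_tries=500):
    for _ in range(n_restarts):
        centers: list[np.ndarray] = []
        for _ in range(n_tries):
            cand = lo + rng.random(3) * (hi - lo)
            if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
                centers.append(cand)
                if len(centers) == k:
                    return np.array(centers)
    return None


def brain_probability_map(config: SimulationConfig) -> np.ndarray:
    """Smooth ellipsoidal gray-matter probability template (full grid, F-order).

    Probability ~0.75 deep inside an ellipsoid spanning most of the grid,
    tapering to ~0.05 outside; every blob placed by :func:`generate_sources`
    falls inside the >0.3 region so group masking keeps the sources.
    """
    dims = np.array(config.grid_dims)
    center = (dims - 1) / 2.0
    semi = np.maximum(0.55 * dims, 1.0)
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    rho = np.sqrt(
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    prob = 0.05 + 0.70 / (1.0 + np.exp((rho - 0.85) / 0.08))
    return prob.ravel(order="F")


def generate_gm_maps(config: SimulationConfig) -> np.ndarray:
    """Per-subject gray-matter probability maps: template + small jitter."""
    rng = config.rng("gm_maps")
    base = brain_probability_map(config)
    noise = rng.normal(0.0, 0.02, size=(config.n_subjects, base.size))
    return np.clip(base[None, :] + noise, 0.0, 1.0)


def generate_pk_maps(
    sources: np.ndarray, config: SimulationConfig
) -> tuple[PKMapStack, GroundTruth]:
    """Mix sources into subject maps: ``maps = loadings @ sources + noise``.

    Loadings are zero-mean normal with SD ``loading_sd`` per component;
    patients get ``group_effect`` added on the target component (the middle
    source), so the planted group difference in mean target loading equals
    ``group_effect`` exactly.
    The full-grid stack is returned unmasked (mask = all voxels); group
    masking is the first step of the SBI stage.
    """
    k, n_vox = sources.shape
    if k != config.n_sources:
        raise ValueError("sources shape inconsistent with config")
    rng = config.rng("loadings")
    loadings = config.loading_sd * rng.standard_normal((config.n_subjects, k))
    target = k // 2
    loadings[config.is_patient, target] += config.group_effect

    noise_rng = config.rng("map_noise")
    maps = loadings @ sources
    if config.map_noise_sd > 0:
        maps = maps + noise_rng.normal(
            0.0, config.map_noise_sd, size=maps.shape
        )

    grid = GridMeta(config.grid_dims, np.diag([2.0, 2.0, 2.0, 1.0]))
    stack = PKMapStack(
        maps=maps,
        mask=np.ones(n_vox, dtype=bool),
        grid=grid,
        subject_ids=subject_ids(config),
    )
    truth = GroundTruth(
        true_sources=sources,
        true_loadings=loadings,
        target_component=target,
        true_connection_weights=connection_weights(config.n_nodes),
        true_interaction_slope=config.interaction_slope,
    )
    return stack, truth


def subject_ids(config: SimulationConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# node time-series
# ---------------------------------------------------------------------------

def nearest_correlation(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Higham-style alternating projection to the nearest correlation matrix."""
    Y = R.copy()
    dS = np.zeros_like(R)
    for _ in range(100):
        Rk = Y - dS
        vals, vecs = np.linalg.eigh(Rk)
        X = (vecs * np.maximum(vals, eps)) @ vecs.T
        dS = X - Rk
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.min(np.linalg.eigvalsh(Y)) > eps / 2:
            break
    return (Y + Y.T) / 2.0


def subject_correlation_matrices(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[np.ndarray, int]:
    """Latent inter-node correlation matrix per subject.

    Connection j of subject i has latent correlation
    ``base_r(j) + coupling * weight(j) * centered_loading(i)``, clipped to
    (-0.95, 0.95); non-positive-definite matrices are repaired to the nearest
    correlation matrix. Returns the (n_subjects, n_nodes, n_nodes) array and
    the number of repair events (also logged).
    """
    n_nodes = config.n_nodes
    base = base_correlation_matrix(n_nodes)
    w = truth.true_connection_weights
    cl = truth.centered_target_loadings
    iu = np.triu_indices(n_nodes, k=1)
    mats = np.empty((config.n_subjects, n_nodes, n_nodes))
    n_repaired = 0
    for i in range(config.n_subjects):
        r = base[iu] + config.coupling * w * cl[i]
        r = np.clip(r, -0.95, 0.95)
        R = np.eye(n_nodes)
        R[iu] = r
        R = R + R.T - np.diag(np.diag(R))
        if np.min(np.linalg.eigvalsh(R)) <= 1e-8:
            R = nearest_correlation(R)
            n_repaired += 1
        mats[i] = R
    if n_repaired:
        logger.info(
            "repaired %d non-positive-definite latent correlation matrices",
            n_repaired,
        )
    return mats, n_repaired


def generate_timeseries(
    truth: GroundTruth, config: SimulationConfig
) -> list[NodeTimeSeries]:
    """Stationary Gaussian node time-series with the planted correlations.

    Time points are drawn i.i.d. from a multivariate normal with the
    subject's latent correlation matrix (no temporal autocorrelation: only
    the connectivity estimates matter downstream).
    """
    mats, _ = subject_correlation_matrices(truth, config)
    rng = config.rng("timeseries")
    names = list(node_table(config.n_nodes)["node"])
    out = []
    for i in range(config.n_subjects):
        L = np.linalg.cholesky(mats[i])
        z = rng.standard_normal((config.n_timepoints, config.n_nodes))
        out.append(
            NodeTimeSeries(
                values=(z @ L.T).T, tr=config.tr_seconds, node_names=names
            )
        )
    return out


# ---------------------------------------------------------------------------
# cognition and cohort table
# ---------------------------------------------------------------------------

#: affine maps from the latent cognition scale to test-like units
TEST_SCALES = {
    "MMSE": (27.7, 2.2),
    "ACER": (83.1, 8.5),
    "RAVLT": (4.2, 4.0),
}


def generate_cognition(
    brain_score_truth: np.ndarray,
    group: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Three cognitive test scores driven by one latent factor.

    The latent factor is
    ``g = -gap * patient + interaction_slope * centered_score * patient +
    noise``; each observed test is ``g`` plus test-specific noise
    (SD :data:`TEST_NOISE_SD` on the latent scale), mapped to MMSE-, ACE-R-
    and RAVLT-like units. At default settings the first principal component
    of the three z-scored tests explains ~80% of their variance.
    """
    rng = config.rng("cognition") if rng is None else rng
    bs = np.asarray(brain_score_truth, dtype=float)
    pat = np.asarray(group) == PATIENT_LABEL if np.asarray(group).dtype.kind in "UO" \
        else np.asarray(group, dtype=bool)
    if len(bs) != len(pat):
        raise ValueError("brain scores and group lengths differ")
    bs_c = bs - bs.mean()
    g_lat = (
        -config.cognition_group_gap * pat.astype(float)
        + config.interaction_slope * bs_c * pat
        + rng.normal(0.0, config.cognition_noise_sd, size=len(bs))
    )
    out = {}
    for test, (center, spread) in TEST_SCALES.items():
        observed = g_lat + rng.normal(0.0, TEST_NOISE_SD, size=len(bs))
        out[test] = center + spread * observed
    return pd.DataFrame(out)


def generate_covariates(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Demographics, motion and total gray matter.

    Ages/education follow the case-control profile of the emulated cohort;
    total GM is planted with correlation :data:`GM_LOADING_R` to the target
    loading within patients (atrophy tracks inflammation) and is independent
    of loading in controls.
    """
    rng = config.rng("covariates")
    pat = config.is_patient
    n = config.n_subjects
    age = np.where(
        pat,
        rng.normal(72.7, 8.5, n),
        rng.normal(68.3, 5.4, n),
    ).round(1)
    sex = np.where(rng.random(n) < np.where(pat, 12 / 28, 8 / 14), "F", "M")
    education = np.clip(
        np.where(pat, rng.normal(12.9, 3.0, n), rng.normal(14.1, 2.7, n)),
        8, 22,
    ).round(1)
    motion = np.exp(rng.normal(-1.8, 0.35, n) + 0.15 * pat).round(4)

    lam = truth.true_loadings[:, truth.target_component]
    z = np.empty(n)
    lam_p = lam[pat]
    lam_z = (lam_p - lam_p.mean()) / max(lam_p.std(), 1e-12)
    z[pat] = GM_LOADING_R * lam_z + np.sqrt(
        1 - GM_LOADING_R ** 2
    ) * rng.standard_normal(pat.sum())
    z[~pat] = rng.standard_normal((~pat).sum())
    total_gm = np.where(pat, 580.0, 640.0) + 55.0 * z

    return pd.DataFrame({
        "age": age, "sex": sex, "education": education,
        "motion_rms": motion, "total_gm": total_gm.round(2),
    })


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    stack: PKMapStack
    gm_maps: np.ndarray
    series: list[NodeTimeSeries]
    table: CohortTable
    truth: GroundTruth


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete multimodal cohort from one master seed."""
    sources = generate_sources(config)
    stack, truth = generate_pk_maps(sources, config)
    gm_maps = generate_gm_maps(config)
    series = generate_timeseries(truth, config)
    cognition = generate_cognition(
        truth.true_loadings[:, truth.target_component],
        config.group_labels,
        config,
    )
    covars = generate_covariates(truth, config)
    table = pd.DataFrame({
        "subject_id": subject_ids(config),
        "group": config.group_labels,
    })
    table = pd.concat(
        [table, covars[["age", "sex", "education"]], cognition,
         covars[["motion_rms", "total_gm"]]],
        axis=1,
    )
    return SyntheticCohort(
        config=config,
        stack=stack,
        gm_maps=gm_maps,
        series=series,
        table=CohortTable(table),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, list[str]]:
    """Write a cohort to disk: NIfTI maps, TSV time-series, CSV table, JSON truth.

    Layout: ``pet/<sub>_pk.nii``, ``gm/<sub>_gmprob.nii``, ``ts/<sub>_ts.tsv``,
    ``cohort.csv``, ``ground_truth.json``. Maps are stored float32; re-reading
    reproduces arrays within float32 precision. Returns the file manifest.
    """
    import nibabel as nib

    out = Path(out_dir)
    for sub in ("pet", "gm", "ts"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    grid = cohort.stack.grid
    files: dict[str, list[str]] = {"pet": [], "gm": [], "ts": []}
    for i, sid in enumerate(cohort.stack.subject_ids):
        vol = grid.unravel(cohort.stack.maps[i]).astype(np.float32)
        p = out / "pet" / f"{sid}_pk.nii"
        nib.save(nib.Nifti1Image(vol, grid.affine), p)
        files["pet"].append(str(p))
        gvol = grid.unravel(cohort.gm_maps[i]).astype(np.float32)
        p = out / "gm" / f"{sid}_gmprob.nii"
        nib.save(nib.Nifti1Image(gvol, grid.affine), p)
        files["gm"].append(str(p))
        ts = cohort.series[i]
        p = out / "ts" / f"{sid}_ts.tsv"
        pd.DataFrame(ts.values.T, columns=ts.node_names).to_csv(
            p, sep="\t", index=False
        )
        files["ts"].append(str(p))
    cohort.table.table.to_csv(out / "cohort.csv", index=False)
    files["cohort"] = [str(out / "cohort.csv")]

    truth = cohort.truth
    payload = {
        "config": dataclasses.asdict(cohort.config),
        "target_component": int(truth.target_component),
        "true_loadings": truth.true_loadings.tolist(),
        "true_connection_weights": truth.true_connection_weights.tolist(),
        "true_interaction_slope": float(truth.true_interaction_slope),
        "true_sources": truth.true_sources.tolist(),
        "tr_seconds": cohort.config.tr_seconds,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
    files["ground_truth"] = [str(out / "ground_truth.json")]
    return files


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Reload a :class:`GroundTruth` written by :func:`write_cohort`."""
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        true_sources=np.array(payload["true_sources"]),
        true_loadings=np.array(payload["true_loadings"]),
        target_component=payload["target_component"],
        true_connection_weights=np.array(payload["true_connection_weights"]),
        true_interaction_slope=payload["true_interaction_slope"],
    )
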