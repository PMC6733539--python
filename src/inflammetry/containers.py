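"""Shared in-memory containers for the inflammetry pipeline.

These are thin, validated dataclasses that the stage modules pass between
each other: masked PET binding maps, ICA decompositions, node time-series,
connectivity vectors and the cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical resting-state node set: 5 default-mode, 4 frontoparietal,
#: 4 subcortical nodes (bilateral putamen and hippocampus).
DMN_NODES = ["vACC", "dPCC", "vPCC", "lIPL", "rIPL"]
FPN_NODES = ["lSFG", "rSFG", "lAG", "rAG"]
SUBCORTICAL_NODES = ["lPut", "rPut", "lHipp", "rHipp"]
CANONICAL_NODES = DMN_NODES + FPN_NODES + SUBCORTICAL_NODES

#: network membership for the canonical node set
NODE_NETWORK = {
    **{n: "DMN" for n in DMN_NODES},
    **{n: "FPN" for n in FPN_NODES},
    **{n: "SC" for n in SUBCORTICAL_NODES},
}

PATIENT_LABEL = "AD_MCI"
CONTROL_LABEL = "HC"


def connection_pairs(node_names: list[str]) -> list[tuple[str, str]]:
    """Upper-triangle node pairs in lexicographic (i < j) index order.

    This fixed ordering is the documented bijection between connectivity
    vectors and node pairs, used everywhere a per-connection quantity is
    stored: pair k corresponds to (i, j) with i < j, i varying slowest.
    """
    n = len(node_names)
    return [(node_names[i], node_names[j]) for i in range(n) for j in range(i + 1, n)]


def connection_labels(node_names: list[str]) -> list[str]:
    return [f"{a}—{b}" for a, b in connection_pairs(node_names)]


@dataclass
class GridMeta:
    """Voxel-grid metadata: array shape, affine (voxel -> mm), voxel order.

    Voxel vectors use Fortran raveling (first axis fastest-varying).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def ravel(self, volume: np.ndarray) -> np.ndarray:
        return np.asarray(volume).ravel(order="F")

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat).reshape(self.shape, order="F")

    def voxel_coordinates_mm(self) -> np.ndarray:
        """(n_voxels, 3) world coordinates of voxel centers, Fortran order."""
        idx = np.indices(self.shape).reshape(3, -1, order="C")
        # np.indices is C-ordered over the grid; reorder to Fortran raveling
        flat_f = np.arange(self.n_voxels).reshape(self.shape, order="F")
        order = np.argsort(flat_f.ravel(order="C"), kind="stable")
        ijk = idx[:, order].T
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]


@dataclass
class PKMapStack:
    """Subject-by-voxel matrix of PET binding-potential values.

    ``maps`` holds only voxels inside ``mask`` (columns follow the masked
    Fortran-order voxel sequence).
    """

    maps: np.ndarray
    mask: np.ndarray
    grid: GridMeta
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.maps.ndim != 2:
            raise ValueError("maps must be subject x voxel")
        if int(self.mask.sum()) != self.maps.shape[1]:
            raise ValueError(
                f"masked voxel count {int(self.mask.sum())} does not match "
                f"matrix columns {self.maps.shape[1]}"
            )
        if not np.isfinite(self.maps).all():
            raise ValueError("maps contain non-finite values")
        if len(self.subject_ids) != self.maps.shape[0]:
            raise ValueError("subject_ids length must match number of rows")

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]


@dataclass
class SourceDecomposition:
    """Spatial ICA result: source maps (component x voxel) and the mixing
    matrix of per-subject loadings (subject x component).

    Each source is standardized to unit variance over masked voxels and
    sign-fixed so its skewness over voxels is positive ("hot spots" load
    positively); the scale and sign are folded into the loadings.
    """

    sources: np.ndarray
    loadings: np.ndarray
    n_components: int
    mean: np.ndarray
    selected: int | None = None

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.sources.shape[0] != self.n_components:
            raise ValueError("sources rows must equal n_components")
        if self.loadings.shape[1] != self.n_components:
            raise ValueError("loadings columns must equal n_components")


@dataclass
class NodeTimeSeries:
    """Node x time matrix of (cleaned or raw) signals with TR metadata."""

    values: np.ndarray
    tr: float
    node_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be node x time")
        if len(self.node_names) != self.values.shape[0]:
            raise ValueError("node_names length must match rows")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if self.values.shape[1] < 10:
            raise ValueError("need at least 10 time points")
        if not np.isfinite(self.values).all():
            raise ValueError("time-series contain non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityVector:
    """Per-subject vector of pairwise Pearson correlations (upper triangle)."""

    r: np.ndarray
    pair_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1 or len(self.r) != len(self.pair_index):
            raise ValueError("r length must match pair_index")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def labels(self) -> list[str]:
        return [f"{a}—{b}" for a, b in self.pair_index]


@dataclass
class CohortTable:
    """Cohort table: group labels, demographics, cognition, covariates."""

    table: pd.DataFrame

    REQUIRED = [
        "subject_id", "group", "age", "sex", "education",
        "MMSE", "ACER", "RAVLT", "motion_rms", "total_gm",
    ]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        groups = set(self.table["group"])
        unknown = groups - {PATIENT_LABEL, CONTROL_LABEL}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def is_patient(self) -> np.ndarray:
        return (self.table["group"] == PATIENT_LABEL).to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.table)
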