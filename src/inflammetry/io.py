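"""File I/O: NIfTI stacks, node time-series TSVs, motion files, manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import CohortTable, GridMeta, NodeTimeSeries, PKMapStack

logger = logging.getLogger(__name__)


def read_nifti_stack(
    paths: list[str | Path], mask: np.ndarray | None = None
) -> PKMapStack:
    """Load subject NIfTI volumes into a subject x voxel matrix.

    All files must share grid shape and affine (a mismatch raises with the
    offending file named). Voxels are raveled Fortran-style (first axis
    fastest-varying); an optional boolean ``mask`` over the full grid
    restricts the columns.
    """
    if not paths:
        raise ValueError("no input files")
    imgs = [nib.load(str(p)) for p in paths]
    ref = imgs[0]
    shape, affine = ref.shape[:3], ref.affine
    rows = []
    for p, img in zip(paths, imgs):
        if img.shape[:3] != shape or not np.allclose(img.affine, affine):
            raise ValueError(f"grid mismatch in {p}")
        rows.append(np.asarray(img.get_fdata()).ravel(order="F"))
    maps = np.vstack(rows)
    grid = GridMeta(tuple(int(s) for s in shape), np.asarray(affine))
    if mask is None:
        mask = np.ones(grid.n_voxels, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        maps = maps[:, mask]
    return PKMapStack(
        maps=maps, mask=mask, grid=grid,
        subject_ids=[Path(p).name.split("_")[0] for p in paths],
    )


def write_source_maps(
    sources: np.ndarray, mask: np.ndarray, grid: GridMeta, out_dir: str | Path
) -> list[str]:
    """Write component source maps as NIfTI volumes (zeros outside the mask)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for c in range(sources.shape[0]):
        flat = np.zeros(grid.n_voxels, dtype=np.float32)
        flat[mask] = sources[c]
        img = nib.Nifti1Image(grid.unravel(flat).astype(np.float32), grid.affine)
        p = out / f"source_{c + 1:02d}.nii"
        nib.save(img, p)
        written.append(str(p))
    return written


def read_timeseries_tsv(path: str | Path, tr: float) -> NodeTimeSeries:
    """Read a node time-series TSV (nodes as columns, header of node names)."""
    df = pd.read_csv(path, sep="\t")
    return NodeTimeSeries(
        values=df.to_numpy(dtype=float).T, tr=tr, node_names=list(df.columns)
    )


def read_motion_params(path: str | Path) -> np.ndarray:
    """6-column whitespace-delimited realignment parameters (rotations in rad)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns of motion parameters")
    return arr


def read_cohort_csv(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Record of one pipeline run: config hash, seed, file digests.

    Deterministic stages reproduce identical digests under identical config
    and seed; timestamps are recorded but excluded from equality.
    """

    def __init__(self, config_hash: str, seed: int):
        import time

        from . import __version__

        self.config_hash = config_hash
        self.seed = seed
        self.version = __version__
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, files: list[str | Path],
               status: str = "ok", error: str | None = None) -> None:
        self.stages[stage] = {
            "status": status,
            "error": error,
            "digests": {Path(f).name: file_digest(f) for f in files},
        }

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "started": self.started,
            "stages": self.stages,
        }

    def deterministic_view(self) -> dict:
        """The manifest without timestamps, for reproducibility comparisons."""
        d = self.to_dict()
        d.pop("started")
        return d

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
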