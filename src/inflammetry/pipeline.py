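"""Stage orchestration: simulate → connectivity → SBI → first-level → second-level.

Each stage reads the previous stage's plain-text artifacts (NIfTI / TSV /
CSV / JSON) from the output directory, so any stage can be re-run or
inspected on its own, and writes a manifest of file digests at the end.
A stage failure halts the run with a stage-tagged error that is also
recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import crossmodal as cm
from . import sbi
from . import second_level as sl
from . import simulate as sim
from .config import PipelineConfig
from .containers import CohortTable
from .io import RunManifest, read_cohort_csv, read_nifti_stack, \
    read_timeseries_tsv, write_source_maps

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages on a synthetic cohort and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), config.seed)

    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

    try:
        files = stage_simulate(config, out)
        manifest.record("simulate", files)
        files = stage_connectivity(config, out)
        manifest.record("connectivity", files)
        files = stage_sbi(config, out)
        manifest.record("sbi", files)
        files = stage_crossmodal(config, out)
        manifest.record("crossmodal", files)
        files = stage_secondlevel(config, out)
        manifest.record("secondlevel", files)
    except PipelineError as err:
        manifest.record(err.stage, [], status="error", error=str(err.cause))
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _wrap(stage: str):
    def decorator(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(stage, err) from err
        return inner
    return decorator


@_wrap("simulate")
def stage_simulate(config: PipelineConfig, out: Path) -> list[str]:
    cohort = sim.generate_cohort(config.simulate)
    files = sim.write_cohort(cohort, out / "sim")
    return [f for group in files.values() for f in group]


@_wrap("connectivity")
def stage_connectivity(config: PipelineConfig, out: Path) -> list[str]:
    sim_dir = out / "sim"
    cohort = read_cohort_csv(sim_dir / "cohort.csv")
    rows, labels = [], None
    for sid in cohort.table["subject_id"]:
        ts_path = sim_dir / "ts" / f"{sid}_ts.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing upstream time-series {ts_path}")
        ts = read_timeseries_tsv(ts_path, tr=config.simulate.tr_seconds)
        vec = conn.connectivity_vector(ts)
        rows.append(vec.r)
        labels = vec.labels
    fc = pd.DataFrame(np.vstack(rows), columns=labels)
    fc.insert(0, "subject_id", cohort.table["subject_id"])
    fc_path = out / "connectivity.csv"
    fc.to_csv(fc_path, index=False)

    stats = conn.group_connectivity_stats(
        np.vstack(rows), cohort.table["group"].to_numpy(),
        patient_label="AD_MCI",
        pair_index=[tuple(lbl.split("—")) for lbl in labels],
    )
    stats_path = out / "connectivity_group_stats.csv"
    stats.to_csv(stats_path, index=False)
    return [str(fc_path), str(stats_path)]


@_wrap("sbi")
def stage_sbi(config: PipelineConfig, out: Path) -> list[str]:
    sim_dir = out / "sim"
    cohort = read_cohort_csv(sim_dir / "cohort.csv")
    ids = list(cohort.table["subject_id"])
    pet_paths = [sim_dir / "pet" / f"{sid}_pk.nii" for sid in ids]
    gm_paths = [sim_dir / "gm" / f"{sid}_gmprob.nii" for sid in ids]
    for p in pet_paths + gm_paths:
        if not p.exists():
            raise FileNotFoundError(f"missing upstream map {p}")
    gm_stack = read_nifti_stack(gm_paths)
    mask = sbi.build_group_mask(gm_stack.maps, config.sbi.mask_threshold)
    stack = read_nifti_stack(pet_paths, mask=mask)

    n_comp = config.sbi.n_components or sbi.estimate_n_components(stack)
    seed = config.stage_seed("sbi")
    decomp = sbi.decompose(stack, n_comp, seed=seed)
    tests = sbi.test_loading_group_difference(
        decomp, cohort.is_patient, n_perm=config.sbi.n_perm, seed=seed
    ).merged(sbi.test_loading_gm_association(
        decomp, cohort.table["total_gm"].to_numpy(), cohort.is_patient
    ))
    selected = sbi.select_component(tests, alpha=config.sbi.alpha)
    decomp.selected = selected

    loadings = pd.DataFrame(
        decomp.loadings,
        columns=[f"IC{c + 1}" for c in range(n_comp)],
    )
    loadings.insert(0, "subject_id", ids)
    loadings_path = out / "sbi_loadings.csv"
    loadings.to_csv(loadings_path, index=False)
    tests_path = out / "sbi_component_tests.csv"
    tests.table.assign(selected=tests.table["component"] == selected) \
        .to_csv(tests_path, index=False)
    source_files = write_source_maps(
        decomp.sources, mask, stack.grid, out / "sbi_sources"
    )
    meta_path = out / "sbi_meta.json"
    with open(meta_path, "w") as fh:
        json.dump({
            "n_components": int(n_comp),
            "selected_component": int(selected),
            "mask_voxels": int(mask.sum()),
            "mask_threshold": config.sbi.mask_threshold,
        }, fh, indent=2)
    return [str(loadings_path), str(tests_path), str(meta_path), *source_files]


def _covariate_matrix(cohort: CohortTable) -> np.ndarray:
    cov = cohort.table[sl.SECOND_LEVEL_COVARIATES].copy()
    cov["sex"] = (cov["sex"] == "F").astype(float)
    return cov.to_numpy(dtype=float)


@_wrap("crossmodal")
def stage_crossmodal(config: PipelineConfig, out: Path) -> list[str]:
    cohort = read_cohort_csv(out / "sim" / "cohort.csv")
    fc_df = pd.read_csv(out / "connectivity.csv")
    with open(out / "sbi_meta.json") as fh:
        selected = json.load(fh)["selected_component"]
    loadings_df = pd.read_csv(out / "sbi_loadings.csv")
    fc = fc_df.drop(columns="subject_id").to_numpy(dtype=float)
    y = loadings_df[f"IC{selected + 1}"].to_numpy(dtype=float)

    outliers = cm.grubbs_screen(y, alpha=config.sbi.alpha)
    keep = np.setdiff1d(np.arange(len(y)), outliers)
    if len(outliers):
        logger.warning(
            "excluding %d loading outliers (Grubbs): subjects %s",
            len(outliers), list(loadings_df["subject_id"].iloc[outliers]),
        )
    fc, y = fc[keep], y[keep]
    cohort_kept = CohortTable(cohort.table.iloc[keep].reset_index(drop=True))

    if config.crossmodal.covariate_placement in ("first_level", "both"):
        Z = _covariate_matrix(cohort_kept)
        fc = cm.residualize(fc, Z)
        y = cm.residualize(y, Z)

    seed = config.stage_seed("crossmodal")
    cv_cfg = config.crossmodal.cv_config(seed)
    result = cm.significance_and_thresholding(
        fc, y, cv_cfg,
        n_perm=config.crossmodal.n_perm,
        alpha=config.crossmodal.alpha,
        seed=seed,
    )

    conn_labels = [c for c in fc_df.columns if c != "subject_id"]
    conn_table = pd.DataFrame({
        "connection": [conn_labels[j] for j in result.kept_columns],
        "weight": result.coefficients,
        "structure_coefficient": result.structure_coefficients,
        "p_perm": result.connection_p,
        "p_fdr": result.connection_p_fdr,
        "significant": np.isin(
            np.arange(len(result.kept_columns)), result.significant_connections
        ),
    })
    conn_path = out / "crossmodal_connections.csv"
    conn_table.to_csv(conn_path, index=False)

    scores = pd.DataFrame({
        "subject_id": cohort.table["subject_id"].iloc[keep].to_numpy(),
        "brain_score": result.brain_scores,
    })
    scores_path = out / "brain_scores.csv"
    scores.to_csv(scores_path, index=False)

    summary_path = out / "crossmodal_summary.json"
    with open(summary_path, "w") as fh:
        json.dump({
            "insample_r": result.insample_r,
            "cv_r_median": result.cv_r_median,
            "model_p": result.model_p,
            "shrinkage": result.shrinkage,
            "n_excluded_outliers": int(len(outliers)),
            "n_significant_connections": int(len(result.significant_connections)),
        }, fh, indent=2)
    return [str(conn_path), str(scores_path), str(summary_path)]


@_wrap("secondlevel")
def stage_secondlevel(config: PipelineConfig, out: Path) -> list[str]:
    cohort = read_cohort_csv(out / "sim" / "cohort.csv")
    scores = pd.read_csv(out / "brain_scores.csv")
    merged = cohort.table.merge(scores, on="subject_id", how="inner")

    composite = sl.cognitive_pca(merged[sl.COGNITIVE_TESTS])
    covariates = merged[sl.SECOND_LEVEL_COVARIATES]
    result = sl.fit_interaction_model(
        composite.pc1_scores,
        merged["brain_score"].to_numpy(),
        merged["group"].to_numpy(),
        covariates=covariates,
        estimator=config.secondlevel.estimator,
    )
    within = sl.within_group_correlations(
        composite.pc1_scores,
        merged["brain_score"].to_numpy(),
        merged["group"].to_numpy(),
    )
    summary = sl.cohort_summary(CohortTable(merged[CohortTable.REQUIRED]))

    terms_path = out / "secondlevel_terms.csv"
    result.terms.to_csv(terms_path, index=False)
    within_path = out / "secondlevel_withingroup.csv"
    within.to_csv(within_path, index=False)
    summary_path = out / "cohort_summary.csv"
    summary.to_csv(summary_path, index=False)
    meta_path = out / "secondlevel_meta.json"
    with open(meta_path, "w") as fh:
        json.dump({
            "pc1_variance_explained": composite.variance_explained,
            "pc1_loadings": composite.loadings.tolist(),
            "interaction_t": float(result.term("brain_score_x_group")["t"]),
            "interaction_p": float(result.term("brain_score_x_group")["p"]),
        }, fh, indent=2)
    return [str(terms_path), str(within_path), str(summary_path), str(meta_path)]
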