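"""End-to-end orchestration of the analysis chain.

``run_all`` executes: cohort simulation (or loading) -> per-subject
preprocessing and QA -> ReHo mapping and seed discovery -> seed-based
connectivity -> Monte-Carlo extent thresholds -> group statistics with
gray-matter correction -> behavior regressions and conjunction ->
mediation.  A single summary dictionary is written as JSON; for a fixed
seed the summary is byte-identical across runs.

Heavy per-subject stage outputs are content-addressed by the resolved
config hash and reloaded on reruns unless ``force`` is given.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .atlas import NETWORKS, SEED_REGIONS, AtlasSpec, default_atlas
from .behavior import add_composites, group_summary
from .clustersim import estimate_extent_threshold
from .config import PipelineConfig
from .connectivity import fc_map_z
from .core import SeedROI, StatMap
from .mediation import extract_mediator, fit_mediation
from .preprocess import (exclusion_check, framewise_drms,
                         motion_group_comparison, preprocess_series, scrub)
from .reho import normalize_reho, reho_map, select_seeds, smooth_map, smooth_series
from .stats import (behavior_regression, cluster_table,
                    cluster_table_from_set, conjunction, group_glm, logit_gm,
                    one_sample_map, partial_correlation, significant_set,
                    t_critical)
from .synth import Cohort, default_truth, generate_cohort

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and subject context."""

    def __init__(self, stage: str, detail: str, subject_id: str | None = None):
        self.stage = stage
        self.subject_id = subject_id
        where = f"stage {stage!r}" + (f", subject {subject_id}" if subject_id else "")
        super().__init__(f"{where}: {detail}")


def _cache_path(outdir: Path, stage: str) -> Path:
    return outdir / "cache" / f"{stage}.npz"


def _cache_load(outdir: Path, stage: str, cfg_hash: str, force: bool):
    path = _cache_path(outdir, stage)
    if force or not path.exists():
        return None
    with np.load(path, allow_pickle=False) as z:
        if str(z["config_hash"]) != cfg_hash:
            return None
        return {k: z[k] for k in z.files if k != "config_hash"}


def _cache_save(outdir: Path, stage: str, cfg_hash: str, **arrays) -> None:
    path = _cache_path(outdir, stage)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, config_hash=cfg_hash, **arrays)


def _round_floats(obj, ndigits: int = 8):
    """Round floats recursively so the summary JSON is stable and readable."""
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _table_records(df: pd.DataFrame) -> list[dict]:
    return [{k: (v if not isinstance(v, (np.floating, np.integer)) else
                 (float(v) if isinstance(v, np.floating) else int(v)))
             for k, v in row.items()} for row in df.to_dict("records")]


def run_all(config: PipelineConfig, outdir, force: bool = False,
            cohort: Cohort | None = None) -> dict:
    """Run the whole chain; returns (and writes) the summary dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.resolved_hash()
    config.save(outdir / "config_resolved.yaml")
    timings: dict[str, float] = {}

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = time.perf_counter() - timings[stage]
        log.info("stage %-12s %.1f s", stage, timings[stage])

    # ----- cohort -------------------------------------------------------
    tic("cohort")
    if cohort is None:
        if not config.simulate:
            raise StageError("cohort", "simulate=False requires a cohort or data_dir")
        cohort = generate_cohort(
            config.n_patient, config.n_control, seed=config.seed,
            n_volumes=config.n_volumes, tr_s=config.tr_s)
    atlas = cohort.atlas
    brain = atlas.brain_mask
    nuisance_masks = {"global": brain, "wm": atlas.regions["wm"],
                      "csf": atlas.regions["csf"]}
    toc("cohort")

    # ----- behavior -----------------------------------------------------
    tic("behavior")
    phenotypes = add_composites(cohort.phenotypes)
    toc("behavior")

    # ----- preprocessing pass 1: QA + ReHo maps -------------------------
    tic("reho")
    n = cohort.n_subjects
    excluded = []
    mean_drms = np.zeros(n)
    n_scrubbed = np.zeros(n, dtype=int)
    cached = _cache_load(outdir, "reho_maps", cfg_hash, force)
    if cached is not None:
        reho_smoothed = list(cached["reho"])
        gm_logit = list(cached["gm"])
        mean_drms = cached["mean_drms"]
        excluded = [cohort.subjects[i].subject_id
                    for i in np.where(cached["excluded"])[0]]
    else:
        reho_smoothed, gm_logit = [], []
        excl_flags = np.zeros(n, dtype=bool)
        for i in range(n):
            sid = cohort.subjects[i].subject_id
            try:
                if exclusion_check(cohort.motions[i], config.exclusion_max_mm,
                                   config.exclusion_max_deg):
                    excl_flags[i] = True
                    excluded.append(sid)
                pp, motion = preprocess_series(
                    cohort.bold(i), cohort.motions[i], nuisance_masks,
                    n_discard=config.n_discard,
                    band_hz=(config.band_low_hz, config.band_high_hz),
                    global_signal=config.global_signal)
                mean_drms[i] = framewise_drms(motion).mean()
                rmap = normalize_reho(reho_map(pp, neighborhood=config.neighborhood))
                reho_smoothed.append(smooth_map(rmap.values, config.fwhm_mm,
                                                atlas.voxel_size_mm, brain))
                gm_logit.append(logit_gm(cohort.gm_maps[i], config.fwhm_mm,
                                         atlas.voxel_size_mm, mask=brain))
            except Exception as exc:  # noqa: BLE001 - abort names the subject
                raise StageError("reho", str(exc), sid) from exc
        _cache_save(outdir, "reho_maps", cfg_hash,
                    reho=np.stack(reho_smoothed), gm=np.stack(gm_logit),
                    mean_drms=mean_drms, excluded=excl_flags)
    if excluded:
        log.warning("%d subject(s) exceed the motion exclusion rule: %s",
                    len(excluded), excluded)

    groups = cohort.groups()
    covariates = phenotypes[["age", "gender", "education"]]
    motion_qa = motion_group_comparison(mean_drms, groups)

    # seed discovery from the ReHo group difference
    reho_stat = group_glm(reho_smoothed, groups, covariates, gm_logit, brain)
    if config.extent_source == "alphasim":
        sim_group = estimate_extent_threshold(
            brain, config.fwhm_mm, atlas.voxel_size_mm, config.group_voxel_p,
            config.group_cluster_alpha, n_iter=config.clustersim_iterations,
            seed=config.seed + 1, connectivity=config.connectivity)
        sim_behavior = estimate_extent_threshold(
            brain, config.fwhm_mm, atlas.voxel_size_mm, config.behavior_voxel_p,
            config.behavior_cluster_alpha, n_iter=config.clustersim_iterations,
            seed=config.seed + 2, connectivity=config.connectivity)
        group_extent = sim_group.extent_threshold_voxels
        behavior_extent = sim_behavior.extent_threshold_voxels
        clustersim_summary = {"group": sim_group.to_dict(),
                              "behavior": sim_behavior.to_dict()}
    else:
        group_extent = config.group_min_extent_voxels
        behavior_extent = config.behavior_min_extent_voxels
        clustersim_summary = {"group": None, "behavior": None}

    if config.seed_source == "atlas":
        seeds = [SeedROI(name, atlas.regions[name], source="atlas")
                 for name in SEED_REGIONS]
    else:
        seeds = select_seeds(reho_stat, t_critical(config.group_voxel_p, reho_stat.df),
                             group_extent, atlas)
        # keep at most one seed per planted seed region (the discovery can
        # also flag target regions; seeds are the two canonical networks)
        by_name = {s.name: s for s in seeds if s.name in SEED_REGIONS}
        seeds = list(by_name.values())
        if not seeds:
            log.warning("no ReHo-derived seeds survive; falling back to atlas seeds")
            seeds = [SeedROI(name, atlas.regions[name], source="atlas")
                     for name in SEED_REGIONS]
    reho_table = cluster_table(reho_stat, config.group_voxel_p, group_extent,
                               atlas, network="ReHo",
                               connectivity=config.connectivity)
    toc("reho")

    # ----- preprocessing pass 2: connectivity ---------------------------
    tic("connectivity")
    cached = _cache_load(outdir, "fc_maps", cfg_hash, force)
    if cached is not None and all(f"fc_{s.name}" in cached for s in seeds):
        fc_maps = {s.name: list(cached[f"fc_{s.name}"]) for s in seeds}
        n_scrubbed = cached["n_scrubbed"]
    else:
        fc_maps = {s.name: [] for s in seeds}
        for i in range(n):
            sid = cohort.subjects[i].subject_id
            try:
                pp, motion = preprocess_series(
                    cohort.bold(i), cohort.motions[i], nuisance_masks,
                    n_discard=config.n_discard,
                    band_hz=(config.band_low_hz, config.band_high_hz),
                    global_signal=config.global_signal)
                smoothed = smooth_series(pp, config.fwhm_mm)
                scrubbed, report = scrub(smoothed, framewise_drms(motion),
                                         config.drms_threshold_mm)
                n_scrubbed[i] = report.flagged_volumes.size
                for s in seeds:
                    fc_maps[s.name].append(fc_map_z(scrubbed, s, subject_id=sid).values)
            except Exception as exc:  # noqa: BLE001
                raise StageError("connectivity", str(exc), sid) from exc
        _cache_save(outdir, "fc_maps", cfg_hash, n_scrubbed=n_scrubbed,
                    **{f"fc_{name}": np.stack(maps)
                       for name, maps in fc_maps.items()})
    toc("connectivity")

    # ----- group statistics ---------------------------------------------
    tic("stats")
    group_tables = {}
    positive_masks = {}
    group_stats = {}
    for s in seeds:
        maps = fc_maps[s.name]
        pos = np.zeros(atlas.grid_shape, dtype=bool)
        for g in ("patient", "control"):
            sub = [m for m, gg in zip(maps, groups) if gg == g]
            stat1, sig = one_sample_map(sub, brain, config.one_sample_alpha_fwe)
            if config.one_sample_correction == "cluster":
                # extent-corrected network map (positive t only)
                sig = significant_set(stat1, config.one_sample_voxel_p,
                                      group_extent,
                                      connectivity=config.connectivity)
                sig &= stat1.values > 0
            pos |= sig
        positive_masks[s.name] = pos
        stat = group_glm(maps, groups, covariates, gm_logit,
                         pos if pos.any() else brain)
        group_stats[s.name] = stat
        group_tables[s.name] = cluster_table(
            stat, config.group_voxel_p, group_extent, atlas,
            network=s.name, connectivity=config.connectivity)
    toc("stats")

    # ----- behavior regressions, conjunction, mediation ------------------
    tic("mediation")
    patients = groups == "patient"
    pheno_pat = phenotypes.loc[patients]
    cov_pat = pheno_pat[["age", "gender", "education"]]
    behavior_summary = {}
    conjunction_tables = {}
    mediation_summary = None
    # 5 fixed design columns + the voxelwise GM column need headroom
    if patients.sum() < 10:
        log.warning("only %d patients: behavior regressions and mediation "
                    "skipped (need >= 10)", int(patients.sum()))
        seeds_for_behavior = []
    else:
        seeds_for_behavior = seeds
    for s in seeds_for_behavior:
        maps_pat = [m for m, is_p in zip(fc_maps[s.name], patients) if is_p]
        gm_pat = [m for m, is_p in zip(gm_logit, patients) if is_p]
        analysis_mask = positive_masks[s.name]
        if not analysis_mask.any():
            analysis_mask = brain
        sig_sets, score_stats = {}, {}
        for score in ("EM", "EF"):
            stat = behavior_regression(maps_pat, pheno_pat[score].to_numpy(),
                                       cov_pat, analysis_mask, gm_maps=gm_pat)
            score_stats[score] = stat
            sig_sets[score] = significant_set(stat, config.behavior_voxel_p,
                                              behavior_extent,
                                              connectivity=config.connectivity)
            behavior_summary[f"{s.name}_{score}_sig_voxels"] = int(sig_sets[score].sum())
        overlap = conjunction(sig_sets["EM"], sig_sets["EF"])
        conj_table = cluster_table_from_set(
            overlap, atlas, stat_values=score_stats["EM"].values,
            network=s.name, connectivity=config.connectivity)
        conjunction_tables[s.name] = conj_table
        behavior_summary[f"{s.name}_conjunction_voxels"] = int(overlap.sum())

        if s.name == "seed_DLPFC" and overlap.any():
            strengths = extract_mediator(maps_pat, overlap)
            partials = {
                score: dict(zip(("r", "p"), partial_correlation(
                    strengths, pheno_pat[score].to_numpy(),
                    cov_pat.to_numpy())))
                for score in ("EM", "EF")
            }
            med = fit_mediation(
                pheno_pat["EF"].to_numpy(), strengths,
                pheno_pat["EM"].to_numpy(), alpha=config.mediation_alpha,
                covariates=cov_pat.to_numpy() if config.mediation_covariates else None)
            mediation_summary = {"result": med.to_dict(),
                                 "partial_correlations": partials,
                                 "mediator_cluster_voxels": int(overlap.sum())}
            log.info("\n%s", med.report())
    toc("mediation")

    summary = {
        "config_hash": cfg_hash,
        "n_patient": int(patients.sum()),
        "n_control": int((~patients).sum()),
        "excluded_subjects": sorted(excluded),
        "motion_qa": motion_qa,
        "mean_scrubbed_volumes": float(np.mean(n_scrubbed)),
        "group_composites": _table_records(group_summary(phenotypes)),
        "em_ef_correlation_pooled": float(
            np.corrcoef(phenotypes["EM"], phenotypes["EF"])[0, 1]),
        "seeds": [{"name": s.name, "source": s.source, "voxels": s.size}
                  for s in seeds],
        "reho_difference_clusters": _table_records(reho_table),
        "extent_thresholds": {"group": int(group_extent),
                              "behavior": int(behavior_extent),
                              "source": config.extent_source},
        "clustersim": clustersim_summary,
        "group_difference_clusters": {
            name: _table_records(tab) for name, tab in group_tables.items()},
        "behavior": behavior_summary,
        "conjunction_clusters": {
            name: _table_records(tab) for name, tab in conjunction_tables.items()},
        "mediation": mediation_summary,
    }
    summary = _round_floats(summary)
    rio.save_json(outdir / "summary.json", summary)
    log.info("wrote %s", outdir / "summary.json")
    return summary
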