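"""End-to-end pipeline orchestration on synthetic or provided data.

Stages, in order: cohort + task-design + BOLD synthesis (or data loading)
-> per-participant first-level FIR GLM with AR pre-whitening -> nine
second-level maps -> voxelwise + cluster-extent thresholding (permutation
or Monte Carlo calibrated) -> cluster report with timecourse QA ->
region-by-contrast correlation-pattern analysis with the stratified split
test.  Every product carries a run manifest (version, config hash, seeds).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .design import DesignConfig, generate_session_design
from .glm import (
    BUILTIN_CONTRASTS,
    compute_contrast,
    build_design_matrix,
    fit_first_level,
)
from .group import (
    CONTRAST_NAMES,
    GROUP_MODELS,
    cluster_report,
    estimate_smoothness,
    find_clusters,
    fit_group_maps,
    montecarlo_cluster_threshold,
    permutation_cluster_threshold,
    qa_cluster_timecourses,
    threshold_voxelwise,
)
from .patterns import region_contrast_values, split_similarity_test
from .synth import (
    EffectSpec,
    NoiseSpec,
    cohort_to_table,
    generate_atlas_fixture,
    generate_bold_session,
    generate_cohort,
    make_ellipsoid_mask,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults reproduce the published analysis settings.

    FIR length 7, contrast timepoints (3, 4), AR max lag 10, 6 discarded
    lead-in volumes per run, voxelwise two-tailed p < 0.01, 10,000
    pattern-test iterations with cutoffs 0.3/0.7.
    """

    # synthesis
    n_participants: int = 21
    n_high_risk: int = 10
    target_corr: float = 0.78
    grid: tuple[int, int, int] = (20, 20, 12)
    n_regions: int = 26
    voxel_size_mm: float = 3.0
    tr: float = 2.0
    noise: dict = field(default_factory=lambda: asdict(NoiseSpec()))
    effect_amplitude: float = 0.0  # 0 = null cohort
    effect_regions: tuple[int, ...] = (1,)
    arbs_slope: float = 0.0
    bis_slope: float = 0.0
    # design
    design: DesignConfig = field(default_factory=DesignConfig)
    # first level
    n_fir: int = 7
    contrast_timepoints: tuple[int, int] = (3, 4)
    ar_max_lag: int = 10
    n_discard: int = 6
    # thresholding
    voxel_p: float = 0.01
    connectivity: str = "faces"
    calibration: str = "montecarlo"  # "montecarlo" | "permutation" | "none"
    calibration_iterations: int = 200
    alpha: float = 0.05
    # correlation pattern
    pattern_iterations: int = 10_000
    cutoff_low: float = 0.3
    cutoff_high: float = 0.7
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = asdict(self.design)
        # YAML round-trips sequences as lists
        d["noise"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d["noise"].items()
        }
        for k in ("grid", "contrast_timepoints", "effect_regions"):
            d[k] = list(d[k])
        return d


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    timings_s: dict = field(default_factory=dict)

    @classmethod
    def for_config(cls, config: PipelineConfig) -> "RunManifest":
        blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
        return cls(
            version=__version__,
            config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
            seed=config.seed,
        )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic analysis; returns a dict of products.

    Products: cohort table, StatMapSet, threshold info, cluster report with
    QA verdicts, SimilarityResult, behavioral summaries, manifest.  When
    ``out_dir`` is given, tables and JSON summaries are also written there.
    """
    manifest = RunManifest.for_config(config)
    t0 = time.time()
    rng = np.random.default_rng(config.seed)

    # --- synthesis -----------------------------------------------------
    cohort = generate_cohort(
        n=config.n_participants,
        n_high=config.n_high_risk,
        target_corr=config.target_corr,
        seed=int(rng.integers(2**31)),
    )
    mask = make_ellipsoid_mask(config.grid)
    atlas, region_table = generate_atlas_fixture(
        config.grid, n_regions=config.n_regions, seed=int(rng.integers(2**31)), mask=mask
    )
    effects = EffectSpec()
    for region in config.effect_regions:
        if config.effect_amplitude:
            effects.amplitudes[region] = {
                "aversive-nogo": 2 * config.effect_amplitude,
                "neutral-nogo": 2 * config.effect_amplitude,
                "aversive-go": config.effect_amplitude,
                "neutral-go": config.effect_amplitude,
            }
        if config.arbs_slope:
            effects.arbs_slopes[region] = {
                "aversive-nogo": config.arbs_slope,
                "aversive-go": config.arbs_slope,
            }
        if config.bis_slope:
            effects.bis_slopes[region] = {
                "aversive-nogo": config.bis_slope,
                "aversive-go": config.bis_slope,
            }
    noise = NoiseSpec(**config.noise)
    coords = np.argwhere(mask)
    slice_of_voxel = coords[:, 2].astype(int)

    sessions = []
    datasets = []
    designs = []
    for p in cohort:
        s = generate_bold_session(
            p,
            design=generate_session_design(config.design, seed=int(rng.integers(2**31))),
            effects=effects,
            noise=noise,
            grid=config.grid,
            atlas=atlas,
            mask=mask,
            tr=config.tr,
            n_discard=config.n_discard,
            voxel_size_mm=config.voxel_size_mm,
            seed=int(rng.integers(2**31)),
        )
        sessions.append(s)
        designs.append(s.design)
        n_per_run = s.volumes_per_run
        keep = np.concatenate(
            [
                np.arange(r * n_per_run + config.n_discard, (r + 1) * n_per_run)
                for r in range(s.n_runs)
            ]
        )
        datasets.append(s.data[mask][:, keep])
    manifest.timings_s["synthesis"] = round(time.time() - t0, 2)

    # --- first level ----------------------------------------------------
    t1 = time.time()
    first_level = []
    resid_volumes = []
    for s, data in zip(sessions, datasets):
        dm = build_design_matrix(s.design, tr=config.tr, n_discard=config.n_discard,
                                 n_fir=config.n_fir)
        fit = fit_first_level(data, dm, slice_of_voxel=slice_of_voxel,
                              max_lag=config.ar_max_lag)
        cms = {}
        for cname in CONTRAST_NAMES:
            cdef = BUILTIN_CONTRASTS[cname]
            if tuple(cdef.timepoints) != tuple(config.contrast_timepoints):
                from dataclasses import replace

                cdef = replace(cdef, timepoints=tuple(config.contrast_timepoints))
            cms[cname] = compute_contrast(fit, cdef)
        first_level.append(cms)
        resid = data - fit.betas @ dm.matrix.T
        vol = np.zeros(config.grid + (3,))
        for j in range(3):  # a few residual volumes for smoothness pooling
            vol[..., j][tuple(coords.T)] = resid[:, j * (resid.shape[1] // 3)]
        resid_volumes.append(vol)
    manifest.timings_s["first_level"] = round(time.time() - t1, 2)

    # --- group maps -----------------------------------------------------
    t2 = time.time()
    arbs = np.array([p.arbs for p in cohort], dtype=float)
    bis = np.array([p.bis for p in cohort], dtype=float)
    stat_maps = fit_group_maps(first_level, arbs, bis)
    manifest.timings_s["group"] = round(time.time() - t2, 2)

    # --- thresholding ---------------------------------------------------
    t3 = time.time()
    smooth = estimate_smoothness(
        np.concatenate(resid_volumes, axis=-1), mask, config.voxel_size_mm
    )
    if config.calibration == "montecarlo":
        extent, _ = montecarlo_cluster_threshold(
            mask,
            fwhm_mm=smooth.fwhm_combined_mm,
            voxel_p=config.voxel_p,
            alpha=config.alpha,
            n_iter=config.calibration_iterations,
            voxel_size_mm=config.voxel_size_mm,
            connectivity=config.connectivity,
            seed=int(rng.integers(2**31)),
        )
    elif config.calibration == "permutation":
        extent, _ = permutation_cluster_threshold(
            datasets,
            designs,
            arbs,
            bis,
            mask_shape=config.grid,
            voxel_coords=coords,
            n_iter=config.calibration_iterations,
            voxel_p=config.voxel_p,
            alpha=config.alpha,
            connectivity=config.connectivity,
            tr=config.tr,
            n_discard=config.n_discard,
            seed=int(rng.integers(2**31)),
        )
    else:
        extent = 1

    clusters_by_map = {}
    reports = {}
    vol = np.zeros(config.grid)
    for key, gm in stat_maps.maps.items():
        binary_flat, critical = threshold_voxelwise(gm.t, config.voxel_p, gm.df)
        vol[...] = 0.0
        vol[tuple(coords.T)] = gm.t * binary_flat
        clusters = [
            c
            for c in find_clusters(vol != 0, config.connectivity, signs=vol)
            if len(c) >= extent
        ]
        # timecourse QA on surviving clusters (first participant's session
        # stands in for the group mean; verdicts recorded per cluster)
        kept = []
        qa = []
        for cl in clusters:
            verdicts = [
                qa_cluster_timecourses(
                    cl, s.data, s.design, mask, tr=config.tr,
                    n_discard=config.n_discard,
                )["verdict"]
                for s in sessions[:3]
            ]
            verdict = max(set(verdicts), key=verdicts.count)
            qa.append(verdict)
            if verdict != "fail":
                kept.append(cl)
        tvol = np.zeros(config.grid)
        tvol[tuple(coords.T)] = gm.t
        rep = cluster_report(kept, tvol, gm.df, voxel_size_mm=config.voxel_size_mm)
        for row, verdict in zip(rep.clusters, qa):
            row["qa_verdict"] = verdict
        clusters_by_map[key] = kept
        reports[key] = rep
    manifest.timings_s["thresholding"] = round(time.time() - t3, 2)

    # --- correlation patterns -------------------------------------------
    t4 = time.time()
    rcv = region_contrast_values(
        first_level,
        atlas,
        mask=mask,
        voxel_coords=coords,
        contrast_names=CONTRAST_NAMES,
        participant_ids=[p.id for p in cohort],
    )
    sim = split_similarity_test(
        rcv,
        arbs,
        bis,
        [p.risk_class for p in cohort],
        n_iter=config.pattern_iterations,
        cutoffs=(config.cutoff_low, config.cutoff_high),
        seed=int(rng.integers(2**31)),
        keep_similarities=False,
    )
    manifest.timings_s["patterns"] = round(time.time() - t4, 2)
    manifest.timings_s["total"] = round(time.time() - t0, 2)

    products = {
        "cohort": cohort_to_table(cohort),
        "region_table": region_table,
        "stat_maps": stat_maps,
        "extent_threshold": extent,
        "smoothness": smooth,
        "cluster_reports": reports,
        "region_contrast_values": rcv,
        "similarity": sim,
        "manifest": manifest,
    }

    if out_dir is not None:
        from . import io as eio

        out = Path(out_dir)
        eio.write_table(products["cohort"], out / "cohort.tsv")
        eio.write_table(region_table, out / "regions.tsv")
        eio.write_table(rcv.to_frame().reset_index(names="participant_id"),
                        out / "region_contrast_values.tsv")
        rows = []
        for (cname, mname), rep in reports.items():
            for r in rep.clusters:
                rows.append({"contrast": cname, "model": mname, **r})
        import pandas as pd

        eio.write_table(pd.DataFrame(rows), out / "clusters.tsv")
        eio.write_json(
            {
                "extent_threshold": extent,
                "smoothness_fwhm_mm": smooth.fwhm_combined_mm,
                "similarity": {
                    "mean": sim.mean,
                    "sd": sim.sd,
                    "prop_below_low": sim.prop_below_low,
                    "prop_above_high": sim.prop_above_high,
                    "n_iter": sim.n_iter,
                },
                # timings omitted: products must be bit-identical across
                # identical (config, seed) runs
                "manifest": {
                    "version": manifest.version,
                    "config_hash": manifest.config_hash,
                    "seed": manifest.seed,
                },
            },
            out / "summary.json",
        )
    return products
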