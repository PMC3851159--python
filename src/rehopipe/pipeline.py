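"""End-to-end orchestration: cohort in, cluster tables out.

``run_pipeline`` reads a cohort directory (volumes + motion traces + mask +
design CSV, the layout :func:`rehopipe.synthetic.write_cohort` produces),
applies motion QC and preprocessing, computes standardized concordance maps
per subject, runs every pairwise group contrast, calibrates the
cluster-extent threshold by Monte-Carlo simulation and writes NIfTI maps,
CSV cluster tables and a JSON manifest. ``analyze_cohort`` is the in-memory
core the disk front-end and the test suite share.

One global seed expands to per-stage seeds through a fixed counter scheme,
so subjects may be processed in any order without changing results.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import (
    ClusterRecord,
    ClusterSimConfig,
    estimate_fwhm,
    extent_threshold,
    label_clusters,
    simulate_null_distribution,
    voxels_to_mm3,
)
from .inference import COVARIATE_NAMES, GroupDesign, StatMap, critical_t, voxelwise_ttest
from .io import (
    BrainMask,
    DesignTable,
    MotionTrace,
    Volume4D,
    read_design,
    read_mask,
    read_motion,
    read_volume4d,
    write_map3d,
)
from .preprocess import PreprocConfig, motion_qc, preprocess_volume, smooth_gaussian
from .reho import ReHoMap, ReHoParams, compute_reho_map, standardize_map

#: offset separating the cluster-simulation seed stream from cohort seeds
_SIM_SEED_OFFSET = 1_000_003


@dataclass
class PipelineConfig:
    cohort_dir: str | Path
    output_dir: str | Path
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    reho: ReHoParams = field(default_factory=ReHoParams)
    standardization: str = "divided_by_mean"
    adjustment_mode: str = "residualize"
    contrasts: list[tuple[str, str]] | None = None  # None -> all pairs
    voxel_p: float = 0.05
    alpha: float = 0.05
    n_iter: int = 1000
    connectivity: int = 26
    sim_fwhm: tuple[float, float, float] | str = "estimate"
    seed: int = 0


@dataclass
class ContrastResult:
    contrast: tuple[str, str]
    statmap: StatMap
    t_threshold: float
    extent_voxels: int
    extent_mm3: float
    sim_fwhm: tuple[float, float, float]
    clusters: list[ClusterRecord]
    table: pd.DataFrame


@dataclass
class PipelineResult:
    reho_maps: dict[str, ReHoMap]
    contrasts: list[ContrastResult]
    excluded: list[str]
    manifest: dict


def render_cluster_table(records: list[ClusterRecord]) -> pd.DataFrame:
    """Cluster report: sign, size in voxels, signed peak T, world X/Y/Z.

    Positive T marks a concordance increase in the first-listed group;
    increases are listed before decreases, each sorted by descending size.
    """
    ordered = sorted(records, key=lambda r: (r.sign != "increase", -r.size, r.peak_index))
    return pd.DataFrame(
        [
            {
                "sign": r.sign,
                "size_voxels": r.size,
                "size_mm3": round(r.size_mm3, 3),
                "peak_t": round(r.peak_t, 3),
                "x": round(r.peak_world[0], 1),
                "y": round(r.peak_world[1], 1),
                "z": round(r.peak_world[2], 1),
            }
            for r in ordered
        ],
        columns=["sign", "size_voxels", "size_mm3", "peak_t", "x", "y", "z"],
    )


def analyze_cohort(
    volumes: dict[str, Volume4D],
    motions: dict[str, MotionTrace],
    design: DesignTable,
    mask: BrainMask,
    config: PipelineConfig,
) -> PipelineResult:
    """Run QC, preprocessing, ReHo mapping and all group contrasts in memory."""
    qc_results = {}
    excluded = []
    for sid in design.table["id"].astype(str):
        qc = motion_qc(motions[sid], config.preproc)
        qc_results[sid] = qc
        if not qc.passed:
            excluded.append(sid)
    analyzed = [s for s in design.table["id"].astype(str) if s not in excluded]

    groups = design.groups
    for g in groups:
        remaining = [s for s in design.subjects_in(g) if s not in excluded]
        if len(remaining) == 0:
            raise RuntimeError(
                f"all subjects of group {g!r} excluded by motion QC: "
                f"{design.subjects_in(g)}"
            )

    reho_maps: dict[str, ReHoMap] = {}
    for sid in analyzed:
        vol = preprocess_volume(volumes[sid], mask, config.preproc)
        rmap = compute_reho_map(vol, mask, config.reho)
        if config.preproc.smooth_stage == "after_reho":
            smoothed = smooth_gaussian(
                rmap.data, config.preproc.fwhm, mask=mask, affine=mask.affine
            )
            rmap = dataclasses.replace(rmap, data=smoothed)
        reho_maps[sid] = standardize_map(rmap, mask, config.standardization)

    covariates = design.table.set_index(design.table["id"].astype(str))[COVARIATE_NAMES]
    contrasts = config.contrasts or [
        (a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]
    ]

    membership = dict(zip(design.table["id"].astype(str), design.table["group"].astype(str)))
    maps_data = {sid: m.data for sid, m in reho_maps.items()}

    results: list[ContrastResult] = []
    for ci, (g1, g2) in enumerate(contrasts):
        gd = GroupDesign(
            maps=maps_data,
            membership=membership,
            contrast=(g1, g2),
            covariates=covariates,
            adjustment_mode=config.adjustment_mode,
        )
        statmap = voxelwise_ttest(gd, mask)
        t_thr = critical_t(config.voxel_p, statmap.df)

        if config.sim_fwhm == "estimate":
            # smoothness of the maps actually entering the test
            est = np.mean(
                [estimate_fwhm(maps_data[s], mask) for s in gd.group_ids[0] + gd.group_ids[1]],
                axis=0,
            )
            sim_fwhm = tuple(float(x) for x in est)
        else:
            sim_fwhm = tuple(config.sim_fwhm)
        sim = ClusterSimConfig(
            mask=mask,
            fwhm=sim_fwhm,
            voxel_p=config.voxel_p,
            alpha=config.alpha,
            n_iter=config.n_iter,
            connectivity=config.connectivity,
            seed=config.seed + _SIM_SEED_OFFSET + ci,
        )
        dist = simulate_null_distribution(sim)
        extent = extent_threshold(dist)
        clusters = label_clusters(
            statmap, mask, t_thr, connectivity=config.connectivity, extent_threshold=extent
        )
        results.append(
            ContrastResult(
                contrast=(g1, g2),
                statmap=statmap,
                t_threshold=t_thr,
                extent_voxels=extent,
                extent_mm3=voxels_to_mm3(extent, mask.affine),
                sim_fwhm=sim_fwhm,
                clusters=clusters,
                table=render_cluster_table(clusters),
            )
        )

    manifest = {
        "rehopipe_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": config.seed,
        "n_subjects_input": design.n_subjects,
        "n_subjects_analyzed": len(analyzed),
        "excluded_by_motion_qc": {"count": len(excluded), "ids": excluded},
        "groups": {g: len([s for s in analyzed if membership[s] == g]) for g in groups},
        "preproc": dataclasses.asdict(config.preproc),
        "reho": dataclasses.asdict(config.reho),
        "standardization": config.standardization,
        "adjustment_mode": config.adjustment_mode,
        "voxel_p": config.voxel_p,
        "alpha": config.alpha,
        "n_iter": config.n_iter,
        "connectivity": config.connectivity,
        "contrasts": [
            {
                "groups": list(r.contrast),
                "df": r.statmap.df,
                "t_threshold": r.t_threshold,
                "extent_voxels": r.extent_voxels,
                "extent_mm3": r.extent_mm3,
                "sim_fwhm_mm": [round(float(x), 3) for x in r.sim_fwhm],
                "n_clusters": len(r.clusters),
            }
            for r in results
        ],
    }
    return PipelineResult(
        reho_maps=reho_maps, contrasts=results, excluded=excluded, manifest=manifest
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Disk front-end: load the cohort directory, analyze, write outputs."""
    cohort = Path(config.cohort_dir)
    design = read_design(cohort / "design.csv")
    mask = read_mask(cohort / "mask.nii.gz")
    volumes, motions = {}, {}
    for sid in design.table["id"].astype(str):
        volumes[sid] = read_volume4d(cohort / f"{sid}_bold.nii.gz")
        motions[sid] = read_motion(cohort / f"rp_{sid}.txt")

    result = analyze_cohort(volumes, motions, design, mask, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, rmap in result.reho_maps.items():
        write_map3d(rmap.data, rmap.affine, out / f"{sid}_reho.nii.gz")
    for r in result.contrasts:
        tag = f"{r.contrast[0]}_vs_{r.contrast[1]}"
        write_map3d(r.statmap.t, r.statmap.affine, out / f"tmap_{tag}.nii.gz")
        r.table.to_csv(out / f"clusters_{tag}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return result
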