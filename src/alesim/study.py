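"""End-to-end study orchestration: grids -> simulation -> ALE -> evaluation.

A study expands a condition grid into dataset specifications, analyses each
dataset with the three thresholding routes, and aggregates the outcome
records into condition tables (sensitivity, spurious rate, cluster size,
contribution curves).  Per-dataset seeds are derived from the master seed
and the (condition, replicate) position, so results are independent of the
worker count and of scheduling order; completed conditions are checkpointed
and skipped on rerun.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import ale
from .evaluate import OutcomeRecord, Vicinity, aggregate, evaluate_dataset
from .grid import VoxelGrid, load_tpm_mask, make_synthetic_mask
from .params import CountSampler
from .simulate import (
    Condition,
    GroundTruth,
    SimulatedDataset,
    StudyGrid,
    enumerate_grid,
    simulate_dataset,
)

__all__ = [
    "StudyConfig",
    "PRESETS",
    "preset_config",
    "build_grid",
    "build_samplers",
    "analyze_dataset",
    "run_study",
    "derive_minimum_size",
]

METHODS = ("uncorrected", "vfwe", "cfwe")


@dataclass(frozen=True)
class StudyConfig:
    """Everything that determines a study run.

    ``grid_id`` may be one of the named grids ("main", "quantile", "small")
    or "custom", in which case ``sizes`` x ``signal_levels`` defines the
    conditions.  The desk defaults (4 mm grid, 100 Monte-Carlo iterations)
    trade resolution for runtime; the faithful settings are 2 mm / 10000.
    """

    grid_id: str = "custom"
    sizes: tuple[int, ...] = (15, 23, 25)
    signal_levels: tuple[int, ...] = (0,)
    replicates: int = 200
    voxel_size: float = 4.0
    mc_iterations: int = 100
    alpha: float = 0.05
    p_cf: float = 0.001
    bin_width: float = 1e-5
    displacement_sd: float = 2.0
    connectivity: int = 26
    methods: tuple[str, ...] = METHODS
    master_seed: int = 0
    n_jobs: int = 1
    out_dir: Optional[str] = None
    tpm_path: Optional[str] = None
    # sampler calibration; None -> the published VBM database summaries
    subject_anchors: Optional[tuple[int, int, int, int, int]] = None
    subject_mean: Optional[float] = None
    foci_anchors: Optional[tuple[int, int, int, int, int]] = None
    foci_mean: Optional[float] = None

    def __post_init__(self) -> None:
        for p, name in ((self.alpha, "alpha"), (self.p_cf, "p_cf")):
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mc_iterations < 1:
            raise ValueError("mc_iterations must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown thresholding methods {sorted(unknown)}")


PRESETS: dict[str, StudyConfig] = {
    # fast sanity run: three null sizes on the 4 mm synthetic mask
    "desk-null": StudyConfig(grid_id="custom", sizes=(15, 23, 25),
                             signal_levels=(0,), replicates=200,
                             voxel_size=4.0, mc_iterations=100),
    # scaled-down sensitivity sweep
    "desk-main": StudyConfig(grid_id="custom", sizes=(15, 25, 35),
                             signal_levels=(0, 2, 4, 6, 8, 10), replicates=100,
                             voxel_size=4.0, mc_iterations=100),
    # faithful settings (full grids, 2 mm, 10000 iterations) — not desk scale
    "paper-main": StudyConfig(grid_id="main", replicates=500,
                              voxel_size=2.0, mc_iterations=10_000),
    "paper-quantile": StudyConfig(grid_id="quantile", replicates=500,
                                  voxel_size=2.0, mc_iterations=10_000),
}


def preset_config(name: str, **overrides) -> StudyConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def build_grid(config: StudyConfig) -> VoxelGrid:
    """The analysis grid: TPM-derived mask if a volume is given, else the
    synthetic MNI-like ellipsoid mask."""
    if config.tpm_path:
        return load_tpm_mask(config.tpm_path, voxel_size=config.voxel_size)
    return make_synthetic_mask(voxel_size=config.voxel_size)


def build_samplers(config: StudyConfig) -> tuple[CountSampler, CountSampler]:
    """Subject and foci samplers from the study configuration (defaults:
    the published VBM database summaries)."""
    from .params import (
        QuantileAnchors, VBM_FOCI_ANCHORS, VBM_FOCI_MEAN,
        VBM_SUBJECT_ANCHORS, VBM_SUBJECT_MEAN, make_count_sampler,
    )
    subj_anchors = (QuantileAnchors(*config.subject_anchors)
                    if config.subject_anchors else VBM_SUBJECT_ANCHORS)
    foci_anchors = (QuantileAnchors(*config.foci_anchors)
                    if config.foci_anchors else VBM_FOCI_ANCHORS)
    subj_mean = config.subject_mean if config.subject_mean is not None else (
        VBM_SUBJECT_MEAN if config.subject_anchors is None else None)
    foci_mean = config.foci_mean if config.foci_mean is not None else (
        VBM_FOCI_MEAN if config.foci_anchors is None else None)
    return (make_count_sampler(subj_anchors, subj_mean),
            make_count_sampler(foci_anchors, foci_mean))


def _conditions(config: StudyConfig) -> list[Condition]:
    if config.grid_id == "custom":
        return [
            Condition(n_total, n_signal, config.replicates)
            for n_total in config.sizes
            for n_signal in config.signal_levels
        ]
    return enumerate_grid(config.grid_id, config.replicates).conditions


def dataset_seed(master_seed: int, cond_index: int, replicate: int) -> list[int]:
    """Schedule-independent per-dataset seed material."""
    return [int(master_seed), int(cond_index), int(replicate)]


def analyze_dataset(
    dataset: SimulatedDataset,
    grid: VoxelGrid,
    spec: ale.KernelSpec = ale.KernelSpec(),
    *,
    mc_iterations: int = 100,
    alpha: float = 0.05,
    p_cf: float = 0.001,
    bin_width: float = 1e-5,
    connectivity: int = 26,
    methods: Sequence[str] = METHODS,
    vicinity: Optional[Vicinity] = None,
    rng: Optional[np.random.Generator] = None,
    return_maps: bool = False,
):
    """Full ALE analysis of one dataset.

    Computes the MA maps and ALE map, the analytic voxel null, the
    Monte-Carlo max-statistic null (shared by vFWE and cFWE), applies the
    requested thresholding methods and scores the outcome measures.

    Returns ``(records, clusters)`` keyed by method; with ``return_maps``
    also a dict of the intermediate maps and nulls.
    """
    if rng is None:
        rng = np.random.default_rng()
    if vicinity is None:
        vicinity = Vicinity()

    ma_maps = [ale.modeled_activation(e, grid, spec) for e in dataset.experiments]
    ale_map = ale.ale_union(ma_maps)
    vnull = ale.voxel_null(ma_maps, grid, bin_width)
    cutoff = ale.cluster_forming_cutoff(vnull, p_cf)

    need_mc = ("vfwe" in methods) or ("cfwe" in methods)
    null = None
    if need_mc:
        null = ale.max_stat_null(
            dataset, grid, spec, cutoff, mc_iterations, rng, connectivity
        )

    clusters: dict[str, ale.ClusterSet] = {}
    for method in methods:
        if method == "uncorrected":
            clusters[method] = ale.threshold_uncorrected(
                ale_map, vnull, grid, p_cf, connectivity
            )
        elif method == "vfwe":
            clusters[method] = ale.threshold_vfwe(
                ale_map, null, grid, alpha, connectivity
            )
        elif method == "cfwe":
            clusters[method] = ale.threshold_cfwe(
                ale_map, vnull, null, grid, alpha, p_cf, connectivity
            )
    records = evaluate_dataset(dataset, clusters, ma_maps, vicinity, grid)
    if return_maps:
        maps = {"ma_maps": ma_maps, "ale": ale_map, "voxel_null": vnull,
                "cf_cutoff": cutoff, "max_stat_null": null}
        return records, clusters, maps
    return records, clusters


def _run_condition(
    cond_index: int,
    cond: Condition,
    config: StudyConfig,
    grid: VoxelGrid,
    samplers: tuple[CountSampler, CountSampler],
    truth: GroundTruth,
) -> list[OutcomeRecord]:
    subject_sampler, foci_sampler = samplers
    out: list[OutcomeRecord] = []
    for rep in range(cond.replicates):
        seed = dataset_seed(config.master_seed, cond_index, rep)
        rng = np.random.default_rng(seed)
        dataset = simulate_dataset(
            cond.n_total, cond.n_signal, subject_sampler, foci_sampler,
            grid, truth, cond.stratum, seed=rng,
        )
        records, _ = analyze_dataset(
            dataset, grid,
            mc_iterations=config.mc_iterations, alpha=config.alpha,
            p_cf=config.p_cf, bin_width=config.bin_width,
            connectivity=config.connectivity, methods=config.methods,
            rng=rng,
        )
        out.extend(records.values())
    return out


def _checkpoint_path(out_dir: Path, cond: Condition) -> Path:
    return out_dir / "checkpoints" / f"{cond.label()}.pkl"


def run_study(config: StudyConfig) -> dict:
    """Run a full study and return its result tables.

    Returns a dict with ``records`` (flat list of OutcomeRecord), ``table``
    (condition-level aggregate) and ``config``.  With ``out_dir`` set, the
    aggregate table, a run manifest, and per-condition checkpoints are
    written; checkpointed conditions are skipped on rerun.
    """
    grid = build_grid(config)
    samplers = build_samplers(config)
    truth = GroundTruth(displacement_sd=config.displacement_sd)
    conditions = _conditions(config)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        (out_dir / "checkpoints").mkdir(parents=True, exist_ok=True)

    todo: list[tuple[int, Condition]] = []
    done: dict[int, list[OutcomeRecord]] = {}
    for i, cond in enumerate(conditions):
        ckpt = _checkpoint_path(out_dir, cond) if out_dir else None
        if ckpt and ckpt.exists():
            done[i] = pickle.loads(ckpt.read_bytes())
        else:
            todo.append((i, cond))

    results = Parallel(n_jobs=config.n_jobs)(
        delayed(_run_condition)(i, cond, config, grid, samplers, truth)
        for i, cond in todo
    )
    for (i, cond), recs in zip(todo, results):
        done[i] = recs
        if out_dir:
            _checkpoint_path(out_dir, cond).write_bytes(pickle.dumps(recs))

    records = [r for i in sorted(done) for r in done[i]]
    table = aggregate(records)
    if out_dir:
        table.to_csv(out_dir / "condition_table.tsv", sep="\t", index=False)
        manifest = asdict(config)
        manifest["n_conditions"] = len(conditions)
        manifest["n_mask_voxels"] = grid.n_mask
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"records": records, "table": table, "config": config}


def derive_minimum_size(
    f1_by_size: dict[int, float], criterion: float = 0.50
) -> Optional[int]:
    """Smallest dataset size whose mean dominant contribution is below the
    criterion; None if the curve never dips below it."""
    if not f1_by_size:
        raise ValueError("empty contribution curve")
    for size in sorted(f1_by_size):
        if f1_by_size[size] < criterion:
            return size
    return None
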