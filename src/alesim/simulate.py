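"""Simulated experiments and datasets with an injected ground-truth effect.

Each simulated experiment draws its subject count and its foci count
independently from the database-calibrated samplers, then places that many
foci uniformly in the gray-matter mask.  In "signal" experiments the first
focus is replaced by the ground-truth location, jittered by an isotropic
Gaussian displacement and snapped back onto the mask, which models the
spatial scatter of a real converging effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .grid import OutOfGridError, VoxelGrid, sample_uniform_foci
from .params import CountSampler, StratumSpec, all_strata, stratum_range

#: MNI-mm ground-truth coordinate in the left primary motor cortex.
TRUE_LOCATION = (-30.0, -26.0, 58.0)

#: Default per-axis SD (mm) of the ground-truth displacement: half the 4 mm
#: detection half-width, i.e. "slight" relative to the vicinity box.
DEFAULT_DISPLACEMENT_SD = 2.0


@dataclass(frozen=True)
class GroundTruth:
    """True-effect location and the scale of its per-experiment displacement."""

    location: tuple[float, float, float] = TRUE_LOCATION
    displacement_sd: float = DEFAULT_DISPLACEMENT_SD

    def __post_init__(self) -> None:
        if self.displacement_sd < 0:
            raise ValueError("displacement scale must be >= 0")


@dataclass
class Experiment:
    """One simulated study: subject count, reported foci (mm), signal flag."""

    id: int
    n_subjects: int
    foci: np.ndarray  # (k, 3) world mm, k >= 1
    is_signal: bool = False

    def __post_init__(self) -> None:
        self.foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if self.foci.shape[0] < 1 or self.foci.shape[1] != 3:
            raise ValueError("an experiment needs at least one (x, y, z) focus")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def n_foci(self) -> int:
        return int(self.foci.shape[0])


@dataclass
class SimulatedDataset:
    """A set of experiments plus the condition labels that produced it."""

    experiments: list[Experiment]
    n_total: int
    n_signal: int
    stratum: Optional[StratumSpec] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_signal > self.n_total:
            raise ValueError("n_signal cannot exceed n_total")
        if len(self.experiments) != self.n_total:
            raise ValueError("experiment list length must equal n_total")
        if sum(e.is_signal for e in self.experiments) != self.n_signal:
            raise ValueError("signal flags inconsistent with n_signal")

    def structure(self) -> list[tuple[int, int]]:
        """Per-experiment (n_subjects, n_foci), the sufficient statistic for nulls."""
        return [(e.n_subjects, e.n_foci) for e in self.experiments]


def displaced_true_focus(
    truth: GroundTruth, grid: VoxelGrid, rng: np.random.Generator
) -> np.ndarray:
    """Ground-truth location plus isotropic Gaussian jitter, snapped to the mask.

    The offset is resampled (up to 100 times) if the snapped voxel leaves the
    mask; with a zero displacement scale the exact location is returned,
    snapped to its voxel center.
    """
    loc = np.asarray(truth.location, dtype=float)
    for _ in range(100):
        cand = loc + rng.normal(0.0, truth.displacement_sd, size=3)
        try:
            idx = grid.world_to_voxel(cand)
        except OutOfGridError:
            continue
        if grid.mask[idx]:
            return grid.voxel_to_world(idx)
    # pathological mask/scale combination: fall back to the truth voxel
    idx = grid.world_to_voxel(loc)
    return grid.voxel_to_world(idx)


def simulate_experiment(
    subject_sampler: CountSampler,
    foci_sampler: CountSampler,
    grid: VoxelGrid,
    signal: bool,
    truth: GroundTruth,
    rng: np.random.Generator,
    exp_id: int = 0,
) -> Experiment:
    """Draw one experiment: counts, uniform foci, optional true-effect focus."""
    n_subjects = int(subject_sampler.sample(1, rng)[0])
    k = int(foci_sampler.sample(1, rng)[0])
    foci = sample_uniform_foci(grid, k, rng)
    if signal:
        foci[0] = displaced_true_focus(truth, grid, rng)
    return Experiment(id=exp_id, n_subjects=n_subjects, foci=foci, is_signal=signal)


def simulate_dataset(
    n_total: int,
    n_signal: int,
    subject_sampler: CountSampler,
    foci_sampler: CountSampler,
    grid: VoxelGrid,
    truth: GroundTruth = GroundTruth(),
    stratum: Optional[StratumSpec] = None,
    seed: Union[int, Sequence[int], np.random.Generator, None] = None,
) -> SimulatedDataset:
    """Simulate a dataset of ``n_total`` experiments, the first ``n_signal``
    of which carry the true effect (labels are exchangeable).

    With a ``stratum`` given, both samplers are restricted to the stratum's
    quartile range before drawing.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_signal <= n_total):
        raise ValueError(f"n_signal={n_signal} must lie in [0, n_total={n_total}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if stratum is not None:
        subject_sampler = subject_sampler.restrict(
            *stratum_range("subjects", stratum.subjects, subject_sampler.anchors)
        )
        foci_sampler = foci_sampler.restrict(
            *stratum_range("foci", stratum.foci, foci_sampler.anchors)
        )

    experiments = [
        simulate_experiment(
            subject_sampler, foci_sampler, grid, i < n_signal, truth, rng, exp_id=i
        )
        for i in range(n_total)
    ]
    seed_label = seed if isinstance(seed, (int, np.integer)) else None
    return SimulatedDataset(
        experiments=experiments,
        n_total=n_total,
        n_signal=n_signal,
        stratum=stratum,
        seed=seed_label,
    )


@dataclass(frozen=True)
class Condition:
    """One cell of a study grid."""

    n_total: int
    n_signal: int
    replicates: int
    stratum: Optional[StratumSpec] = None

    def label(self) -> str:
        s = f"N{self.n_total}_k{self.n_signal}"
        if self.stratum is not None:
            s += f"_{self.stratum.label()}"
        return s


@dataclass
class StudyGrid:
    """Enumerated list of study conditions."""

    grid_id: str
    conditions: list[Condition]

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def n_datasets(self) -> int:
        return sum(c.replicates for c in self.conditions)


def enumerate_grid(grid_id: str, replicates: int = 500) -> StudyGrid:
    """The study's condition grids.

    * ``main``: dataset sizes 15..45 crossed with 0..10 true-effect
      experiments (341 conditions).
    * ``quantile``: 16 subject-by-foci quartile strata at sizes 5..30,
      null datasets only (the homogeneity study targets spurious clusters).
    * ``small``: sizes 5..15, null datasets only (small-dataset addendum).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conditions: list[Condition] = []
    if grid_id == "main":
        for n_total in range(15, 46):
            for n_signal in range(0, 11):
                conditions.append(Condition(n_total, n_signal, replicates))
    elif grid_id == "quantile":
        for stratum in all_strata():
            for n_total in range(5, 31):
                conditions.append(Condition(n_total, 0, replicates, stratum))
    elif grid_id == "small":
        for n_total in range(5, 16):
            conditions.append(Condition(n_total, 0, replicates))
    else:
        raise ValueError(f"unknown grid id {grid_id!r}")
    return StudyGrid(grid_id=grid_id, conditions=conditions)


# --- text round trip ---------------------------------------------------------

_COLUMNS = ["experiment", "n_subjects", "x", "y", "z", "signal"]


def dataset_to_table(dataset: SimulatedDataset) -> pd.DataFrame:
    """Long-format foci table: one row per focus."""
    rows = []
    for e in dataset.experiments:
        for x, y, z in e.foci:
            rows.append((e.id, e.n_subjects, x, y, z, int(e.is_signal)))
    return pd.DataFrame(rows, columns=_COLUMNS)


def save_dataset(dataset: SimulatedDataset, path: Union[str, Path]) -> None:
    """Write a dataset as a tab-separated foci table plus a JSON sidecar."""
    path = Path(path)
    dataset_to_table(dataset).to_csv(path, sep="\t", index=False)
    manifest = {
        "n_total": dataset.n_total,
        "n_signal": dataset.n_signal,
        "stratum": None if dataset.stratum is None else
            {"subjects": dataset.stratum.subjects, "foci": dataset.stratum.foci},
        "seed": dataset.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))


def load_dataset(path: Union[str, Path]) -> SimulatedDataset:
    """Inverse of :func:`save_dataset` (lossless round trip)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    experiments = []
    for eid, g in table.groupby("experiment", sort=True):
        experiments.append(
            Experiment(
                id=int(eid),
                n_subjects=int(g["n_subjects"].iloc[0]),
                foci=g[["x", "y", "z"]].to_numpy(dtype=float),
                is_signal=bool(g["signal"].iloc[0]),
            )
        )
    stratum = manifest.get("stratum")
    return SimulatedDataset(
        experiments=experiments,
        n_total=int(manifest["n_total"]),
        n_signal=int(manifest["n_signal"]),
        stratum=None if stratum is None else StratumSpec(**stratum),
        seed=manifest.get("seed"),
    )
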