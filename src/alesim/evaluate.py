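"""Outcome measures: detection, spurious convergence, contribution profiles.

Three quantities summarise a thresholded analysis of a simulated dataset:

* sensitivity — was any significant cluster found in the close vicinity
  (a +/-4 mm axis-aligned box, i.e. 2 voxels at 2 mm) of the ground truth;
* spurious convergence — significant clusters outside that vicinity, which
  under the simulation can only arise from incidental convergence;
* contribution — per spurious cluster, the fraction f_k of the ALE value
  attributable to the k most dominant experiments, obtained per voxel by
  sorting the MA values in decreasing order, complementing, cumulative
  multiplication, and dividing by the voxel's ALE; then averaged over the
  cluster's voxels.  f_k is non-decreasing and f_K = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ale import Cluster, ClusterSet
from .grid import VoxelGrid
from .simulate import TRUE_LOCATION, SimulatedDataset

__all__ = [
    "Vicinity",
    "classify_clusters",
    "contribution_profile",
    "OutcomeRecord",
    "evaluate_dataset",
    "aggregate",
]


@dataclass(frozen=True)
class Vicinity:
    """Detection region around the ground truth.

    Default: axis-aligned box, +/-4 mm in each direction.  ``shape="ball"``
    switches to a Euclidean ball of that radius (non-default).
    """

    center: tuple[float, float, float] = TRUE_LOCATION
    half_width: float = 4.0
    shape: str = "box"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half-width must be positive")
        if self.shape not in ("box", "ball"):
            raise ValueError("shape must be 'box' or 'ball'")

    def contains(self, world: np.ndarray) -> np.ndarray:
        """Boolean per row of an (n, 3) world-mm array."""
        d = np.atleast_2d(world) - np.asarray(self.center)
        if self.shape == "box":
            return np.all(np.abs(d) <= self.half_width + 1e-9, axis=1)
        return np.sum(d**2, axis=1) <= self.half_width**2 + 1e-9


def classify_clusters(
    clusters: ClusterSet, vicinity: Vicinity, grid: VoxelGrid
) -> tuple[list[Cluster], list[Cluster]]:
    """Split clusters into (true, spurious).

    A cluster is "true" iff any member voxel lies within the vicinity.
    """
    true_cl, spurious = [], []
    for c in clusters:
        world = grid.voxels_to_world(c.indices)
        (true_cl if vicinity.contains(world).any() else spurious).append(c)
    return true_cl, spurious


def contribution_profile(
    cluster: Cluster, ma_maps: Sequence[np.ndarray]
) -> np.ndarray:
    """Per-k dominant-experiment contribution fractions of a cluster.

    Per voxel the K MA values are sorted in decreasing order, complemented,
    and cumulatively multiplied; f_k(v) = (1 - prod_{i<=k}(1 - MA_(i)(v)))
    / ALE(v).  The returned vector (length K) averages f_k over the
    cluster's voxels.  Requires ALE > 0 on every cluster voxel (always the
    case for suprathreshold voxels).
    """
    if cluster.size < 1:
        raise ValueError("cluster is empty")
    coords = tuple(cluster.indices.T)
    vals = np.stack([ma[coords] for ma in ma_maps])  # (K, m)
    vals = -np.sort(-vals, axis=0)  # decreasing per voxel
    comp = np.cumprod(1.0 - vals, axis=0)
    ale = 1.0 - comp[-1]
    if np.any(ale <= 0):
        raise ValueError("ALE value is zero on a cluster voxel")
    f = (1.0 - comp) / ale
    return f.mean(axis=1)


@dataclass
class OutcomeRecord:
    """Per-dataset, per-method outcome summary."""

    condition: dict
    method: str
    detected: bool
    true_cluster_size: int
    n_spurious: int
    spurious_profiles: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.detected and self.true_cluster_size < 1:
            raise ValueError("a detected dataset must have a true cluster")


def evaluate_dataset(
    dataset: SimulatedDataset,
    clusters_by_method: dict[str, ClusterSet],
    ma_maps: Sequence[np.ndarray],
    vicinity: Vicinity,
    grid: VoxelGrid,
) -> dict[str, OutcomeRecord]:
    """All three outcome measures for each thresholding method.

    ``true_cluster_size`` is the largest true cluster (0 if none); every
    spurious cluster gets a contribution profile from the same MA maps, so
    the methods differ only through cluster selection.
    """
    condition = {
        "n_total": dataset.n_total,
        "n_signal": dataset.n_signal,
        "stratum": None if dataset.stratum is None else dataset.stratum.label(),
    }
    records = {}
    for method, clusters in clusters_by_method.items():
        true_cl, spurious = classify_clusters(clusters, vicinity, grid)
        profiles = [contribution_profile(c, ma_maps) for c in spurious]
        records[method] = OutcomeRecord(
            condition=condition,
            method=method,
            detected=bool(true_cl),
            true_cluster_size=max((c.size for c in true_cl), default=0),
            n_spurious=len(spurious),
            spurious_profiles=profiles,
        )
    return records


def _profile_stat(profiles: list[np.ndarray], k: int) -> float:
    vals = [p[k - 1] for p in profiles if len(p) >= k]
    return float(np.mean(vals)) if vals else float("nan")


def aggregate(
    records: Iterable[OutcomeRecord],
    by: Sequence[str] = ("n_total", "n_signal", "stratum", "method"),
    per_dataset: bool = False,
) -> pd.DataFrame:
    """Condition-level table of the outcome measures.

    Per condition and method: sensitivity (fraction detected), spurious rate
    (fraction of datasets with >= 1 spurious cluster), mean true-cluster size
    over detected datasets, and mean f1/f2 over spurious clusters with a
    normal-approximation 95% half-width.  Contribution means pool all
    spurious clusters in the condition (cluster-weighted); ``per_dataset``
    averages within dataset first.
    """
    rows: dict[tuple, dict] = {}
    for r in records:
        key_parts = []
        for b in by:
            key_parts.append(r.method if b == "method" else r.condition.get(b))
        key = tuple(key_parts)
        g = rows.setdefault(
            key,
            {"n": 0, "detected": 0, "with_spurious": 0, "true_sizes": [],
             "f1": [], "f2": [], "n_clusters": 0},
        )
        g["n"] += 1
        g["detected"] += int(r.detected)
        g["with_spurious"] += int(r.n_spurious > 0)
        if r.detected:
            g["true_sizes"].append(r.true_cluster_size)
        profs = r.spurious_profiles
        g["n_clusters"] += len(profs)
        if per_dataset and profs:
            g["f1"].append(_profile_stat(profs, 1))
            g["f2"].append(_profile_stat(profs, 2))
        else:
            g["f1"].extend(p[0] for p in profs)
            g["f2"].extend(p[1] for p in profs if len(p) >= 2)

    out = []
    for key, g in rows.items():
        n = g["n"]
        f1 = np.asarray(g["f1"], dtype=float)
        f2 = np.asarray(g["f2"], dtype=float)
        row = dict(zip(by, key))
        row.update(
            n_datasets=n,
            sensitivity=g["detected"] / n,
            spurious_rate=g["with_spurious"] / n,
            mean_true_size=float(np.mean(g["true_sizes"])) if g["true_sizes"] else np.nan,
            n_spurious_clusters=g["n_clusters"],
            mean_f1=f1.mean() if len(f1) else np.nan,
            mean_f2=f2.mean() if len(f2) else np.nan,
            f1_ci=1.96 * f1.std(ddof=1) / np.sqrt(len(f1)) if len(f1) > 1 else np.nan,
            f2_ci=1.96 * f2.std(ddof=1) / np.sqrt(len(f2)) if len(f2) > 1 else np.nan,
        )
        out.append(row)
    df = pd.DataFrame(out)
    return df.sort_values(list(by)).reset_index(drop=True) if len(df) else df
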