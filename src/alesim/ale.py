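"""Activation likelihood estimation: MA maps, ALE union, nulls, thresholding.

The ALE statistic measures spatial convergence of reported coordinates
across experiments.  Each experiment contributes a modeled-activation (MA)
map: a 3-D Gaussian kernel at every reported focus, combined across the
experiment's foci by voxelwise maximum.  The kernel width shrinks with the
experiment's sample size, reflecting lower spatial uncertainty of larger
studies.  The ALE map is the voxelwise union of the MA maps,

    ALE(v) = 1 - prod_i (1 - MA_i(v)),

i.e. the probability that at least one experiment "activates" the voxel
under independence.

Inference offers three routes, all against a null of spatial independence
(every experiment's foci relocated uniformly within the mask):

* uncorrected: voxels above the analytic voxel-null cutoff at p;
* vFWE: voxels above the Monte-Carlo max-ALE null quantile at alpha;
* cFWE: suprathreshold clusters (cluster-forming p) larger than the
  Monte-Carlo max-cluster-size null quantile at alpha.

The analytic voxel null is obtained by convolving the per-experiment MA
histograms in -log(1 - MA) space, where the union formula becomes a sum of
independent terms; this is exactly the histogram-combination construction of
the reference ALE implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from .grid import VoxelGrid
from .simulate import Experiment, SimulatedDataset

__all__ = [
    "KernelSpec",
    "kernel_sd",
    "modeled_activation",
    "ale_union",
    "VoxelNull",
    "voxel_null",
    "cluster_forming_cutoff",
    "MaxStatNull",
    "max_stat_null",
    "Cluster",
    "ClusterSet",
    "label_clusters",
    "threshold_vfwe",
    "threshold_cfwe",
    "threshold_uncorrected",
]

# MAD->SD conversion of the empirical localisation-uncertainty constants:
# a 1-D Gaussian has E|X| = sigma * sqrt(2/pi), so sigma = c / (2*sqrt(2/pi))
# when c is a full-width mean-displacement constant.
_MAD_TO_SD = 2.0 * math.sqrt(2.0 / math.pi)
_FWHM_TO_SD = math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class KernelSpec:
    """Two-component spatial-uncertainty model of the ALE kernel.

    ``subject_mm`` is the between-subject localisation uncertainty constant
    (scaled by 1/sqrt(n)); ``template_mm`` the between-template constant.
    ``truncate_sd`` bounds the kernel support (values beyond are exactly 0;
    at 5 SD the truncated mass is < 1e-6).
    """

    subject_mm: float = 11.6
    template_mm: float = 5.7
    truncate_sd: float = 5.0


def kernel_sd(spec: KernelSpec, n_subjects: int) -> float:
    """Combined Gaussian SD in mm for an experiment of ``n_subjects``.

    sigma = sqrt(template^2 + subject^2 / n) / (2*sqrt(2/pi)); strictly
    decreasing in n, approaching the template-only limit as n -> inf.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return math.sqrt(spec.template_mm**2 + spec.subject_mm**2 / n_subjects) / _MAD_TO_SD


@lru_cache(maxsize=4096)
def _kernel_array_cached(
    sigma_mm: float, voxel_size: float, truncate_sd: float
) -> np.ndarray:
    """Discrete kernel on voxel centers, normalized to unit total mass."""
    radius = int(math.ceil(truncate_sd * sigma_mm / voxel_size))
    ax = np.arange(-radius, radius + 1) * voxel_size
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    k = np.exp(-d2 / (2.0 * sigma_mm**2))
    k[d2 > (truncate_sd * sigma_mm) ** 2] = 0.0
    k /= k.sum()
    return k


def kernel_array(spec: KernelSpec, n_subjects: int, voxel_size: float) -> np.ndarray:
    return _kernel_array_cached(kernel_sd(spec, n_subjects), voxel_size, spec.truncate_sd)


def kernel_peak(spec: KernelSpec, n_subjects: int, voxel_size: float) -> float:
    """Central MA value of a single-focus experiment."""
    k = kernel_array(spec, n_subjects, voxel_size)
    return float(k.max())


def _paste_max(vol: np.ndarray, kern: np.ndarray, center: Sequence[int]) -> None:
    """In-place voxelwise max of ``kern`` centered at ``center`` into ``vol``."""
    r = (kern.shape[0] - 1) // 2
    c0, c1, c2 = int(center[0]), int(center[1]), int(center[2])
    s0, s1, s2 = vol.shape
    lo0, lo1, lo2 = c0 - r, c1 - r, c2 - r
    hi0, hi1, hi2 = c0 + r + 1, c1 + r + 1, c2 + r + 1
    if lo0 >= 0 and lo1 >= 0 and lo2 >= 0 and hi0 <= s0 and hi1 <= s1 and hi2 <= s2:
        sub = vol[lo0:hi0, lo1:hi1, lo2:hi2]  # interior fast path
        np.maximum(sub, kern, out=sub)
        return
    vlo0, vlo1, vlo2 = max(lo0, 0), max(lo1, 0), max(lo2, 0)
    vhi0, vhi1, vhi2 = min(hi0, s0), min(hi1, s1), min(hi2, s2)
    if vlo0 >= vhi0 or vlo1 >= vhi1 or vlo2 >= vhi2:
        return
    klo0, klo1, klo2 = vlo0 - lo0, vlo1 - lo1, vlo2 - lo2
    sub = vol[vlo0:vhi0, vlo1:vhi1, vlo2:vhi2]
    np.maximum(
        sub,
        kern[klo0:klo0 + vhi0 - vlo0, klo1:klo1 + vhi1 - vlo1, klo2:klo2 + vhi2 - vlo2],
        out=sub,
    )


def modeled_activation(
    experiment: Experiment,
    grid: VoxelGrid,
    spec: KernelSpec = KernelSpec(),
    out: Optional[np.ndarray] = None,
) -> np.ndarray:
    """MA map of one experiment: voxelwise max of its per-focus kernels.

    Values lie in [0, 1) and are exactly zero beyond the truncation radius of
    every focus; voxels outside the mask are zeroed.
    """
    kern = kernel_array(spec, experiment.n_subjects, grid.voxel_size)
    if out is None:
        out = np.zeros(grid.shape)
    else:
        out.fill(0.0)
    for focus in experiment.foci:
        center = grid.world_to_voxel(focus)  # raises off the bounding box
        _paste_max(out, kern, center)
    out *= grid.mask
    return out


def ale_union(ma_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise union 1 - prod(1 - MA_i) of the modeled-activation maps."""
    if len(ma_maps) < 1:
        raise ValueError("need at least one MA map")
    if len(ma_maps) == 1:
        return np.array(ma_maps[0], dtype=float)  # exact identity
    shape = ma_maps[0].shape
    acc = np.ones(shape)
    for ma in ma_maps:
        if ma.shape != shape:
            raise ValueError("MA maps must share a common grid")
        acc *= 1.0 - ma
    return 1.0 - acc


# --- analytic voxel null -----------------------------------------------------


@dataclass
class VoxelNull:
    """Distribution of the ALE score under spatial independence.

    Stored as a histogram over bins uniform in L = -log(1 - ALE) (bin width
    ``bin_width``; bin j is centered at j * bin_width).  In L space the union
    across experiments is a sum of independent per-experiment terms, so the
    null is the convolution of the per-experiment MA histograms.
    """

    probs: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        s = self.probs.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError("null histogram must have total mass 1")
        self.probs = self.probs / s
        self._tail = np.cumsum(self.probs[::-1])[::-1]  # P(bin index >= j)

    def tail(self, ale: float) -> float:
        """P(ALE >= ale) up to bin discretization."""
        if ale <= 0:
            return 1.0
        L = -math.log1p(-ale)
        j = int(math.ceil(L / self.bin_width - 0.5))
        if j >= len(self.probs):
            return 0.0
        return float(self._tail[max(j, 0)])


def _l_histogram(ma_values: np.ndarray, bin_width: float) -> np.ndarray:
    """Probability histogram of -log(1 - MA) over mask voxels."""
    L = -np.log1p(-ma_values)
    idx = np.rint(L / bin_width).astype(np.int64)
    h = np.bincount(idx).astype(float)
    return h / h.sum()


def _trim(p: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Drop trailing bins with cumulative mass below ``eps``, lumping the
    dropped mass into the last kept bin.  Moving mass downward this way keeps
    every tail probability P(index >= j) exact for j up to the trim point,
    which is all the cutoff search ever reads (eps << any usable p)."""
    np.maximum(p, 0.0, out=p)
    tail = np.cumsum(p[::-1])[::-1]
    keep = np.nonzero(tail > eps)[0]
    if not len(keep):
        return p[:1]
    j = int(keep[-1])
    out = p[: j + 1].copy()
    out[j] = tail[j]  # bin j plus everything beyond it
    return out


def voxel_null(
    ma_maps: Sequence[np.ndarray],
    grid: VoxelGrid,
    bin_width: float = 1e-5,
) -> VoxelNull:
    """Analytic ALE null from per-experiment MA histograms over the mask.

    Equivalent to drawing one mask voxel independently per experiment and
    forming the union of the sampled MA values; computed by pairwise-tree
    FFT convolution of the histograms in -log(1 - MA) space.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(ma_maps) < 1:
        raise ValueError("need at least one MA map")
    mask = grid.mask
    hists = [_l_histogram(ma[mask], bin_width) for ma in ma_maps]
    while len(hists) > 1:
        nxt = [
            _trim(fftconvolve(hists[i], hists[i + 1]))
            for i in range(0, len(hists) - 1, 2)
        ]
        if len(hists) % 2:
            nxt.append(hists[-1])
        hists = nxt
    return VoxelNull(probs=hists[0], bin_width=bin_width)


def cluster_forming_cutoff(null: VoxelNull, p: float = 0.001) -> float:
    """Smallest histogram bin edge whose tail probability is <= p.

    Returned on the ALE scale; significance is strict (``ALE > cutoff``).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    tail = null._tail
    j = int(np.searchsorted(-tail, -p, side="left"))  # first tail <= p
    if j == 0:
        return 0.0
    edge_L = (j - 0.5) * null.bin_width
    return float(-np.expm1(-edge_L))


# --- Monte-Carlo max-statistic null ------------------------------------------


@dataclass
class MaxStatNull:
    """Monte-Carlo samples of max ALE and max suprathreshold cluster size."""

    max_ale: np.ndarray
    max_cluster: np.ndarray
    iterations: int
    cf_cutoff: float
    connectivity: int = 26


def _structure_of(dataset) -> list[tuple[int, int]]:
    if isinstance(dataset, SimulatedDataset):
        return dataset.structure()
    return [(int(n), int(k)) for n, k in dataset]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def max_stat_null(
    dataset,
    grid: VoxelGrid,
    spec: KernelSpec,
    cf_cutoff: float,
    iterations: int,
    rng: np.random.Generator,
    connectivity: int = 26,
) -> MaxStatNull:
    """Null distribution of the max statistics under uniform relocation.

    Per iteration every experiment's foci are redrawn uniformly in the mask
    (keeping its subject and foci counts), the ALE map recomputed, and the
    maximum ALE value and the largest connected component above ``cf_cutoff``
    recorded.  Only the dataset *structure* (per-experiment counts) matters.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    struct = _structure_of(dataset)
    # float32 scratch: the null only feeds order statistics, and the ~1e-7
    # relative rounding is far below Monte-Carlo resolution
    kerns = {
        n: kernel_array(spec, n, grid.voxel_size).astype(np.float32)
        for n, _ in struct
    }
    conn = _connectivity_structure(connectivity)
    mask = grid.mask
    idx = grid.mask_indices
    n_mask = grid.n_mask

    max_ale = np.empty(iterations)
    max_cluster = np.zeros(iterations, dtype=np.int64)
    ma = np.zeros(grid.shape, dtype=np.float32)
    acc = np.empty(grid.shape, dtype=np.float32)
    tmp = np.empty(grid.shape, dtype=np.float32)
    notmask = ~mask
    total_foci = sum(k for _, k in struct)
    for it in range(iterations):
        acc.fill(1.0)
        picks = rng.integers(0, n_mask, size=total_foci)
        pos = 0
        for n_subj, n_foci in struct:
            ma.fill(0.0)
            centers = idx[picks[pos:pos + n_foci]].tolist()
            pos += n_foci
            kern = kerns[n_subj]
            for c in centers:
                _paste_max(ma, kern, c)
            np.subtract(1.0, ma, out=tmp)
            acc *= tmp
        ale = np.subtract(1.0, acc, out=tmp)
        ale[notmask] = 0.0
        max_ale[it] = ale.max()
        sup = ale > cf_cutoff
        if sup.any():
            labels, n_lab = ndimage.label(sup, structure=conn)
            if n_lab:
                sizes = np.bincount(labels[sup])
                max_cluster[it] = int(sizes.max())
    return MaxStatNull(
        max_ale=max_ale,
        max_cluster=max_cluster,
        iterations=iterations,
        cf_cutoff=cf_cutoff,
        connectivity=connectivity,
    )


def _mc_threshold(samples: np.ndarray, alpha: float) -> float:
    """Exact Monte-Carlo critical value: the ceil((1-alpha)(N+1))-th order
    statistic of N null samples, so that P(observed > threshold) <= alpha for
    an exchangeable continuous statistic (ties resolved conservatively by the
    strict comparison)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    n = len(samples)
    if n < 1:
        raise ValueError("null distribution is empty")
    k = min(n, int(math.ceil((1.0 - alpha) * (n + 1))))
    return float(np.partition(samples, k - 1)[k - 1])


# --- clusters ----------------------------------------------------------------


@dataclass
class Cluster:
    """Connected set of significant voxels."""

    indices: np.ndarray  # (size, 3) voxel indices
    size: int
    peak_ale: float
    peak_mm: np.ndarray


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i: int) -> Cluster:
        return self.clusters[i]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def to_table(self) -> pd.DataFrame:
        """Cluster table: id, size, peak coordinates (mm), peak ALE."""
        rows = [
            (i, c.size, *np.asarray(c.peak_mm, dtype=float), c.peak_ale)
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "size", "peak_x", "peak_y", "peak_z", "peak_ale"]
        )


def label_clusters(
    significant: np.ndarray,
    ale: np.ndarray,
    grid: VoxelGrid,
    connectivity: int = 26,
) -> ClusterSet:
    """Maximal connected components of a boolean voxel set (default 26-conn)."""
    conn = _connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(significant, structure=conn)
    clusters = []
    for lab in range(1, n_lab + 1):
        members = np.argwhere(labels == lab)
        vals = ale[tuple(members.T)]
        peak = int(np.argmax(vals))
        clusters.append(
            Cluster(
                indices=members,
                size=len(members),
                peak_ale=float(vals[peak]),
                peak_mm=grid.voxel_to_world(members[peak]),
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters)


def threshold_vfwe(
    ale: np.ndarray,
    null: MaxStatNull,
    grid: VoxelGrid,
    alpha: float = 0.05,
    connectivity: int = 26,
) -> ClusterSet:
    """Voxel-level FWE: keep voxels with ALE above the max-ALE null quantile."""
    thr = _mc_threshold(null.max_ale, alpha)
    return label_clusters(ale > thr, ale, grid, connectivity)


def threshold_cfwe(
    ale: np.ndarray,
    vnull: VoxelNull,
    null: MaxStatNull,
    grid: VoxelGrid,
    alpha: float = 0.05,
    p_cf: float = 0.001,
    connectivity: int = 26,
) -> ClusterSet:
    """Cluster-level FWE: suprathreshold components (cluster-forming p)
    kept iff larger than the max-cluster-size null quantile."""
    cutoff = cluster_forming_cutoff(vnull, p_cf)
    comps = label_clusters(ale > cutoff, ale, grid, connectivity)
    size_thr = _mc_threshold(null.max_cluster.astype(float), alpha)
    return ClusterSet([c for c in comps if c.size > size_thr])


def threshold_uncorrected(
    ale: np.ndarray,
    vnull: VoxelNull,
    grid: VoxelGrid,
    p: float = 0.001,
    connectivity: int = 26,
) -> ClusterSet:
    """Uncorrected inference: suprathreshold components, no size filter."""
    cutoff = cluster_forming_cutoff(vnull, p)
    return label_clusters(ale > cutoff, ale, grid, connectivity)
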