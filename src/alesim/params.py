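"""Samplers for experiment-level parameters of simulated VBM meta-analyses.

Coordinate-based meta-analysis simulations need realistic per-experiment
parameters: the number of subjects (which sets the width of the spatial
uncertainty kernel) and the number of reported foci (which sets how much
incidental convergence a dataset can produce).  Without access to the raw
BrainMap VBM records, the samplers here are calibrated to the published
summary statistics of that database:

* subjects: min 2, quartiles 13 / 20 / 32, max 479, mean 30.63 (SD 40.91)
* foci:     min 1, quartiles 2 / 4 / 8,    max 75,  mean 6.54  (SD 7.88)

The sampler is a quantile-anchored piecewise distribution over integers:
uniform within each inter-quartile bin, with a geometric-decay upper tail on
(q75, maximum] whose decay ratio is solved so that the overall expectation
matches the published mean.  The induced standard deviation is reported but
not enforced.  A small, fixed asymmetry of the bin masses (the "quantile
guard") pins the large-sample empirical quartiles exactly onto the printed
anchors; see :data:`QUANTILE_GUARD`.

Quantile-stratified sampling (used for the homogeneous-dataset study)
restricts a sampler's support to one of four quartile strata per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InvalidAnchorsError",
    "InfeasibleCalibrationError",
    "EmptyRequestError",
    "QuantileAnchors",
    "TailCalibration",
    "CountSampler",
    "StratumSpec",
    "make_count_sampler",
    "sample_counts",
    "stratum_range",
    "default_subject_sampler",
    "default_foci_sampler",
    "default_samplers",
    "STRATUM_CATEGORIES",
    "all_strata",
    "VBM_SUBJECT_ANCHORS",
    "VBM_FOCI_ANCHORS",
    "VBM_SUBJECT_MEAN",
    "VBM_SUBJECT_SD",
    "VBM_FOCI_MEAN",
    "VBM_FOCI_SD",
]


class InvalidAnchorsError(ValueError):
    """Quantile anchors are non-monotone or not positive integers."""


class InfeasibleCalibrationError(ValueError):
    """No tail shape can reconcile the anchors with the target mean."""


class EmptyRequestError(ValueError):
    """A draw of zero counts was requested."""


#: Mass shifted from the two upper inter-quantile bins to the two lower ones.
#: With exactly 0.25 mass per bin the CDF hits 0.25/0.50/0.75 *exactly* at the
#: anchors, so the empirical quartiles of a large sample straddle the anchor
#: (e.g. a sample median alternating between 20 and 20.5).  The guard makes
#: P(X <= anchor) strictly exceed the nominal level by a margin large relative
#: to binomial noise at 1e6 draws, so empirical quartiles equal the anchors
#: almost surely.  The mean calibration is solved after the guard is applied.
QUANTILE_GUARD = 0.002


@dataclass(frozen=True)
class QuantileAnchors:
    """Five-number summary anchoring a count distribution.

    Invariants: ``minimum <= q25 <= q50 <= q75 <= maximum``, all integers >= 1.
    """

    minimum: int
    q25: int
    q50: int
    q75: int
    maximum: int

    def __post_init__(self) -> None:
        vals = (self.minimum, self.q25, self.q50, self.q75, self.maximum)
        for v in vals:
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise InvalidAnchorsError(f"anchors must be integers, got {v!r}")
            if v < 1:
                raise InvalidAnchorsError(f"anchors must be >= 1, got {v}")
        if not all(a <= b for a, b in zip(vals, vals[1:])):
            raise InvalidAnchorsError(f"anchors must be non-decreasing, got {vals}")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.minimum, self.q25, self.q50, self.q75, self.maximum)


# Published BrainMap-VBM summaries (after the database's >500-subject outlier
# filter), used as the package defaults.
VBM_SUBJECT_ANCHORS = QuantileAnchors(2, 13, 20, 32, 479)
VBM_SUBJECT_MEAN = 30.63
VBM_SUBJECT_SD = 40.91
VBM_FOCI_ANCHORS = QuantileAnchors(1, 2, 4, 8, 75)
VBM_FOCI_MEAN = 6.54
VBM_FOCI_SD = 7.88


@dataclass(frozen=True)
class TailCalibration:
    """How the upper tail (q75, maximum] was shaped.

    ``rule`` is ``"geometric"`` (weights proportional to ``ratio**(x - lo)``),
    ``"uniform"`` (no mean target given), or ``"none"`` (degenerate tail).
    ``achieved_mean``/``achieved_sd`` are the analytic moments of the full
    calibrated distribution; the SD is reported, not enforced.
    """

    rule: str
    ratio: Optional[float]
    achieved_mean: float
    achieved_sd: float
    target_mean: Optional[float] = None
    target_sd: Optional[float] = None


RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CountSampler:
    """Integer-count sampler with explicit probability mass function.

    Draws are integers in ``[support[0], support[1]]``; the pmf is anchored to
    ``anchors`` and (optionally) mean-calibrated via ``calibration``.
    """

    values: np.ndarray
    pmf: np.ndarray
    anchors: QuantileAnchors
    calibration: TailCalibration
    support: tuple[int, int]

    def __post_init__(self) -> None:
        if not np.isclose(self.pmf.sum(), 1.0, atol=1e-9):
            raise ValueError("pmf must sum to 1")

    # --- analytic summaries -------------------------------------------------
    def mean(self) -> float:
        return float(np.dot(self.values, self.pmf))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.dot((self.values - m) ** 2, self.pmf)))

    def quantile(self, q: float) -> int:
        """Smallest value v with P(X <= v) >= q."""
        cdf = np.cumsum(self.pmf)
        idx = int(np.searchsorted(cdf, q - 1e-12))
        return int(self.values[min(idx, len(self.values) - 1)])

    # --- sampling -----------------------------------------------------------
    def sample(self, n: int, rng: RngLike = None) -> np.ndarray:
        if n < 1:
            raise EmptyRequestError("requested a draw of zero counts")
        gen = _as_rng(rng)
        # inverse-CDF draw; much faster than rng.choice for large n
        cdf = np.cumsum(self.pmf)
        u = gen.random(n)
        return self.values[np.searchsorted(cdf, u, side="right").clip(0, len(self.values) - 1)]

    # --- stratified restriction ----------------------------------------------
    def restrict(self, lo: int, hi: int) -> "CountSampler":
        """Condition the sampler on the inclusive integer range [lo, hi]."""
        keep = (self.values >= lo) & (self.values <= hi)
        mass = self.pmf[keep].sum()
        if mass <= 0:
            raise InfeasibleCalibrationError(
                f"restriction [{lo}, {hi}] carries no probability mass"
            )
        values = self.values[keep]
        pmf = self.pmf[keep] / mass
        m = float(np.dot(values, pmf))
        sd = float(np.sqrt(np.dot((values - m) ** 2, pmf)))
        cal = TailCalibration(
            rule=self.calibration.rule,
            ratio=self.calibration.ratio,
            achieved_mean=m,
            achieved_sd=sd,
        )
        return CountSampler(values=values, pmf=pmf, anchors=self.anchors,
                            calibration=cal, support=(int(values[0]), int(values[-1])))


def _bin_ranges(a: QuantileAnchors) -> list[tuple[int, int]]:
    """Integer bins [min,q25], (q25,q50], (q50,q75], (q75,max]; may be empty."""
    return [
        (a.minimum, a.q25),
        (a.q25 + 1, a.q50),
        (a.q50 + 1, a.q75),
        (a.q75 + 1, a.maximum),
    ]


def _tail_mean(lo: int, hi: int, log_ratio: float) -> float:
    x = np.arange(lo, hi + 1, dtype=float)
    logw = (x - lo) * log_ratio
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return float(np.dot(w, x))


def _tail_pmf(lo: int, hi: int, log_ratio: float) -> np.ndarray:
    x = np.arange(lo, hi + 1, dtype=float)
    logw = (x - lo) * log_ratio
    w = np.exp(logw - logw.max())
    return w / w.sum()


def make_count_sampler(
    anchors: QuantileAnchors,
    target_mean: Optional[float] = None,
    target_sd: Optional[float] = None,
) -> CountSampler:
    """Build a quantile-anchored, mean-calibrated integer sampler.

    The distribution is uniform over the integers of each inter-quartile bin,
    with bin masses ``0.25 ± QUANTILE_GUARD`` (positive sign on the two lower
    bins).  If the upper-tail bin ``(q75, maximum]`` is non-empty and a
    ``target_mean`` is given, the tail follows a geometric decay whose ratio
    is solved so the overall expectation equals ``target_mean``.  ``target_sd``
    is recorded for reporting only.

    Raises
    ------
    InvalidAnchorsError
        if the anchors are non-monotone.
    InfeasibleCalibrationError
        if no tail shape can reach ``target_mean``.
    """
    if target_mean is not None and not (anchors.minimum <= target_mean <= anchors.maximum):
        raise InfeasibleCalibrationError(
            f"target mean {target_mean} outside [{anchors.minimum}, {anchors.maximum}]"
        )

    ranges = _bin_ranges(anchors)
    base_w = [0.25 + QUANTILE_GUARD, 0.25 + QUANTILE_GUARD,
              0.25 - QUANTILE_GUARD, 0.25 - QUANTILE_GUARD]
    # merge empty bins into the previous non-empty one (bin 1 is never empty)
    merged: list[list] = []  # [lo, hi, weight, is_tail]
    for k, ((lo, hi), w) in enumerate(zip(ranges, base_w)):
        if lo > hi:
            merged[-1][2] += w
        else:
            merged.append([lo, hi, w, k == 3])

    values = np.arange(anchors.minimum, anchors.maximum + 1)
    pmf = np.zeros_like(values, dtype=float)

    tail_bin = merged[-1] if merged[-1][3] else None
    fixed_mean = 0.0
    for lo, hi, w, is_tail in merged:
        if is_tail:
            continue
        span = np.arange(lo, hi + 1)
        pmf[span - anchors.minimum] += w / len(span)
        fixed_mean += w * span.mean()

    rule, ratio = "none", None
    if tail_bin is not None:
        lo, hi, w, _ = tail_bin
        if target_mean is None or lo == hi:
            rule = "uniform" if lo != hi else "none"
            tail = np.full(hi - lo + 1, 1.0 / (hi - lo + 1))
        else:
            need = (target_mean - fixed_mean) / w
            if not (lo < need < hi):
                raise InfeasibleCalibrationError(
                    f"target mean {target_mean} needs tail mean {need:.2f} "
                    f"outside ({lo}, {hi})"
                )
            rho = brentq(lambda r: _tail_mean(lo, hi, r) - need, -30.0, 30.0,
                         xtol=1e-12)
            rule, ratio = "geometric", float(np.exp(rho))
            tail = _tail_pmf(lo, hi, rho)
        pmf[lo - anchors.minimum : hi - anchors.minimum + 1] += w * tail
    elif target_mean is not None:
        # no free tail: the distribution is fully determined by the anchors
        m = float(np.dot(values, pmf))
        if abs(m - target_mean) > 0.02 * max(target_mean, 1.0):
            raise InfeasibleCalibrationError(
                f"anchors fix the mean at {m:.3f}, incompatible with "
                f"target {target_mean}"
            )

    m = float(np.dot(values, pmf))
    sd = float(np.sqrt(np.dot((values - m) ** 2, pmf)))
    cal = TailCalibration(rule=rule, ratio=ratio, achieved_mean=m, achieved_sd=sd,
                          target_mean=target_mean, target_sd=target_sd)
    return CountSampler(values=values, pmf=pmf, anchors=anchors, calibration=cal,
                        support=(anchors.minimum, anchors.maximum))


def sample_counts(sampler: CountSampler, n: int, rng: RngLike = None) -> np.ndarray:
    """Draw ``n`` integer counts; reproducible for a fixed seed."""
    return sampler.sample(n, rng)


STRATUM_CATEGORIES = ("low", "low-medium", "high-medium", "high")


def stratum_range(parameter: str, category: str, anchors: QuantileAnchors) -> tuple[int, int]:
    """Inclusive integer range of a quartile stratum.

    Bins are half-open on the left, ``(q_{k-1}, q_k]``, with the minimum
    included in "low"; the four ranges partition ``[minimum, maximum]``.
    """
    if parameter not in ("subjects", "foci"):
        raise ValueError(f"unknown parameter {parameter!r}")
    table = dict(zip(STRATUM_CATEGORIES, _bin_ranges(anchors)))
    if category not in table:
        raise ValueError(f"unknown stratum category {category!r}")
    lo, hi = table[category]
    if lo > hi:
        raise InfeasibleCalibrationError(
            f"stratum {category!r} is empty for anchors {anchors.as_tuple()}"
        )
    return (lo, hi)


@dataclass(frozen=True)
class StratumSpec:
    """One of the 16 subject-by-foci quartile strata."""

    subjects: str
    foci: str

    def __post_init__(self) -> None:
        for cat in (self.subjects, self.foci):
            if cat not in STRATUM_CATEGORIES:
                raise ValueError(f"unknown stratum category {cat!r}")

    def label(self) -> str:
        return f"subjects:{self.subjects}/foci:{self.foci}"


def all_strata() -> list[StratumSpec]:
    """The 16 subject-category x foci-category pairs."""
    return [StratumSpec(s, f) for s in STRATUM_CATEGORIES for f in STRATUM_CATEGORIES]


def default_subject_sampler() -> CountSampler:
    return make_count_sampler(VBM_SUBJECT_ANCHORS, VBM_SUBJECT_MEAN, VBM_SUBJECT_SD)


def default_foci_sampler() -> CountSampler:
    return make_count_sampler(VBM_FOCI_ANCHORS, VBM_FOCI_MEAN, VBM_FOCI_SD)


def default_samplers() -> tuple[CountSampler, CountSampler]:
    """(subject sampler, foci sampler) calibrated to the VBM database summaries."""
    return default_subject_sampler(), default_foci_sampler()
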