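# Methods

This note documents the models, numerical choices and limitations behind
`alesim`. It is the package's own account of its science; every number in
it is computed by the tests or the acceptance script, not asserted.

## Parameter samplers

The simulation needs per-experiment subject counts and foci counts that
behave like the VBM subset of the BrainMap database. Only summary
statistics of that database are published, so the samplers are
*quantile-anchored*: a discrete distribution on the integers
`[minimum, maximum]` that is uniform within each inter-quartile bin
(`[min, q25]`, `(q25, q50]`, `(q50, q75]`) and follows a geometric decay on
the upper tail `(q75, max]`. The geometric ratio is the one free parameter;
it is solved (Brent's method on the analytic expectation) so the overall
mean equals the published mean. Defaults: subjects anchored at
(2, 13, 20, 32, 479) with mean 30.63; foci at (1, 2, 4, 8, 75) with mean
6.54.

Consequences of this design:

* all five anchors and the mean are reproduced exactly (up to Monte-Carlo
  error); the standard deviation is *approximated* by the geometric tail
  (≈31.8 vs. 40.9 for subjects, ≈6.0 vs. 7.9 for foci) and is reported,
  not enforced — matching SD as well would require a second tail parameter
  and sacrifice the closed quantile anchoring;
* subject and foci counts are drawn independently, mirroring the two
  independent database draws of the original workflow.

**Quantile guard.** With exactly 0.25 mass per bin the CDF equals 0.25/0.5/
0.75 exactly *at* the anchors, so the empirical quartiles of a large sample
straddle the anchor (a 10⁶-draw median would fall on 20 or 20.5 at coin-flip
odds). A fixed asymmetry of ±0.002 (added to the two lower bins, removed
from the two upper) makes `P(X ≤ anchor)` strictly exceed the nominal level
by ≈4 binomial standard errors at 10⁶ draws, pinning the empirical quartiles
to the anchors. The mean calibration absorbs the guard because the tail
ratio is solved after it is applied.

Quartile strata for the homogeneity study use half-open bins
`(q_{k-1}, q_k]` with the minimum included in "low"; the four ranges
partition the support by construction. Stratified sampling conditions the
pmf on the stratum range (the mean target is deliberately not re-imposed).

## Brain grid and mask

Analysis runs on a regular isotropic grid in MNI-style mm coordinates.
Default resolution is 4 mm (desk scale); 2 mm reproduces the faithful
setting, with the detection vicinity of ±4 mm being two voxels at 2 mm.
The mask is either

* a gray-matter mask from a tissue-probability map: probability **strictly**
  greater than 0.10, resampled to the target resolution by nearest-neighbour
  interpolation *before* thresholding (avoids smoothing-induced mask
  growth); or
* the built-in synthetic ellipsoid (semi-axes 72×90×72 mm centered at
  (0, −18, 18)): ≈1.95 litres, ≈30.5k voxels at 4 mm — the volume of a
  lenient gray-matter mask — containing the ground-truth location. It is
  the canonical no-download fixture; it has no sulci/gyri structure, so
  absolute cluster shapes on real masks will differ, but the statistics
  validated here (rates, contribution fractions) depend on mask volume and
  kernel scale rather than mask topology.

Foci are snapped to voxel centers; uniform sampling is uniform over mask
voxels.

## Dataset simulation

A dataset of `n_total` experiments draws each experiment's counts from the
samplers and its foci uniformly from the mask. The first `n_signal`
experiments (labels exchangeable) replace their first focus with the
ground truth (−30, −26, 58) plus an isotropic Gaussian displacement,
re-snapped to the mask. The displacement scale is not specified beyond
"slight" in the source material; the default is SD = 2 mm per axis — half
the 4 mm vicinity half-width, so that detection is essentially never lost
to displacement (P(|offset| > 4 mm per axis) < 0.05) while the cluster
center still wanders around the truth. Offsets that leave the mask are
resampled.

Condition grids: `main` = sizes 15–45 × 0–10 signal experiments (341
conditions; the enumeration follows the stated ranges — note 31 × 11 = 341),
`quantile` = 16 strata × sizes 5–30 (null datasets: the homogeneity
analysis concerns spurious-cluster contributions), `small` = sizes 5–15
(null).

## ALE

**Kernel.** The two-component spatial-uncertainty model: between-subject
uncertainty 11.6 mm scaled by 1/√n plus between-template uncertainty
5.7 mm, converted from mean-displacement constants to a Gaussian SD by
σ(n) = √(5.7² + 11.6²/n) / (2√(2/π)) mm (≈10 mm FWHM at n = 10). The
discrete kernel is evaluated on voxel centers, truncated at 5 SD
(truncation error < 1e-6) and normalized to unit mass, so the MA value is
a per-voxel probability. Per experiment, overlapping kernels combine by
voxelwise maximum (non-additive MA).

**Voxel null.** Under spatial independence each experiment contributes the
MA value of one uniformly drawn mask voxel, and the ALE union becomes a sum
in L = −log(1 − MA) space. The null is therefore computed *analytically*
by histogramming each experiment's MA values over the mask (bin width 1e-5
in L, matching 1e-5 in ALE units at small scores) and convolving the
histograms (pairwise-tree FFT convolution). Trailing bins with cumulative
mass < 1e-9 are lumped into the last kept bin, which leaves every tail
probability above that mass exact. The construction is verified against
brute-force enumeration on ≤100-voxel masks with up to 3 experiments.

**Cluster-forming cutoff.** The smallest histogram bin edge with tail
probability ≤ p (conservative); significance is strict (`ALE > cutoff`).

**Max-statistic null.** Monte-Carlo: per iteration all foci are relocated
uniformly in the mask, ALE recomputed, and the maximum ALE and the largest
suprathreshold connected component recorded. 100 iterations in the desk
preset, 10,000 in the faithful preset — an accuracy/time dial affecting
threshold granularity, not validity. The scratch volumes use float32; the
~1e-7 relative rounding is far below Monte-Carlo resolution.

**FWE thresholds.** The critical value is the ⌈(1−α)(N+1)⌉-th order
statistic of the N null samples with strict exceedance — the exact
Monte-Carlo test, whose level is ⌈α(N+1)⌉/(N+1) ≤ α for a continuous
statistic (5/101 ≈ .0495 at N = 100, α = .05). The alternative
⌈(1−α)N⌉-th order statistic is anticonservative at small N (level
6/101 ≈ .059), which is why it is not used. Cluster-size ties are broken
conservatively by the strict comparison.

**Connectivity** is 26-neighbour by default (configurable: 6/18/26); the
choice is a convention, not specified by the validated procedure.

## Outcome measures

* **Sensitivity**: any significant cluster with a voxel inside the
  axis-aligned ±4 mm box around the truth ("in each direction"); a
  Euclidean-ball option exists but is non-default.
* **Spurious rate**: fraction of datasets with ≥1 significant cluster
  outside the vicinity. On null datasets this is the empirical family-wise
  false-positive rate.
* **Contributions**: per voxel, MA values sorted in decreasing order,
  complemented, cumulatively multiplied; f_k = (1 − ∏_{i≤k}(1 − MA_(i))) /
  ALE, averaged over the cluster's voxels. Identities f_K = 1 and f_k
  non-decreasing hold exactly. Aggregation pools all spurious clusters of
  a condition (cluster-weighted); per-dataset averaging is available since
  either convention is defensible.

The minimum-dataset-size heuristic is the smallest size whose mean f₁
falls below 50%; for strata that never cross (e.g. all experiments
reporting < 5 foci) it is reported as absent.

## Study runner

Per-dataset seeds derive from (master seed, condition index, replicate
index) via numpy's SeedSequence, so results are identical across worker
counts and scheduling orders. Completed conditions are checkpointed
(pickle) and skipped on rerun; the run manifest records the full
configuration.

Desk-scale problem sizes (chosen once as the package's validation
conditions): 4 mm grid, 100 Monte-Carlo iterations, 200 null datasets per
size for alpha control, 300–400 null datasets for contribution estimates,
100 datasets per point for sensitivity curves. At FWE α = .05 only ~5% of
null datasets yield any spurious cluster, so contribution means at desk
scale rest on tens of clusters — their Monte-Carlo error (a few percentage
points, reported as `f1_ci`/`f2_ci`) dominates comparisons against
published central values.

The strata-ordering checks (higher-foci strata → lower f₁; higher-subject
strata → higher f₁) use **uncorrected** clusters: uncorrected inference is
one of the three thresholding routes of the contribution analysis, and at
desk scale it yields enough clusters per stratum for stable means, which
FWE-corrected nulls cannot at any feasible replicate count.

## Limitations

* The samplers emulate printed summaries, not the raw database; dependence
  between subject and foci counts (if any) is not modeled.
* One ground-truth focus; no multiple true effects, no inter-experiment
  spatial correlation beyond the injected effect, no study-quality
  weighting.
* The synthetic mask lacks anatomical structure; TPM-based masks restore
  it where needed.
* Desk-scale runs trade replicate counts and grid resolution for runtime;
  the faithful presets exist but are not desk-runnable.
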