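"""Dominant-experiment contribution fractions of significant clusters.

For a small dataset, computes for each uncorrected cluster the fraction of
its ALE value contributed by the k most dominant experiments (per voxel:
sort MA values, complement, cumulative product; then average over the
cluster's voxels).  Small datasets yield clusters driven largely by one or
two experiments.
"""

import numpy as np

from alesim import contribution_profile, default_samplers, make_synthetic_mask, simulate_dataset
from alesim.study import analyze_dataset

grid = make_synthetic_mask()
subjects, foci = default_samplers()

for n_total in (6, 12, 24):
    f1s, f2s = [], []
    for rep in range(10):
        rng = np.random.default_rng([n_total, rep])
        ds = simulate_dataset(n_total, 0, subjects, foci, grid, seed=rng)
        records, clusters = analyze_dataset(
            ds, grid, methods=("uncorrected",), rng=rng)
        for p in records["uncorrected"].spurious_profiles:
            f1s.append(p[0])
            f2s.append(p[1])
    print(f"{n_total:2d} experiments: mean f1 = {np.mean(f1s):.2f}, "
          f"mean f2 = {np.mean(f2s):.2f}  ({len(f1s)} clusters)")
# f1 is the average fraction of ALE explained by the single most dominant
# experiment; it falls as datasets grow, which is the basis of the
# minimum-dataset-size recommendation.
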