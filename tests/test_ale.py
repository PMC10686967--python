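"""ALE statistic, analytic voxel null (vs brute force), and thresholding."""

import math

import numpy as np
import pytest

from alesim import ale as ale_mod
from alesim.ale import (
    KernelSpec,
    MaxStatNull,
    VoxelNull,
    ale_union,
    cluster_forming_cutoff,
    kernel_array,
    kernel_peak,
    kernel_sd,
    label_clusters,
    max_stat_null,
    modeled_activation,
    threshold_cfwe,
    threshold_uncorrected,
    threshold_vfwe,
    voxel_null,
)
from alesim.grid import OutOfGridError, VoxelGrid
from alesim.simulate import Experiment

SPEC = KernelSpec()


def _experiment(foci, n_subjects=20, **kw):
    return Experiment(id=0, n_subjects=n_subjects, foci=np.atleast_2d(foci), **kw)


class TestKernel:
    def test_sd_decreases_with_sample_size(self):
        sds = [kernel_sd(SPEC, n) for n in (1, 10, 40, 400)]
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_large_n_limit_is_template_only(self):
        template_only = SPEC.template_mm / (2 * math.sqrt(2 / math.pi))
        assert kernel_sd(SPEC, 10**9) == pytest.approx(template_only, rel=1e-4)

    @pytest.mark.parametrize("n", [1, 5, 13, 30, 100, 479])
    def test_matches_independent_two_component_formula(self, n):
        """Cross-check against the component-wise FWHM formulation."""
        mad_to_sd = 2.0 * math.sqrt(2.0 / math.pi)
        fwhm_to_sd = math.sqrt(8.0 * math.log(2.0))
        fwhm_template = SPEC.template_mm / mad_to_sd * fwhm_to_sd
        fwhm_subject = SPEC.subject_mm / mad_to_sd * fwhm_to_sd / math.sqrt(n)
        expected = math.hypot(fwhm_template, fwhm_subject) / fwhm_to_sd
        assert kernel_sd(SPEC, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_sample_size_rejected(self):
        with pytest.raises(ValueError):
            kernel_sd(SPEC, 0)


class TestModeledActivation:
    def test_single_focus_peak_value_and_location(self, desk_grid):
        e = _experiment([10.0, -10.0, 18.0], n_subjects=25)
        ma = modeled_activation(e, desk_grid, SPEC)
        idx = desk_grid.world_to_voxel(e.foci[0])
        assert ma.argmax() == np.ravel_multi_index(idx, desk_grid.shape)
        # direct kernel evaluation: normalized Gaussian on voxel centers
        sigma = kernel_sd(SPEC, 25)
        r = int(np.ceil(SPEC.truncate_sd * sigma / desk_grid.voxel_size))
        ax = np.arange(-r, r + 1) * desk_grid.voxel_size
        d2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
              + ax[None, None, :] ** 2)
        k = np.exp(-d2 / (2 * sigma**2))
        k[d2 > (SPEC.truncate_sd * sigma) ** 2] = 0
        assert ma[idx] == pytest.approx(k.max() / k.sum(), rel=1e-12)

    def test_values_vanish_beyond_truncation_radius(self, desk_grid):
        e = _experiment([10.0, -10.0, 18.0], n_subjects=25)
        ma = modeled_activation(e, desk_grid, SPEC)
        radius = SPEC.truncate_sd * kernel_sd(SPEC, 25)
        world = desk_grid.voxels_to_world(np.argwhere(ma > 0))
        dist = np.linalg.norm(world - e.foci[0], axis=1)
        assert dist.max() <= radius + desk_grid.voxel_size
        assert 0 <= ma.min() and ma.max() < 1

    def test_coincident_foci_are_idempotent(self, desk_grid):
        one = modeled_activation(_experiment([0.0, -18.0, 18.0]), desk_grid)
        two = modeled_activation(
            _experiment([[0.0, -18.0, 18.0], [0.0, -18.0, 18.0]]), desk_grid)
        assert np.array_equal(one, two)

    def test_distant_foci_equal_voxelwise_max(self, desk_grid):
        f1, f2 = [40.0, -18.0, 18.0], [-40.0, -18.0, 18.0]
        both = modeled_activation(_experiment([f1, f2]), desk_grid)
        m1 = modeled_activation(_experiment(f1), desk_grid)
        m2 = modeled_activation(_experiment(f2), desk_grid)
        assert np.array_equal(both, np.maximum(m1, m2))

    def test_focus_off_grid_rejected(self, desk_grid):
        with pytest.raises(OutOfGridError):
            modeled_activation(_experiment([500.0, 0.0, 0.0]), desk_grid)


class TestAleUnion:
    def test_union_formula(self):
        a = np.full((2, 2, 2), 0.1)
        b = np.full((2, 2, 2), 0.05)
        assert np.allclose(ale_union([a, b]), 1 - 0.9 * 0.95)  # 0.145

    def test_single_map_is_identity(self):
        a = np.random.default_rng(0).random((3, 3, 3)) * 0.5
        assert np.array_equal(ale_union([a]), a)

    def test_zero_maps_give_zero(self):
        z = np.zeros((2, 2, 2))
        assert np.array_equal(ale_union([z, z]), z)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ale_union([np.zeros((2, 2, 2)), np.zeros((3, 3, 3))])

    def test_ale_dominates_each_ma_map(self, desk_grid, samplers):
        from alesim.simulate import simulate_dataset
        ds = simulate_dataset(10, 0, *samplers, desk_grid, seed=3)
        mas = [modeled_activation(e, desk_grid) for e in ds.experiments]
        union = ale_union(mas)
        assert union.max() < 1
        for ma in mas:
            assert np.all(union >= ma - 1e-12)


def _brute_force_tail(ma_values_per_exp, thresholds):
    """P(ALE >= t) by exhaustive enumeration over ordered voxel tuples."""
    comp = np.ones(1)
    for vals in ma_values_per_exp:
        comp = np.multiply.outer(comp, 1.0 - vals).ravel()
    atoms = 1.0 - comp
    return np.array([(atoms >= t).mean() for t in thresholds]), atoms


class TestVoxelNull:
    @pytest.mark.parametrize("n_exp", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, tiny_grid, n_exp):
        """Histogram-convolution null equals brute force on a 100-voxel mask."""
        rng = np.random.default_rng(21)
        mas = []
        for i in range(n_exp):
            e = _experiment(tiny_grid.voxel_to_world((1 + i, 2, 2)),
                            n_subjects=10 + 5 * i)
            mas.append(modeled_activation(e, tiny_grid, SPEC))
        null = voxel_null(mas, tiny_grid, bin_width=1e-7)
        vals = [ma[tiny_grid.mask] for ma in mas]
        _, atoms = _brute_force_tail(vals, [])
        # probe tails at midpoints of well-separated atom gaps
        u = np.unique(atoms)
        gaps = np.nonzero(np.diff(u) > 1e-5)[0]
        probes = (u[gaps] + u[gaps + 1]) / 2
        oracle, _ = _brute_force_tail(vals, probes)
        got = np.array([null.tail(t) for t in probes])
        assert np.allclose(got, oracle, atol=1e-9)

    def test_single_experiment_null_is_empirical_ma_distribution(self, tiny_grid):
        e = _experiment(tiny_grid.voxel_to_world((2, 2, 2)), n_subjects=15)
        ma = modeled_activation(e, tiny_grid, SPEC)
        null = voxel_null([ma], tiny_grid, bin_width=1e-7)
        vals = ma[tiny_grid.mask]
        for t in (1e-4, np.median(vals[vals > 0]), vals.max() * 0.99):
            assert null.tail(t) == pytest.approx((vals >= t).mean(), abs=1e-9)

    def test_tail_at_zero_is_one(self, tiny_grid):
        ma = modeled_activation(
            _experiment(tiny_grid.voxel_to_world((2, 2, 2))), tiny_grid)
        null = voxel_null([ma], tiny_grid)
        assert null.tail(0.0) == 1.0

    def test_invalid_bin_width_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            voxel_null([np.zeros(tiny_grid.shape)], tiny_grid, bin_width=0.0)


class TestClusterFormingCutoff:
    def test_cutoff_matches_brute_force_order_statistic(self, tiny_grid):
        e = _experiment(tiny_grid.voxel_to_world((2, 2, 2)), n_subjects=15)
        ma = modeled_activation(e, tiny_grid, SPEC)
        null = voxel_null([ma], tiny_grid, bin_width=1e-7)
        vals = np.sort(ma[tiny_grid.mask])
        for p in (0.05, 0.02):
            cutoff = cluster_forming_cutoff(null, p)
            # the significance set {v > cutoff} must equal the brute-force one
            oracle_set = vals[(vals > 0)][
                np.array([(vals >= v).mean() for v in vals[vals > 0]]) <= p
            ]
            got_set = vals[vals > cutoff]
            assert np.array_equal(np.unique(got_set), np.unique(oracle_set))

    def test_near_one_p_gives_distribution_minimum(self, tiny_grid):
        ma = modeled_activation(
            _experiment(tiny_grid.voxel_to_world((2, 2, 2))), tiny_grid)
        null = voxel_null([ma], tiny_grid)
        cutoff = cluster_forming_cutoff(null, 1 - 1e-9)
        vals = ma[tiny_grid.mask]
        assert abs(cutoff - vals.min()) <= null.bin_width

    def test_cutoff_monotone_in_p(self, tiny_grid):
        ma = modeled_activation(
            _experiment(tiny_grid.voxel_to_world((2, 2, 2))), tiny_grid)
        null = voxel_null([ma], tiny_grid)
        assert cluster_forming_cutoff(null, 0.001) >= cluster_forming_cutoff(null, 0.01)

    def test_invalid_p_rejected(self, tiny_grid):
        ma = modeled_activation(
            _experiment(tiny_grid.voxel_to_world((2, 2, 2))), tiny_grid)
        null = voxel_null([ma], tiny_grid)
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                cluster_forming_cutoff(null, p)


class TestMaxStatNull:
    def test_reproducible_for_fixed_seed(self, desk_grid):
        struct = [(20, 3), (40, 5)]
        a = max_stat_null(struct, desk_grid, SPEC, 0.01, 5,
                          np.random.default_rng(9))
        b = max_stat_null(struct, desk_grid, SPEC, 0.01, 5,
                          np.random.default_rng(9))
        assert np.array_equal(a.max_ale, b.max_ale)
        assert np.array_equal(a.max_cluster, b.max_cluster)

    def test_single_focus_max_equals_kernel_peak(self, desk_grid):
        null = max_stat_null([(25, 1)], desk_grid, SPEC, 0.5, 20,
                             np.random.default_rng(10))
        peak = kernel_peak(SPEC, 25, desk_grid.voxel_size)
        assert np.allclose(null.max_ale, peak, rtol=1e-5)
        assert np.all(null.max_cluster == 0)  # cutoff above the peak

    def test_cluster_sizes_are_nonnegative_integers(self, desk_grid):
        null = max_stat_null([(20, 10), (30, 8)], desk_grid, SPEC, 0.02, 10,
                             np.random.default_rng(11))
        assert null.max_cluster.dtype.kind == "i"
        assert np.all(null.max_cluster >= 0)


class TestLabelClusters:
    def _grid(self):
        return VoxelGrid(shape=(5, 5, 5), voxel_size=2.0, origin=np.zeros(3),
                         mask=np.ones((5, 5, 5), dtype=bool))

    def test_isolated_voxel(self):
        g = self._grid()
        sig = np.zeros(g.shape, dtype=bool)
        sig[2, 2, 2] = True
        cs = label_clusters(sig, sig.astype(float), g)
        assert len(cs) == 1 and cs[0].size == 1
        assert np.allclose(cs[0].peak_mm, g.voxel_to_world((2, 2, 2)))

    def test_corner_touch_depends_on_connectivity(self):
        g = self._grid()
        sig = np.zeros(g.shape, dtype=bool)
        sig[0, 0, 0] = sig[1, 1, 1] = True
        ale_map = sig.astype(float)
        assert len(label_clusters(sig, ale_map, g, connectivity=26)) == 1
        assert len(label_clusters(sig, ale_map, g, connectivity=6)) == 2

    def test_empty_set_and_bad_connectivity(self):
        g = self._grid()
        sig = np.zeros(g.shape, dtype=bool)
        assert len(label_clusters(sig, sig.astype(float), g)) == 0
        with pytest.raises(ValueError):
            label_clusters(sig, sig.astype(float), g, connectivity=10)


class TestThresholding:
    def _grid(self):
        return VoxelGrid(shape=(6, 6, 6), voxel_size=2.0, origin=np.zeros(3),
                         mask=np.ones((6, 6, 6), dtype=bool))

    def test_mc_threshold_is_order_statistic(self):
        samples = np.arange(1.0, 101.0)  # 1..100
        # exact Monte-Carlo rule: ceil(0.95 * 101) = 96th order statistic
        assert ale_mod._mc_threshold(samples, 0.05) == 96.0
        assert ale_mod._mc_threshold(samples, 0.5) == 51.0

    def test_vfwe_empty_when_observed_below_null(self):
        g = self._grid()
        ale_map = np.full(g.shape, 0.01)
        null = MaxStatNull(np.linspace(0.02, 0.05, 100),
                           np.zeros(100, dtype=int), 100, 0.015)
        assert len(threshold_vfwe(ale_map, null, g)) == 0

    def test_vfwe_detects_voxels_above_every_null_max(self):
        g = self._grid()
        ale_map = np.zeros(g.shape)
        ale_map[2, 2, :4] = 0.9  # 4-voxel line, plus 6 more below
        ale_map[3, 2, :6] = 0.9
        null = MaxStatNull(np.linspace(0.02, 0.05, 100),
                           np.zeros(100, dtype=int), 100, 0.015)
        cs = threshold_vfwe(ale_map, null, g)
        assert len(cs) == 1 and cs[0].size == 10

    def test_cfwe_size_filter(self):
        g = self._grid()
        ale_map = np.zeros(g.shape)
        ale_map[1:3, 1:3, 1:3] = 0.5  # one 8-voxel component
        vnull = VoxelNull(np.array([0.9985, 0.0005, 0.001]), 0.01)
        small = MaxStatNull(np.full(100, 0.9),
                            np.full(100, 12, dtype=int), 100, 0.0)
        assert len(threshold_cfwe(ale_map, vnull, small, g)) == 0  # 8 < 12
        large_ok = MaxStatNull(np.full(100, 0.9),
                               np.full(100, 3, dtype=int), 100, 0.0)
        cs = threshold_cfwe(ale_map, vnull, large_ok, g)
        assert len(cs) == 1 and cs[0].size == 8

    def test_uncorrected_is_superset_of_cfwe(self, desk_grid, samplers):
        from alesim.simulate import GroundTruth, simulate_dataset
        from alesim.study import analyze_dataset
        rng = np.random.default_rng(31)
        ds = simulate_dataset(15, 8, *samplers, desk_grid,
                              GroundTruth(displacement_sd=0.0), seed=rng)
        _, clusters = analyze_dataset(ds, desk_grid, mc_iterations=40, rng=rng)
        def voxset(cs):
            return {tuple(v) for c in cs for v in c.indices}
        assert voxset(clusters["cfwe"]) <= voxset(clusters["uncorrected"])
        assert len(clusters["cfwe"]) >= 1  # strong convergence is detected

    def test_uncorrected_suprathreshold_fraction_matches_p(self, desk_grid, samplers):
        """Under the null, ~p of mask voxels exceed the cluster-forming cutoff."""
        from alesim.simulate import simulate_dataset
        from alesim.study import analyze_dataset
        p = 0.001
        fracs = []
        for rep in range(40):
            rng = np.random.default_rng([100, rep])
            ds = simulate_dataset(15, 0, *samplers, desk_grid, seed=rng)
            records, clusters = analyze_dataset(
                ds, desk_grid, methods=("uncorrected",), p_cf=p, rng=rng)
            n_sup = sum(c.size for c in clusters["uncorrected"])
            fracs.append(n_sup / desk_grid.n_mask)
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert mean <= p + 3 * se        # conservative cutoff never exceeds p
        assert mean >= 0.2 * p           # but is not vacuously strict

    def test_invalid_alpha_rejected(self):
        g = self._grid()
        null = MaxStatNull(np.ones(10), np.ones(10, dtype=int), 10, 0.0)
        with pytest.raises(ValueError):
            threshold_vfwe(np.zeros(g.shape), null, g, alpha=1.5)
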