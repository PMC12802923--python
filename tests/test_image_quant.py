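"""Unit and property tests for the nuclear quantification chain."""

import itertools

import numpy as np
import pytest
from skimage.filters import threshold_multiotsu

from mitoquant.image_quant import (
    NucleusMask,
    expand_labels_euclidean,
    expand_masks,
    measure_nucleus_signal,
    multi_otsu_thresholds,
    quantify_stack,
    resample_isotropic,
    segment_nuclei,
)
from mitoquant.stacks import ImageStack3D
from mitoquant.synth import NoiseModel, SceneSpec, simulate_cell_stack

from conftest import brute_force_multiotsu


# ------------------------------------------------------------- resampling ---

class TestResample:
    def test_constant_stack_stays_constant(self, flat_stack):
        out = resample_isotropic(flat_stack, 65.0)
        assert out.spacing_nm == (65.0, 65.0, 65.0)
        np.testing.assert_allclose(out.channels["DAPI"], 7.0)
        np.testing.assert_allclose(out.channels["Top2"], 3.0)

    def test_z_axis_geometry(self, flat_stack):
        out = resample_isotropic(flat_stack, 65.0)
        nz = flat_stack.shape[0]
        expected_nz = int(np.floor((nz - 1) * 200.0 / 65.0)) + 1
        assert out.shape == (expected_nz, 24, 24)
        # physical extent preserved to within one voxel
        in_extent = (nz - 1) * 200.0
        out_extent = (out.shape[0] - 1) * 65.0
        assert abs(in_extent - out_extent) <= 65.0

    def test_impulse_matches_trilinear_weight_oracle(self):
        shape = (6, 9, 9)
        vol = np.zeros(shape)
        vol[3, 4, 5] = 1.0
        stack = ImageStack3D({"a": vol}, spacing_nm=(200.0, 65.0, 65.0))
        out = resample_isotropic(stack, 65.0)
        # independent per-voxel oracle: product of 1-D hat weights
        expected = np.zeros(out.shape)
        for idx in np.ndindex(out.shape):
            w = 1.0
            for ax, (j, s) in enumerate(zip(idx, (200.0, 65.0, 65.0))):
                src = j * 65.0 / s
                w *= max(0.0, 1.0 - abs(src - (3, 4, 5)[ax]))
            expected[idx] = w
        np.testing.assert_allclose(out.channels["a"], expected, atol=1e-12)

    def test_coarse_target_warns(self, flat_stack):
        with pytest.warns(UserWarning, match="coarser"):
            resample_isotropic(flat_stack, 500.0)


# -------------------------------------------------------------- multi-Otsu ---

class TestMultiOtsu:
    def test_two_separated_modes(self):
        counts = np.zeros(32)
        counts[2] = 100  # value 10 region
        counts[28] = 100
        vals = np.linspace(0, 217, 32)
        (thr,) = multi_otsu_thresholds(counts, vals, n_classes=2)
        assert vals[2] < thr <= vals[28]

    def test_equals_exhaustive_oracle_on_random_histograms(self, rng):
        for _ in range(100):
            nbins = int(rng.integers(6, 33))
            n_classes = int(rng.integers(2, 5))
            counts = rng.integers(0, 50, nbins).astype(float)
            while np.count_nonzero(counts) < n_classes:
                counts = rng.integers(0, 50, nbins).astype(float)
            vals = np.sort(rng.uniform(0, 100, nbins))
            got = multi_otsu_thresholds(counts, vals, n_classes=n_classes)
            want = brute_force_multiotsu(counts, vals, n_classes)
            np.testing.assert_array_equal(got, want)

    def test_count_scale_invariance(self, rng):
        counts = rng.integers(1, 40, 24).astype(float)
        vals = np.arange(24, dtype=float)
        a = multi_otsu_thresholds(counts, vals, n_classes=4)
        b = multi_otsu_thresholds(counts * 17.0, vals, n_classes=4)
        np.testing.assert_array_equal(a, b)

    def test_agrees_with_skimage_on_objective(self, rng):
        """skimage uses a different threshold convention (last bin of the
        lower class); the achieved between-class objective must agree."""

        def objective(counts, vals, first_upper_bins):
            bounds = [0, *first_upper_bins, len(counts)]
            obj = 0.0
            for a, b in zip(bounds[:-1], bounds[1:]):
                w = counts[a:b].sum()
                if w > 0:
                    obj += counts[a:b] @ vals[a:b] * (counts[a:b] @ vals[a:b]) / w
            return obj

        for k in (2, 3, 4):
            counts = rng.integers(0, 60, 28).astype(float)
            while np.count_nonzero(counts) < k:
                counts = rng.integers(0, 60, 28).astype(float)
            vals = np.arange(28, dtype=float)
            mine = multi_otsu_thresholds(counts, vals, n_classes=k)
            sk = threshold_multiotsu(classes=k, hist=(counts, vals))
            mine_bins = np.searchsorted(vals, mine, side="left")
            sk_bins = np.searchsorted(vals, sk, side="right")
            assert objective(counts, vals, mine_bins) == pytest.approx(
                objective(counts, vals, sk_bins), rel=1e-12
            )

    def test_too_few_distinct_values_raises(self):
        counts = np.zeros(16)
        counts[3] = 5
        counts[9] = 5
        with pytest.raises(ValueError, match="distinct"):
            multi_otsu_thresholds(counts, n_classes=4)


# ------------------------------------------------------------ segmentation ---

class TestSegmentNuclei:
    def test_recovers_constructed_ellipsoids(self):
        spec = SceneSpec(n_cells=3, seed=7)
        stack, labels, truth = simulate_cell_stack(spec)
        iso = resample_isotropic(stack, 65.0)
        _, masks = segment_nuclei(iso)
        assert len(masks) == 3
        found = np.array([m.centroid_um for m in masks])
        want = truth[["cz_um", "cy_um", "cx_um"]].to_numpy()
        for c in want:  # centroid within one coarse voxel (200 nm)
            assert np.min(np.linalg.norm(found - c, axis=1)) < 0.2

    def test_hot_speck_removed_by_volume_filter(self):
        spec = SceneSpec(n_cells=1, seed=3)
        stack, _, _ = simulate_cell_stack(spec)
        iso = resample_isotropic(stack, 65.0)
        dapi = iso.channels["DAPI"]
        dapi[5, 5, 5] = dapi.max() * 2
        dapi[5, 5, 6] = dapi.max() * 2
        _, masks = segment_nuclei(iso)
        assert len(masks) == 1

    def test_empty_foreground_gives_empty_list(self):
        stack = ImageStack3D({"DAPI": np.zeros((8, 16, 16))}, spacing_nm=(65.0,) * 3)
        labels, masks = segment_nuclei(stack)
        assert masks == [] and labels.max() == 0

    def test_anisotropic_input_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="isotropic"):
            segment_nuclei(flat_stack)


# --------------------------------------------------------------- expansion ---

class TestExpansion:
    def test_radius_zero_is_identity(self):
        labels = np.zeros((9, 9, 9), dtype=np.int32)
        labels[4, 4, 4] = 1
        np.testing.assert_array_equal(expand_labels_euclidean(labels, 0), labels)

    def test_single_voxel_radius5_matches_lattice_ball(self):
        labels = np.zeros((13, 13, 13), dtype=np.int32)
        labels[6, 6, 6] = 1
        out = expand_labels_euclidean(labels, 5.0)
        # brute-force lattice-ball enumeration
        count = sum(
            1
            for v in itertools.product(range(-6, 7), repeat=3)
            if v[0] ** 2 + v[1] ** 2 + v[2] ** 2 <= 25
        )
        assert int((out == 1).sum()) == count

    def test_adjacent_labels_partition_union_of_dilations(self):
        labels = np.zeros((7, 21, 7), dtype=np.int32)
        labels[3, 8, 3] = 1
        labels[3, 12, 3] = 2
        out = expand_labels_euclidean(labels, 3.0)
        a = expand_labels_euclidean((labels == 1).astype(np.int32), 3.0) > 0
        b = expand_labels_euclidean((labels == 2).astype(np.int32) * 2, 3.0) > 0
        assert not np.any((out == 1) & (out == 2))
        np.testing.assert_array_equal(out > 0, a | b)
        # equidistant plane goes to the lower label
        assert out[3, 10, 3] == 1

    def test_expansion_monotone_in_radius(self):
        labels = np.zeros((9, 9, 9), dtype=np.int32)
        labels[2, 3, 4] = 1
        small = expand_labels_euclidean(labels, 2.0) > 0
        big = expand_labels_euclidean(labels, 4.0) > 0
        assert np.all(big[small])

    def test_expand_masks_fills_superset(self):
        spec = SceneSpec(n_cells=2, seed=11)
        stack, _, _ = simulate_cell_stack(spec)
        iso = resample_isotropic(stack, 65.0)
        _, masks = segment_nuclei(iso)
        expand_masks(masks, iso.shape, radius_px=5.0)
        for m in masks:
            core = set(map(tuple, m.core_voxels))
            exp = set(map(tuple, m.expanded_voxels))
            assert core <= exp and len(exp) > len(core)


# ------------------------------------------------------------- measurement ---

class TestMeasurement:
    @staticmethod
    def _mask_from(vox):
        return NucleusMask(label=1, core_voxels=np.array(vox), volume_um3=1.0,
                           centroid_um=(0, 0, 0), expanded_voxels=np.array(vox))

    def test_constant_field(self):
        chan = np.full((4, 4, 4), 100.0)
        m = self._mask_from([(i, j, k) for i in range(4) for j in range(4) for k in range(4)])
        r = measure_nucleus_signal(m, chan)
        assert (r.mfi, r.sd, r.cv) == (100.0, 0.0, 0.0)

    def test_two_point_distribution_population_sd(self):
        chan = np.zeros((1, 1, 4))
        chan[0, 0, 2:] = 200.0
        m = self._mask_from([(0, 0, i) for i in range(4)])
        r = measure_nucleus_signal(m, chan)
        assert (r.mfi, r.sd, r.cv) == (100.0, 100.0, 1.0)

    def test_gain_equivariance(self, rng):
        chan = rng.uniform(10, 50, (5, 5, 5))
        m = self._mask_from([(i, i, i) for i in range(5)])
        r1 = measure_nucleus_signal(m, chan)
        r3 = measure_nucleus_signal(m, chan * 3.0)
        assert r3.mfi == pytest.approx(3 * r1.mfi)
        assert r3.cv == pytest.approx(r1.cv)

    def test_zero_mfi_reports_missing_cv(self):
        m = self._mask_from([(0, 0, 0)])
        with pytest.warns(UserWarning, match="CV undefined"):
            r = measure_nucleus_signal(m, np.zeros((1, 1, 1)))
        assert r.cv is None


# ------------------------------------------------------------- full chain ---

class TestQuantifyStack:
    def test_noiseless_diffuse_cv_near_zero(self):
        spec = SceneSpec(n_cells=1, focal_fraction=0.0, seed=21)
        stack, _, _ = simulate_cell_stack(spec)
        df = quantify_stack(stack)
        assert len(df) == 1
        assert df["CV"].iloc[0] <= 0.02

    def test_cv_ranks_focal_fraction(self):
        medians = []
        for ff in (0.0, 0.3, 0.6):
            spec = SceneSpec(n_cells=2, focal_fraction=ff,
                             noise=NoiseModel(read_sd=20.0), seed=31)
            stack, _, _ = simulate_cell_stack(spec)
            medians.append(quantify_stack(stack)["CV"].median())
        assert medians[0] < medians[1] < medians[2]

    def test_mfi_recovers_abundance_ratio(self):
        dfs = []
        for mi in (1000.0, 2000.0):
            spec = SceneSpec(n_cells=2, mean_intensity=mi,
                             noise=NoiseModel(read_sd=15.0), seed=41)
            stack, _, _ = simulate_cell_stack(spec)
            dfs.append(quantify_stack(stack))
        ratio = dfs[1]["MFI"].median() / dfs[0]["MFI"].median()
        assert ratio == pytest.approx(2.0, rel=0.05)
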