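"""Occupancy-ratio calibration and pileup tests."""

import numpy as np
import pytest

from mitoquant.chip import (
    CalibratedTrack,
    GenomeLayout,
    ReadCountSummary,
    calibrate_track,
    occupancy_ratio,
    pileup_centromere,
    pileup_scaled_arms,
    read_layout,
)
from mitoquant.synth import ChipSimSpec, simulate_chip_counts, toy_layout


class TestOccupancyRatio:
    def test_printed_example(self):
        counts = ReadCountSummary(input_exp=200, input_cal=100, ip_exp=300, ip_cal=150)
        assert occupancy_ratio(counts) == 1.0

    def test_all_equal_gives_one(self):
        counts = ReadCountSummary(42, 42, 42, 42)
        assert occupancy_ratio(counts) == 1.0

    def test_genome_swap_gives_reciprocal(self):
        c = ReadCountSummary(input_exp=150, input_cal=100, ip_exp=700, ip_cal=220)
        swapped = ReadCountSummary(input_exp=100, input_cal=150, ip_exp=220, ip_cal=700)
        assert occupancy_ratio(swapped) == pytest.approx(1.0 / occupancy_ratio(c))

    def test_zero_denominator_names_term(self):
        with pytest.raises(ValueError, match="input_exp"):
            occupancy_ratio(ReadCountSummary(0, 1, 1, 1))
        with pytest.raises(ValueError, match="ip_cal"):
            occupancy_ratio(ReadCountSummary(1, 1, 1, 0))


class TestCalibrateTrack:
    def test_or_one_is_identity(self):
        bins = {"chr1": np.array([1.0, 2.0, 3.0])}
        track = calibrate_track(bins, 50, 1.0)
        np.testing.assert_array_equal(track.values["chr1"], [1, 2, 3])

    def test_linearity(self):
        bins = {"chr1": np.arange(10, dtype=float)}
        t2 = calibrate_track(bins, 50, 2.0)
        np.testing.assert_array_equal(t2.values["chr1"], 2 * np.arange(10))
        a = calibrate_track(bins, 50, 0.5)
        b = calibrate_track(bins, 50, 2.0)
        assert b.values["chr1"].sum() == pytest.approx(4 * a.values["chr1"].sum())

    def test_scaling_commutes_with_calibration(self):
        bins = {"chr1": np.arange(1, 8, dtype=float)}
        left = calibrate_track({"chr1": 3.0 * bins["chr1"]}, 50, 1.7)
        right = calibrate_track(bins, 50, 1.7)
        np.testing.assert_allclose(left.values["chr1"], 3.0 * right.values["chr1"])


def _flat_track(layout, value=7.0, bin_bp=50):
    values = {
        c: np.full(int(np.ceil(n / bin_bp)), value) for c, n in layout.chromosomes.items()
    }
    return CalibratedTrack(values=values, bin_bp=bin_bp)


class TestPileupCentromere:
    def test_flat_track_gives_flat_profile(self):
        layout = toy_layout()
        prof = pileup_centromere(_flat_track(layout), layout, 3000, 50)
        np.testing.assert_array_equal(prof.mean, 7.0)
        np.testing.assert_array_equal(prof.sd, 0.0)
        assert np.all(prof.n == 16)

    def test_bin_count_arithmetic(self):
        layout = toy_layout()
        prof = pileup_centromere(_flat_track(layout), layout, 3000, 50)
        assert len(prof.bin_starts) == 120
        prof2 = pileup_centromere(_flat_track(layout, bin_bp=500), layout, 80_000, 500)
        assert len(prof2.bin_starts) == 320

    def test_short_chromosome_bins_missing_not_zero(self):
        layout = GenomeLayout(
            chromosomes={"chrS": 4000, "chrL": 50_000},
            centromeres={"chrS": (1900, 2100), "chrL": (24_900, 25_100)},
        )
        prof = pileup_centromere(_flat_track(layout), layout, 3000, 50)
        # chrS covers only ±2000 of the ±3000 window; outer bins fall back to
        # the long chromosome alone instead of being dragged toward zero
        assert prof.n.min() == 1 and prof.n.max() == 2
        np.testing.assert_array_equal(prof.mean, 7.0)

    def test_enrichment_recovered_at_center(self):
        spec = ChipSimSpec(enrichment=5.0, seed=0)
        ratios = []
        for s in range(20):
            sim = simulate_chip_counts(ChipSimSpec(enrichment=5.0, seed=s))
            track = calibrate_track(sim.bins_ip_exp, sim.bin_bp, occupancy_ratio(sim.summary))
            prof = pileup_centromere(track, spec.layout_exp, 3000, 50)
            center = prof.mean[len(prof.mean) // 2]
            edge = (prof.mean[0] + prof.mean[-1]) / 2
            ratios.append(center / edge)
        assert np.mean(ratios) == pytest.approx(5.0, rel=0.10)


class TestPileupScaledArms:
    def test_flat_track_flat_profile(self):
        layout = toy_layout()
        prof = pileup_scaled_arms(_flat_track(layout), layout)
        assert len(prof.bin_starts) == 200
        np.testing.assert_array_equal(prof.mean, 7.0)
        np.testing.assert_array_equal(prof.sd, 0.0)
        assert np.all(prof.n == 32)

    def test_affine_coverage_stays_affine(self):
        """Coverage linear in distance-from-centromere on every arm maps to a
        linear pseudo-profile with zero cross-arm SD."""
        layout = toy_layout(n_chrom=4, chrom_len=100_000, cen_at=0.5)
        bin_bp = 50
        values = {}
        for chrom, length in layout.chromosomes.items():
            mid = layout.centromere_midpoint(chrom)
            starts = np.arange(0, length, bin_bp)
            centers = starts + bin_bp / 2
            values[chrom] = np.abs(centers - mid) / 1000.0  # µ per kb from cen
        track = CalibratedTrack(values=values, bin_bp=bin_bp)
        prof = pileup_scaled_arms(track, layout)
        diffs = np.diff(prof.mean)
        assert np.all(diffs > 0)
        assert np.std(diffs) < 0.05 * np.mean(diffs)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-6)

    def test_pericentromeric_peak_maps_to_origin(self):
        sim = simulate_chip_counts(ChipSimSpec(enrichment=8.0, seed=3))
        spec_layout = ChipSimSpec().layout_exp
        track = calibrate_track(sim.bins_ip_exp, sim.bin_bp, 1.0)
        prof = pileup_scaled_arms(track, spec_layout)
        assert np.argmax(prof.mean) == 0

    def test_short_arm_excluded_with_warning(self):
        layout = GenomeLayout(
            chromosomes={"chr1": 10_000}, centromeres={"chr1": (20, 60)}
        )
        track = _flat_track(layout)
        with pytest.warns(UserWarning, match="shorter than bin resolution"):
            prof = pileup_scaled_arms(track, layout)
        assert prof.n.max() == 1  # only the long right arm survives


class TestLayoutIO:
    def test_round_trip(self, tmp_path):
        sizes = tmp_path / "sizes.tsv"
        cens = tmp_path / "cens.bed"
        layout = toy_layout()
        sizes.write_text("".join(f"{c}\t{n}\n" for c, n in layout.chromosomes.items()))
        cens.write_text(
            "".join(f"{c}\t{a}\t{b}\n" for c, (a, b) in layout.centromeres.items())
        )
        got = read_layout(sizes, cens)
        assert got.chromosomes == layout.chromosomes
        assert got.centromeres == layout.centromeres

    def test_inverted_interval_rejected(self, tmp_path):
        (tmp_path / "sizes.tsv").write_text("chr1\t1000\n")
        (tmp_path / "cens.bed").write_text("chr1\t500\t400\n")
        with pytest.raises(ValueError, match="end"):
            read_layout(tmp_path / "sizes.tsv", tmp_path / "cens.bed")

    def test_unknown_chromosome_rejected(self, tmp_path):
        (tmp_path / "sizes.tsv").write_text("chr1\t1000\n")
        (tmp_path / "cens.bed").write_text("chr2\t100\t200\n")
        with pytest.raises(ValueError, match="chr2"):
            read_layout(tmp_path / "sizes.tsv", tmp_path / "cens.bed")

    def test_centromere_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            GenomeLayout(chromosomes={"chr1": 100}, centromeres={"chr1": (50, 150)})
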