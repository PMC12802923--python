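"""Spike-in calibrated ChIP-seq normalization and centromere/arm pileups.

Each chromatin sample is mixed with a fixed proportion of calibration-species
cells (here *S. pombe* spiked into *S. cerevisiae*) before immunoprecipitation,
and reads are mapped to both genomes.  Differences in IP efficiency between
samples then cancel through the occupancy ratio

    OR = (INPUT_cal × IP_exp) / (INPUT_exp × IP_cal)

where the four terms are total mapped read counts of the input and IP samples
on the experimental and calibration genomes.  Experimental per-bin IP coverage
multiplied by OR is comparable across samples on an absolute occupancy scale.

Pileups average the calibrated coverage across chromosomes: either anchored at
the centromere midpoint with a fixed flank (e.g. ±3 kb at 50 bp bins, ±80 kb
at 500 bp), or with every chromosome arm linearly rescaled to a common pseudo
length (10 kb at 50 bp bins) and oriented centromere → telomere.  All
coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "ReadCountSummary",
    "CalibratedTrack",
    "PileupProfile",
    "read_layout",
    "occupancy_ratio",
    "calibrate_track",
    "pileup_centromere",
    "pileup_scaled_arms",
]


@dataclass
class GenomeLayout:
    """Chromosome lengths and centromere intervals (0-based half-open)."""

    chromosomes: dict[str, int]
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0, got {length}")
        for name, (start, end) in self.centromeres.items():
            if name not in self.chromosomes:
                raise ValueError(f"centromere chromosome {name!r} missing from sizes")
            if not (0 <= start < end <= self.chromosomes[name]):
                raise ValueError(
                    f"centromere {name}:{start}-{end} outside chromosome "
                    f"(length {self.chromosomes[name]})"
                )

    def centromere_midpoint(self, chrom: str) -> int:
        start, end = self.centromeres[chrom]
        return (start + end) // 2

    def arms(self) -> list[tuple[str, int, int, str]]:
        """All arms as (chrom, genomic_start, genomic_end, side) with side in
        {'left', 'right'}; left arms run telomere->centromere in genomic
        coordinates and are reversed when oriented."""
        out = []
        for chrom in self.chromosomes:
            if chrom not in self.centromeres:
                continue
            cstart, cend = self.centromeres[chrom]
            out.append((chrom, 0, cstart, "left"))
            out.append((chrom, cend, self.chromosomes[chrom], "right"))
        return out


def read_layout(sizes_path: str | Path, cen_path: str | Path) -> GenomeLayout:
    """Read chromosome sizes (TSV ``chrom\\tlength``) and centromeres (BED)."""
    sizes = pd.read_csv(
        sizes_path, sep="\t", names=["chrom", "length"], comment="#", dtype={"chrom": str}
    )
    chromosomes = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
    cens: dict[str, tuple[int, int]] = {}
    bed = pd.read_csv(
        cen_path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    for _, row in bed.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if end <= start:
            raise ValueError(f"centromere {row['chrom']}: end {end} <= start {start}")
        cens[row["chrom"]] = (start, end)
    return GenomeLayout(chromosomes=chromosomes, centromeres=cens)


@dataclass(frozen=True)
class ReadCountSummary:
    """Total mapped read counts entering the occupancy ratio."""

    input_exp: float
    input_cal: float
    ip_exp: float
    ip_cal: float


def occupancy_ratio(counts: ReadCountSummary) -> float:
    """OR = (INPUT_cal × IP_exp) / (INPUT_exp × IP_cal)."""
    for name in ("input_exp", "ip_cal"):
        if getattr(counts, name) <= 0:
            raise ValueError(f"occupancy ratio undefined: {name} is zero")
    if counts.input_cal < 0 or counts.ip_exp < 0:
        raise ValueError("read counts must be nonnegative")
    return (counts.input_cal * counts.ip_exp) / (counts.input_exp * counts.ip_cal)


@dataclass
class CalibratedTrack:
    """Per-bin coverage on the experimental genome, scaled by OR.

    ``values[chrom]`` holds one value per ``bin_bp`` bin tiling the chromosome
    from position 0; the final bin may be partial.
    """

    values: dict[str, np.ndarray]
    bin_bp: int
    or_used: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_bp <= 0:
            raise ValueError("bin width must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom, vals in self.values.items():
            starts = np.arange(len(vals)) * self.bin_bp
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + self.bin_bp,
                     "value": vals}
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bin_bp: int, or_used: float = 1.0) -> "CalibratedTrack":
        values = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            if np.any(starts != np.arange(len(starts)) * bin_bp):
                raise ValueError(f"bins on {chrom} do not tile from 0 at width {bin_bp}")
            values[str(chrom)] = grp["value"].to_numpy(dtype=float)
        return cls(values=values, bin_bp=bin_bp, or_used=or_used)


def calibrate_track(
    binned_counts: dict[str, np.ndarray], bin_bp: int, or_value: float
) -> CalibratedTrack:
    """Scale experimental per-bin IP counts by the occupancy ratio."""
    if or_value <= 0:
        raise ValueError("occupancy ratio must be positive")
    values = {c: np.asarray(v, dtype=float) * or_value for c, v in binned_counts.items()}
    return CalibratedTrack(values=values, bin_bp=bin_bp, or_used=or_value)


@dataclass
class PileupProfile:
    """Cross-chromosome (or cross-arm) mean ± SD per bin.

    ``bin_starts`` are relative to the anchor (centromere pileup) or pseudo
    coordinates (arm pileup); ``n`` counts the chromosomes/arms contributing
    to each bin (those whose window falls inside the chromosome).
    """

    bin_starts: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    bin_bp: int
    anchor: str  # 'centromere_midpoint' or 'arm_scaled'

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start_rel": self.bin_starts, "mean": self.mean, "sd": self.sd,
             "n": self.n}
        )


def _window_mean(
    track: CalibratedTrack, chrom: str, start: float, end: float
) -> float:
    """Base-pair weighted mean of track coverage over [start, end).

    Boundaries may be fractional (arm scaling produces proportional windows);
    partial bin overlaps are weighted by their exact extent.  The window must
    lie inside [0, chrom extent); the caller handles out-of-range windows as
    missing.
    """
    vals = track.values[chrom]
    w = track.bin_bp
    b0 = int(np.floor(start / w))
    b1 = int(np.ceil(end / w))
    total = 0.0
    for b in range(b0, min(b1, len(vals))):
        lo = max(start, b * w)
        hi = min(end, (b + 1) * w)
        if hi > lo:
            total += vals[b] * (hi - lo)
    return total / (end - start)


def pileup_centromere(
    track: CalibratedTrack,
    layout: GenomeLayout,
    flank_bp: int = 3000,
    bin_bp: int = 50,
) -> PileupProfile:
    """Average calibrated coverage around every centromere midpoint.

    Windows of ±``flank_bp`` are anchored at the floor midpoint of each
    centromere interval and kept in genomic orientation.  Bins that would
    extend past a chromosome end are missing for that chromosome and excluded
    from that bin's mean/SD (rather than zero-filled, which would bias flanks
    longer than a short arm).
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank must be a multiple of the bin width")
    n_bins = 2 * flank_bp // bin_bp
    starts_rel = np.arange(-flank_bp, flank_bp, bin_bp)
    stacked = np.full((len(track.values), n_bins), np.nan)
    row = 0
    for chrom in track.values:
        if chrom not in layout.centromeres:
            continue
        mid = layout.centromere_midpoint(chrom)
        chrom_len = layout.chromosomes[chrom]
        track_extent = len(track.values[chrom]) * track.bin_bp
        extent = min(chrom_len, track_extent)
        for j, rel in enumerate(starts_rel):
            a, b = mid + rel, mid + rel + bin_bp
            if a < 0 or b > extent:
                continue  # missing for this chromosome
            stacked[row, j] = _window_mean(track, chrom, a, b)
        row += 1
    stacked = stacked[:row]
    n = np.sum(~np.isnan(stacked), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=0)
    return PileupProfile(
        bin_starts=starts_rel, mean=mean, sd=sd, n=n, bin_bp=bin_bp,
        anchor="centromere_midpoint",
    )


def pileup_scaled_arms(
    track: CalibratedTrack,
    layout: GenomeLayout,
    pseudo_len_bp: int = 10000,
    bin_bp: int = 50,
) -> PileupProfile:
    """Average coverage over arms rescaled to a common pseudo length.

    Each arm is mapped linearly onto ``[0, pseudo_len_bp)`` oriented
    centromere → telomere (left arms reversed); each pseudo bin takes the
    base-pair weighted mean of the source coverage in its proportional
    window.  Arms shorter than the track's bin width are excluded with a
    warning.
    """
    if pseudo_len_bp % bin_bp != 0:
        raise ValueError("pseudo length must be a multiple of the bin width")
    n_bins = pseudo_len_bp // bin_bp
    starts = np.arange(0, pseudo_len_bp, bin_bp)
    rows = []
    for chrom, gstart, gend, side in layout.arms():
        if chrom not in track.values:
            continue
        arm_len = gend - gstart
        if arm_len < track.bin_bp:
            warnings.warn(
                f"arm {chrom}:{side} ({arm_len} bp) shorter than bin resolution; excluded",
                stacklevel=2,
            )
            continue
        extent = min(gend, len(track.values[chrom]) * track.bin_bp)
        profile = np.full(n_bins, np.nan)
        for j in range(n_bins):
            fa, fb = j / n_bins, (j + 1) / n_bins
            if side == "right":  # distance from centromere grows rightward
                a = gstart + fa * arm_len
                b = gstart + fb * arm_len
            else:  # left arm: centromere at gend, telomere at gstart
                a = gend - fb * arm_len
                b = gend - fa * arm_len
            a, b = max(float(gstart), a), min(float(extent), b)
            if b <= a:
                continue
            profile[j] = _window_mean(track, chrom, a, b)
        rows.append(profile)
    stacked = np.array(rows) if rows else np.empty((0, n_bins))
    n = np.sum(~np.isnan(stacked), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0) if len(rows) else np.full(n_bins, np.nan)
        sd = np.nanstd(stacked, axis=0, ddof=0) if len(rows) else np.full(n_bins, np.nan)
    return PileupProfile(
        bin_starts=starts, mean=mean, sd=sd, n=n, bin_bp=bin_bp, anchor="arm_scaled"
    )
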