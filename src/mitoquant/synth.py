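"""Seeded synthetic data with the statistical structure each stage assumes.

Three generators make the whole pipeline testable without any acquisition or
sequencing data:

* :func:`simulate_cell_stack` — anisotropic 3-D fields of yeast-like cells.
  Nuclei are axis-aligned ellipsoids with a soft (≈1 voxel cosine) DAPI edge;
  the Top2 channel splits total nuclear intensity between a uniform diffuse
  component and compact chromatin foci, with the focal fraction as the knob
  the CV readout must recover.  Anaphase scenes carry two DNA masses and an
  optional inter-mass bridge cylinder (DAPI and/or Nop1).  Camera noise is a
  scaled-Poisson photon term plus Gaussian read noise, both defaulting to off
  so every construction is exact.
* :func:`simulate_trajectories` — sister-locus distance dynamics of known
  category (not_separated / breathing / separated) built from sinusoidal
  breathing or linear separation drift plus clipped Gaussian jitter, with a
  hard guarantee that each trajectory classifies to its category.
* :func:`simulate_chip_counts` — two-genome spike-in ChIP read counts with a
  known occupancy ratio (the IP-efficiency ratio of the two genomes) and a
  Gaussian centromeric enrichment of chosen fold height.

Identical spec + seed gives bit-identical output everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chip import GenomeLayout, ReadCountSummary
from .locus_dynamics import classify_trajectory
from .stacks import ImageStack3D

__all__ = [
    "NoiseModel",
    "BridgeSpec",
    "SceneSpec",
    "TrajectorySpec",
    "ChipSimSpec",
    "ChipSimResult",
    "simulate_cell_stack",
    "simulate_trajectories",
    "simulate_chip_counts",
    "toy_layout",
]


# --------------------------------------------------------------------------
# image scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Fluorescence camera noise: scaled Poisson photons + Gaussian read noise.

    ``photon_scale`` is the intensity (a.u.) per detected photon; 0 disables
    the Poisson term.  ``read_sd`` is the additive Gaussian SD in a.u.
    """

    photon_scale: float = 0.0
    read_sd: float = 0.0


@dataclass(frozen=True)
class BridgeSpec:
    channel: str = "DAPI"  # 'DAPI', 'Nop1', or 'both'
    intensity: float = 8000.0
    radius_um: float = 0.15


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of cells.

    Defaults emulate spinning-disk acquisitions: 25 planes at 200 nm spacing
    over 65 nm pixels, so a 5 px expansion after isotropic resampling to
    65 nm spans 325 nm.
    """

    field_shape: tuple[int, int, int] = (25, 160, 160)
    spacing_nm: tuple[float, float, float] = (200.0, 65.0, 65.0)
    n_cells: int = 3
    nucleus_radius_um: float = 0.9
    top2_halo_scale: float = 1.6
    focal_fraction: float = 0.0
    n_foci: int = 4
    focus_radius_um: float = 0.15
    mean_intensity: float = 1000.0
    dapi_intensity: float = 2000.0
    nop1_intensity: float = 1500.0
    background: float = 0.0
    noise: NoiseModel = NoiseModel()
    anaphase: bool = False
    mass_separation_um: float = 2.5
    bridge: BridgeSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.focal_fraction <= 1.0):
            raise ValueError("focal_fraction must lie in [0, 1]")
        if self.n_cells < 1 or self.nucleus_radius_um <= 0 or self.mean_intensity < 0:
            raise ValueError("scene dimensions and intensities must be positive")
        if any(s <= 0 for s in self.spacing_nm) or any(n <= 0 for n in self.field_shape):
            raise ValueError("field shape and spacing must be positive")


def _ellipsoid_rho(shape, spacing_um, center_um, semi_um):
    """Normalized ellipsoidal radius of every voxel (1.0 on the surface)."""
    grids = [np.arange(n) * s for n, s in zip(shape, spacing_um)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij", sparse=True)
    return np.sqrt(
        ((zz - center_um[0]) / semi_um[0]) ** 2
        + ((yy - center_um[1]) / semi_um[1]) ** 2
        + ((xx - center_um[2]) / semi_um[2]) ** 2
    )


def _soft_edge(rho, edge_width_rel):
    """1 inside, cosine ramp to 0 across [1 - w, 1] in normalized radius."""
    out = np.zeros_like(rho)
    out[rho <= 1.0 - edge_width_rel] = 1.0
    ramp = (rho > 1.0 - edge_width_rel) & (rho <= 1.0)
    out[ramp] = 0.5 * (1 + np.cos(np.pi * (rho[ramp] - (1 - edge_width_rel)) / edge_width_rel))
    return out


def simulate_cell_stack(spec: SceneSpec):
    """Render one field of synthetic cells.

    Returns ``(stack, labels, truth)``: the multi-channel stack, a ground
    truth label volume (nucleus core voxels; in anaphase scenes both masses
    of a cell share its label), and a per-cell truth table with centroids,
    focal fraction, and total nuclear Top2 intensity.

    Nuclei overlapping the field boundary are rejected and resampled; if no
    non-overlapping placement exists after many attempts the packing is
    declared impossible.
    """
    # independent substreams so geometry is matched across focal fractions
    # and noise settings of otherwise identical specs
    _geom, _foci, _noise = np.random.SeedSequence(spec.seed).spawn(3)
    rng = np.random.default_rng(_geom)
    rng_foci = np.random.default_rng(_foci)
    rng_noise = np.random.default_rng(_noise)
    shape = spec.field_shape
    spacing_um = np.array(spec.spacing_nm) * 1e-3
    extent_um = (np.array(shape) - 1) * spacing_um
    r = spec.nucleus_radius_um

    # place cells: centers of single nuclei, or of mass pairs in anaphase
    halo = spec.top2_halo_scale
    margin = np.full(3, r * halo * 1.1 + 0.2)
    if spec.anaphase:  # mass pairs extend in-plane by half the separation
        margin[1:] += 0.5 * spec.mass_separation_um
    clearance = 2.0 * halo * r + 0.5  # perinuclear Top2 halos must not touch
    if spec.anaphase:
        clearance += spec.mass_separation_um
    centers = []
    attempts = 0
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > 5000:
            raise ValueError(
                f"cannot pack {spec.n_cells} cells into the field without overlap"
            )
        lo = np.minimum(margin, extent_um / 2)
        hi = extent_um - lo
        if np.any(hi < lo):
            raise ValueError("field too small for the requested nucleus radius")
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - c2) >= clearance for c2 in centers):
            centers.append(c)

    dapi = np.zeros(shape)
    top2 = np.zeros(shape)
    nop1 = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    edge_rel = float(min(spacing_um)) / r  # ~1 fine voxel of soft edge
    truth_rows = []
    cell_mass_centers: list[list[np.ndarray]] = []

    for i, center in enumerate(centers, start=1):
        aniso = rng.uniform(0.9, 1.1, size=3)
        semi = r * aniso
        if spec.anaphase:
            direction = np.array([0.0, *rng.normal(size=2)])
            direction /= np.linalg.norm(direction[1:])
            offset = 0.5 * spec.mass_separation_um * direction
            mass_centers = [center - offset, center + offset]
        else:
            mass_centers = [center]
        cell_mass_centers.append([np.array(mc) for mc in mass_centers])
        nuc_mask = np.zeros(shape, dtype=bool)
        halo_mask = np.zeros(shape, dtype=bool)
        for mc in mass_centers:
            rho = _ellipsoid_rho(shape, spacing_um, mc, semi)
            dapi += spec.dapi_intensity * _soft_edge(rho, edge_rel)
            nuc_mask |= rho <= 1.0
            halo_mask |= rho <= halo  # Top2 occupies the nucleus + perinuclear rim
        labels[nuc_mask] = i
        n_vox = int(nuc_mask.sum())
        n_halo = int(halo_mask.sum())
        if n_vox == 0:
            raise ValueError("nucleus fell between voxels; enlarge radius or field")
        total = spec.mean_intensity * n_vox

        # diffuse component: uniform over the halo domain, carrying
        # (1 - focal_fraction) of the cell's total Top2 intensity
        top2[halo_mask] += (1.0 - spec.focal_fraction) * total / n_halo
        # focal component: spherical foci well inside the (first) mass
        if spec.focal_fraction > 0 and spec.n_foci > 0:
            focus_sets = []
            for _ in range(spec.n_foci):
                mc = mass_centers[rng_foci.integers(len(mass_centers))]
                u = rng_foci.normal(size=3)
                u /= np.linalg.norm(u)
                fc = mc + u * rng_foci.uniform(0, 0.5) * min(semi)
                frho = _ellipsoid_rho(shape, spacing_um, fc, (spec.focus_radius_um,) * 3)
                fset = (frho <= 1.0) & nuc_mask
                if fset.any():
                    focus_sets.append(fset)
            if not focus_sets:  # foci smaller than a voxel: drop all on centroid voxel
                idx = tuple(np.round(mass_centers[0] / spacing_um).astype(int))
                fset = np.zeros(shape, dtype=bool)
                fset[idx] = True
                focus_sets = [fset]
            per_focus = spec.focal_fraction * total / len(focus_sets)
            for fset in focus_sets:
                top2[fset] += per_focus / int(fset.sum())

        # nucleolar sub-mass: crescent at the rim of the last mass
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        nop_center = mass_centers[-1] + 0.55 * u * min(semi)
        nrho = _ellipsoid_rho(shape, spacing_um, nop_center, 0.5 * semi)
        nop1 += spec.nop1_intensity * _soft_edge(nrho, 2 * edge_rel)

        truth_rows.append(
            {
                "cell": i,
                "cz_um": center[0], "cy_um": center[1], "cx_um": center[2],
                "n_core_voxels": n_vox,
                "total_top2": total,
                "focal_fraction": spec.focal_fraction,
                "mean_intensity": spec.mean_intensity,
            }
        )

    # optional bridge cylinder between the two masses of each anaphase cell
    if spec.bridge is not None:
        if not spec.anaphase:
            raise ValueError("bridge requires an anaphase scene (two masses per cell)")
        sel_channels = {
            "DAPI": [dapi], "Nop1": [nop1], "both": [dapi, nop1]
        }[spec.bridge.channel]
        grids = [np.arange(n) * s for n, s in zip(shape, spacing_um)]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        for p0, p1 in ((mc[0], mc[1]) for mc in cell_mass_centers):
            seg = p1 - p0
            seg_len = float(np.linalg.norm(seg))
            u = seg / seg_len
            rel = np.stack([zz - p0[0], yy - p0[1], xx - p0[2]], axis=-1)
            s = rel @ u
            radial = np.linalg.norm(rel - s[..., None] * u, axis=-1)
            cyl = (s >= 0) & (s <= seg_len) & (radial <= spec.bridge.radius_um)
            for ch in sel_channels:
                np.maximum(ch, np.where(cyl, spec.bridge.intensity, 0.0), out=ch)

    channels = {"DAPI": dapi, "Top2": top2, "Nop1": nop1}
    for name, img in channels.items():
        img += spec.background
        if spec.noise.photon_scale > 0:
            img[:] = rng_noise.poisson(img / spec.noise.photon_scale) * spec.noise.photon_scale
        if spec.noise.read_sd > 0:
            img += rng_noise.normal(0.0, spec.noise.read_sd, size=img.shape)
        np.clip(img, 0, None, out=img)

    stack = ImageStack3D(channels=channels, spacing_nm=spec.spacing_nm,
                         meta={"seed": spec.seed})
    return stack, labels, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# locus trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Distance-dynamics parameters for one trajectory category.

    The default sampling cadence is one frame per 3 minutes.  Jitter is a
    Gaussian clipped at ±3 SD so category guarantees are deterministic, not
    merely high-probability: with the defaults, breathing peaks reach
    amplitude − 3·SD > 2 µm and troughs stay within 3·SD ≤ ε.
    """

    category: str = "not_separated"
    n_timepoints: int = 40
    dt_min: float = 3.0
    amplitude_um: float = 0.8
    period_min: float | None = None  # default 4·dt: samples hit peaks/zeroes
    separation_speed_um_min: float = 0.05
    noise_sd_um: float = 0.05
    sep_thr_um: float = 2.0
    eps_um: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in {"not_separated", "breathing", "separated"}:
            raise ValueError(f"unknown category {self.category!r}")
        if self.n_timepoints < 2 or self.dt_min <= 0 or self.noise_sd_um < 0:
            raise ValueError("invalid trajectory dimensions")


def _clipped_normal(rng, sd, size):
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size), -3 * sd, 3 * sd)


def simulate_trajectories(spec: TrajectorySpec, n_cells: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n_cells`` distance series of the requested category.

    Returns a list of ``(t_min, distances_um)`` pairs.  Every series is
    verified against the classification rule at generation time; parameters
    that cannot guarantee the category (e.g. noise too large relative to the
    rejoin tolerance) raise immediately.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sd, eps, thr = spec.noise_sd_um, spec.eps_um, spec.sep_thr_um
    if 3 * sd > eps:
        raise ValueError("noise SD too large: troughs cannot be guaranteed <= eps")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_timepoints) * spec.dt_min
    period = spec.period_min if spec.period_min is not None else 4 * spec.dt_min
    out = []
    for _ in range(n_cells):
        jitter = _clipped_normal(rng, sd, spec.n_timepoints)
        if spec.category == "not_separated":
            if spec.amplitude_um + 3 * sd >= thr:
                raise ValueError("amplitude + noise reaches the separation threshold")
            base = spec.amplitude_um * np.abs(np.sin(2 * np.pi * t / period))
            d = base + np.abs(jitter)
        elif spec.category == "breathing":
            amp = max(spec.amplitude_um, thr + 6 * sd + 0.1)  # peaks must clear thr
            base = amp * np.abs(np.sin(2 * np.pi * t / period))
            d = np.where(base <= eps, np.abs(jitter), base + jitter)
        else:  # separated: linear drift from near zero past the threshold
            speed = spec.separation_speed_um_min
            needed = (thr + 6 * sd + 0.1) / (t[-1] * 0.75) if t[-1] > 0 else np.inf
            speed = max(speed, needed)
            base = speed * t
            d = np.abs(np.where(base <= eps, np.abs(jitter), base + jitter))
        d = np.clip(d, 0.0, None)
        call = classify_trajectory(d, t, sep_thr=thr, eps=eps)
        if call.klass != spec.category:
            raise ValueError(
                f"generated series classified as {call.klass!r}, wanted "
                f"{spec.category!r}; noise incompatible with category guarantee"
            )
        out.append((t, d))
    return out


# --------------------------------------------------------------------------
# spike-in ChIP counts
# --------------------------------------------------------------------------

def toy_layout(n_chrom: int = 16, chrom_len: int = 200_000, cen_width: int = 120,
               cen_at: float = 0.4) -> GenomeLayout:
    """Small regular genome for simulations: equal chromosomes, off-center
    centromeres (so left and right arms differ)."""
    chromosomes = {}
    cens = {}
    for i in range(1, n_chrom + 1):
        name = f"chr{i}"
        chromosomes[name] = chrom_len
        mid = int(cen_at * chrom_len)
        cens[name] = (mid - cen_width // 2, mid - cen_width // 2 + cen_width)
    return GenomeLayout(chromosomes=chromosomes, centromeres=cens)


@dataclass(frozen=True)
class ChipSimSpec:
    """Two-genome spike-in ChIP simulation.

    ``spike_mix`` is the calibration:experimental cell ratio (1.0 = the 1:1
    mix).  IP efficiencies are the per-genome fractions of chromatin
    recovered by the immunoprecipitation; their ratio
    ``ip_efficiency_exp / ip_efficiency_cal`` is the ground-truth occupancy
    ratio the estimator must recover.  The experimental IP coverage profile
    is flat background plus a Gaussian peak of fold height ``enrichment`` at
    every centromere midpoint.
    """

    layout_exp: GenomeLayout = field(default_factory=toy_layout)
    cal_genome_bp: int = 1_200_000
    spike_mix: float = 1.0
    ip_efficiency_exp: float = 0.10
    ip_efficiency_cal: float = 0.10
    total_input_reads: int = 1_000_000
    total_ip_reads: int = 1_000_000
    enrichment: float = 5.0
    peak_width_bp: float = 500.0
    background: float = 1.0  # relative reads per bp off-peak
    bin_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_mix <= 0 or self.ip_efficiency_exp <= 0 or self.ip_efficiency_cal <= 0:
            raise ValueError("mix and IP efficiencies must be positive")
        if self.total_input_reads <= 0 or self.total_ip_reads <= 0:
            raise ValueError("read totals must be positive (zero denominators otherwise)")
        if self.enrichment < 1 or self.background <= 0 or self.peak_width_bp <= 0:
            raise ValueError("enrichment >= 1, background and peak width > 0 required")

    @property
    def expected_or(self) -> float:
        """Closed-form expectation of the occupancy ratio.

        INPUT reads split between genomes in proportion to chromatin mass
        (cells × genome length); IP reads in proportion to mass × IP
        efficiency.  The mass terms cancel in the OR, leaving the efficiency
        ratio."""
        return self.ip_efficiency_exp / self.ip_efficiency_cal


@dataclass
class ChipSimResult:
    summary: ReadCountSummary
    bins_ip_exp: dict[str, np.ndarray]
    bins_input_exp: dict[str, np.ndarray]
    bin_bp: int
    true_or: float


def _bin_weights(spec: ChipSimSpec) -> dict[str, np.ndarray]:
    """Expected relative IP coverage per bin on the experimental genome."""
    weights = {}
    lay = spec.layout_exp
    for chrom, length in lay.chromosomes.items():
        n_bins = int(np.ceil(length / spec.bin_bp))
        starts = np.arange(n_bins) * spec.bin_bp
        widths = np.minimum(starts + spec.bin_bp, length) - starts
        centers = starts + widths / 2.0
        w = spec.background * widths.astype(float)
        if chrom in lay.centromeres:
            mid = lay.centromere_midpoint(chrom)
            bump = (spec.enrichment - 1.0) * np.exp(
                -0.5 * ((centers - mid) / spec.peak_width_bp) ** 2
            )
            w *= 1.0 + bump
        weights[chrom] = w
    return weights


def simulate_chip_counts(spec: ChipSimSpec) -> ChipSimResult:
    """Draw the four read totals and per-bin experimental counts.

    Genome totals are multinomial over chromatin mass (INPUT) or mass ×
    IP efficiency (IP); experimental per-bin counts are multinomial over the
    background-plus-peak profile (IP) or uniform (INPUT).
    """
    rng = np.random.default_rng(spec.seed)
    g_exp = float(sum(spec.layout_exp.chromosomes.values()))
    mass_exp = g_exp
    mass_cal = spec.spike_mix * spec.cal_genome_bp
    p_input = np.array([mass_exp, mass_cal])
    p_input /= p_input.sum()
    input_exp, input_cal = rng.multinomial(spec.total_input_reads, p_input)
    p_ip = np.array([mass_exp * spec.ip_efficiency_exp, mass_cal * spec.ip_efficiency_cal])
    p_ip /= p_ip.sum()
    ip_exp, ip_cal = rng.multinomial(spec.total_ip_reads, p_ip)

    weights = _bin_weights(spec)
    chroms = list(weights)
    flat = np.concatenate([weights[c] for c in chroms])
    p_bins = flat / flat.sum()
    ip_counts = rng.multinomial(int(ip_exp), p_bins)
    widths = np.concatenate(
        [np.minimum(np.arange(len(weights[c])) * spec.bin_bp + spec.bin_bp,
                    spec.layout_exp.chromosomes[c])
         - np.arange(len(weights[c])) * spec.bin_bp for c in chroms]
    ).astype(float)
    input_counts = rng.multinomial(int(input_exp), widths / widths.sum())

    def split(arr):
        out, i = {}, 0
        for c in chroms:
            n = len(weights[c])
            out[c] = arr[i : i + n].astype(float)
            i += n
        return out

    summary = ReadCountSummary(
        input_exp=float(input_exp), input_cal=float(input_cal),
        ip_exp=float(ip_exp), ip_cal=float(ip_cal),
    )
    return ChipSimResult(
        summary=summary,
        bins_ip_exp=split(ip_counts),
        bins_input_exp=split(input_counts),
        bin_bp=spec.bin_bp,
        true_or=spec.expected_or,
    )
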