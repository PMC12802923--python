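# Methods

Models, conventions, parameter defaults, and numerical choices behind each
`mitoquant` component, plus the scope and limits of the synthetic-data
generators.

## Image model and conventions

Stacks (`mitoquant.stacks.ImageStack3D`) are dictionaries of equally shaped
3-D float arrays, axis order (z, y, x), with physical voxel spacing in nm per
axis. The default acquisition geometry is 25 planes at 200 nm spacing over
65 nm pixels. On disk a stack is a multi-page float32 TIFF (one series per
channel, channels in sorted name order) plus a plain-text sidecar
`<name>.tif.spacing.tsv` carrying the spacing and channel names; reading
without a sidecar requires an explicit spacing. All genomic coordinates are
0-based half-open (BED convention); all distances inside the imaging code are
µm unless a name says otherwise.

## Top2 nuclear localization

Pipeline: resample → blur → Multi-Otsu → volume filter → mask expansion →
per-nucleus statistics.

1. **Isotropic resampling** (`resample_isotropic`). Output voxel `j` samples
   physical position `j · target` by trilinear interpolation
   (`scipy.ndimage.map_coordinates`, order 1); the new axis length is
   `floor((n−1)·spacing/target) + 1`, so the sampled region never
   extrapolates beyond the original grid. Default target 65 nm. Resampling
   to a grid coarser than the finest input axis warns.
2. **Segmentation** (`segment_nuclei`). The DAPI channel is Gaussian-blurred
   with σ = 2 px, histogrammed (128 bins), and split into 4 intensity classes
   by Multi-Otsu; the top 2 classes are foreground. Connected components use
   26-connectivity. Components outside 0.5–15 µm³ are discarded (specks and
   fused clumps).
3. **Multi-Otsu** (`multi_otsu_thresholds`). Exhaustive search over all
   threshold tuples maximizing the between-class criterion Σ S²/W (equivalent
   to minimizing within-class variance), vectorized over histogram prefix
   sums. Ties break toward the lexicographically smallest tuple, and a
   returned threshold is the value of the **first bin of the upper class**
   (voxels with value ≥ threshold fall above it). scikit-image's
   implementation reports the last bin of the lower class instead; the two
   agree on the achieved objective, which is what the tests compare.
4. **Mask expansion** (`expand_labels_euclidean`). Each label grows by a
   Euclidean radius (default 5 px = 325 nm at 65 nm/px): a background voxel
   joins the label with the nearest core voxel if that distance is ≤ radius;
   equidistant voxels go to the lower label id. Implemented as one exact
   Euclidean distance transform per label with a running minimum — O(labels ×
   volume), exact, and adequate for the tens of nuclei per field this
   pipeline sees.
5. **Statistics** (`measure_nucleus_signal`). Over the expanded mask: MFI
   (mean), SD (population, ddof = 0 — a descriptive statistic of the voxel
   set, not an estimator), CV = SD/MFI (undefined with a warning when
   MFI = 0). Diffuse Top2 gives CV ≈ 0; focal accumulation raises CV.

## Anaphase-bridge scoring

`locate_dna_masses` segments the DAPI channel keeping only the brightest
Multi-Otsu class (`foreground_classes=1`) so a dimmer bridge cannot fuse the
two masses, and takes the two largest components. `bridge_statistic` walks
1-voxel slabs along the inter-centroid axis restricted to the central 60%
(`core_fraction=0.6`, avoiding the bright mass ends), takes the maximum
intensity within a 0.5 µm radius of the axis in each slab, and returns the
minimum over slabs: a continuous bridge must keep signal in *every*
cross-section, so one dark slab (a gap) kills the statistic. Classification
is strict exceedance: DAPI > 4000 a.u. and/or Nop1 > 5200 a.u. give
`dapi_bridge` / `nucleolar_bridge` / `double_bridge`; otherwise `negative`.
Cells without two separated DNA masses raise `NotAnaphase`.

## Locus separation dynamics

`distance_series` turns paired dot positions into distances; timepoints with
both dots missing are dropped with a warning, and a single resolved dot means
the dots are unresolved, i.e. distance 0. `classify_trajectory` applies the
rule: never above 2 µm → `not_separated`; above 2 µm then later ≤ 0.25 µm →
`breathing`; above 2 µm and never back → `separated`. The 0.25 µm tolerance
absorbs localization noise on "rejoined" dots. The partition property —
`breathing ∪ separated ⇔ max distance > 2 µm` — holds by construction.

## Spike-in calibrated ChIP-seq

Occupancy ratio OR = (INPUT_cal × IP_exp) / (INPUT_exp × IP_cal) from total
mapped read counts; zero denominators raise naming the offending term.
Multiplying experimental per-bin IP coverage by OR puts samples on a common
absolute scale (the chromatin-mass terms cancel, so OR is independent of the
spike-in mix; for the simulation it equals the IP-efficiency ratio).

**Centromere pileups** anchor windows at the floor midpoint
`(start + end) // 2` of each centromere interval, defaults ±3 kb at 50 bp
bins (120 bins) or ±80 kb at 500 bp (320 bins). Bins extending past a
chromosome end are **missing** for that chromosome and excluded from that
bin's mean/SD — zero-filling would drag flank means toward zero wherever a
flank outruns a short arm. SD is the population SD across contributing
chromosomes.

**Scaled-arm pileups** map each arm linearly onto a 10 kb pseudo-axis
oriented centromere → telomere (left arms reversed), 50 bp pseudo-bins. Each
pseudo-bin takes the base-pair weighted mean of source coverage over its
*fractional* proportional window — boundaries are kept as floats and partial
bin overlaps weighted by exact extent, which preserves left/right mirror
symmetry exactly (integer snapping would break it and put spurious SD on
perfectly symmetric tracks). Arms shorter than the track bin width are
excluded with a warning.

## Statistics

Kruskal–Wallis and Mann–Whitney U delegate to scipy; arcsine tests to
scipy's t-tests after y = arcsin(√p). Conventions: all-identical KW groups
return H = 0, p = 1 (scipy raises); MWU uses the exact null distribution iff
both n, m ≤ 8 and there are no ties, else the normal approximation with
continuity and tie correction — the exact two-sided p is
min(1, 2·min(P(U≤u), P(U≥u))), verified against full enumeration. Post-hoc
MWU pairs support Holm and Bonferroni adjustment (statsmodels). Zero-variance
paired arcsine tests return t = 0, p = 1 with a warning.

## Synthetic generators: scope and guarantees

The generators exist to make every claim testable against known ground truth;
they are simplified optical phantoms, not microscope models.

**Cell fields** (`SceneSpec`). Nuclei are ellipsoids placed by rejection
sampling (clearance keeps halos disjoint; impossible packings raise after
5000 attempts). DAPI has a soft cosine edge. Top2 is a diffuse component
spread over a perinuclear halo ellipsoid (1.6× the nuclear radius, so the
5 px expanded mask stays inside signal) plus `n_foci` spheres; a focal
fraction `ff` moves exactly that share of the per-cell total into foci, so
total Top2 intensity is conserved across `ff` **by construction**, and the
RNG is split into geometry/foci/noise substreams so scenes with different
`ff` share identical geometry at the same seed. Anaphase scenes place two
masses per cell (optionally connected by a cylindrical bridge in DAPI, Nop1,
or both); Nop1 forms a crescent. Noise is scaled-Poisson photons plus
Gaussian read noise. Not modeled: PSF blur along z, vignetting, bleaching,
chromatic shift.

**Trajectories** (`TrajectorySpec`). Category templates (flat, sinusoidal
with period 4·dt so samples hit peaks and zero crossings, linear divergence)
plus Gaussian jitter clipped at ±3 SD, making category guarantees
deterministic rather than probabilistic; parameter combinations that cannot
guarantee the category (e.g. noise 3·SD exceeding the rejoin tolerance)
raise at construction, and every generated series is re-checked against the
classifier before being returned.

**ChIP counts** (`ChipSimSpec`). Input totals are multinomial across the two
genomes in proportion to chromatin mass (cells × genome bp); IP totals in
proportion to mass × IP efficiency; per-bin experimental IP counts are
multinomial over background × (1 + (E−1)·Gaussian(centromere midpoint)).
Expected OR = ip_efficiency_exp / ip_efficiency_cal in closed form,
independent of the spike-in mix. Fragment-length effects, mappability, and
PCR duplicates are not modeled.

## Reproducibility

Every stochastic element is seeded through `numpy.random.default_rng` /
`SeedSequence` substreams. The demo pipeline's YAML config (unknown keys
rejected with their path) plus seed fully determine all outputs; each CSV
records `config_hash` (sha256 of the sorted config, output directory
excluded) and seed in a comment header, and reruns are byte-identical
(`float_format="%.10g"` pins the text rendering).

## Parameter defaults

| Parameter | Default | Where |
|---|---|---|
| Isotropic target | 65 nm | `quantify_stack(target_nm=)` |
| Blur σ | 2 px | `segment_nuclei(sigma_px=)` |
| Otsu classes / foreground | 4 / top 2 | `segment_nuclei` |
| Nucleus volume bounds | 0.5–15 µm³ | `segment_nuclei(volume_bounds_um3=)` |
| Mask expansion | 5 px (325 nm) | `expand_masks(radius_px=)` |
| Bridge cylinder radius | 0.5 µm | `bridge_statistic(r_um=)` |
| Bridge core fraction | 0.6 | `bridge_statistic(core_fraction=)` |
| DAPI / Nop1 thresholds | 4000 / 5200 a.u. | `BridgeThresholds` |
| Separation threshold / rejoin ε | 2 / 0.25 µm | `classify_trajectory` |
| Centromere flank / bin | ±3 kb / 50 bp (alt ±80 kb / 500 bp) | `pileup_centromere` |
| Arm pseudo-length / bin | 10 kb / 50 bp | `pileup_scaled_arms` |
| MWU exact-path limit | n, m ≤ 8, no ties | `mann_whitney` |

## Limitations

- Segmentation assumes DAPI-bright, roughly convex, well-separated nuclei;
  heavily overlapping nuclei merge (the volume filter then drops them).
- The bridge statistic assumes a roughly straight inter-mass axis; strongly
  curved bridges leaving the 0.5 µm cylinder are missed.
- Per-label EDT expansion is exact but O(labels × volume); for fields with
  thousands of labels a multi-source transform would be preferable.
- Intensity thresholds (4000/5200 a.u.) are instrument-specific constants;
  apply them only to identically scaled data.
- Generators validate the analysis logic, not biological realism; recovered
  quantities (CV, OR, enrichment) are exact only with respect to the
  generative models above.
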