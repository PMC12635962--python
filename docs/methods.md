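# Methods

## Problem and model

A phase-separated giant unilamellar vesicle (PS-GUV) imaged at its
equator is a thin bright ring.  The lipid marker channel (a rhodamine
lipid that partitions into the liquid-disordered phase) labels Ld arcs;
Lo arcs are marker-dark up to a small bleed-through floor.  The DNA
channel reports membrane-bound DNA.  For one vesicle the quantities of
interest are the mean DNA intensities over the two phases,
I_Lo and I_Ld, both background-subtracted, and the derived statistics

    log FC = log2(I_Lo / I_Ld)
    SPI    = I_Lo / (I_Lo + I_Ld) * 100 %

which satisfy SPI = 100·2^logFC/(1 + 2^logFC) identically.  log FC = 0
and SPI = 50 % are the no-preference references.  Only vesicles with
coexisting phases enter these statistics; everything else is retained
with `qc_pass = False`.

Condition-level results are aggregated in two stages: per-GUV values are
averaged within each replicate, then the condition mean and sample
standard deviation (ddof = 1) are taken across replicate means.  A
replicate with fewer than `min_guvs_per_replicate` (default 20) passing
vesicles flags the condition (`replicate_ok = False`).  No hypothesis
testing is performed; the outputs are descriptive means ± SD.

Ionic-strength helpers implement I = ½ Σ c_i z_i² (mM) and its inversion
c = 2I/z² for a single species, used to construct cation conditions of
equal ionic strength (0.5 mM divalent ≡ 2 mM monovalent ≡ 0.22 mM
trivalent).

## Detection

Detection operates on the sum of both channels, so Lo arcs that are
marker-dark still contribute through bound DNA and vice versa.  Stages:

1. Gaussian smoothing (`detect_smooth_sigma`, default 2 px) and Canny
   edges on the min-max normalized image.
2. Circular Hough transform over the configured radius range
   (`radius_min_um`–`radius_max_um`, default 5–50 um, converted to pixels
   via `pixel_size_um`).  The accumulator only *shortlists* candidates
   (floor 0.25): with dense noise edges the accumulator value of a small
   circle can reach ~0.5 without any ring present, so it cannot be the
   acceptance statistic.
3. Concentric-candidate deduplication keeps, per center, the radius with
   the highest mean annular gradient magnitude (selects the membrane, not
   the halo).
4. Active-ring refinement on a lightly smoothed image (sigma 1 px): the
   image is sampled on a polar grid around the current circle; each ray's
   annular intensity centroid r_c(theta) is fitted to the first-order
   circle model r + dx·cos(theta) + dy·sin(theta) by least squares, and
   the center/radius are updated (up to 6 iterations, steps clamped to
   2–3 px).  Rays carry weight proportional to their background-subtracted
   intensity, so a ring that is bright over only part of its circumference
   (strongly one-sided partitioning) still refines correctly from the
   bright arc alone.
5. The **detection score** is the intensity-weighted fraction of rays
   that are *ring-coherent*: radial centroid within 1.5 px of the fitted
   circle AND at least 70 % of the ray's intensity mass within the
   annulus half-width of it.  A genuine membrane scores near 1 even at
   SNR 3; a circle hallucinated from noise spreads its mass evenly over
   the sampling band (mass fraction ~0.5 per ray) and scores well below
   the default `score_threshold` of 0.6.  The background reference for
   ray profiles is the median of the smoothed image, which is
   pedestal-free because rings occupy a small area fraction.

Rings whose annulus leaves the frame are flagged `edge_clipped`; pairs
with center distance below `overlap_factor`·(r1+r2) are flagged
`overlapping`.  `filter_rings` removes clipped and low-score rings and
keeps overlapping ones (their shared sectors are masked downstream).

On the synthetic benchmark (SNR ≥ 5, in-range, non-overlapping) this
detector reaches recall 1.0 and FDR 0 with centers within ~0.2 px and
radii within ~1.3 % — comfortably inside the 2 px / 5 % targets the test
suite enforces.  Detection degrades gracefully at SNR 3 (some vesicles
are missed; none are invented).

## Profiling

The membrane annulus (|r − radius| ≤ `annulus_halfwidth_px`, default 3 px
≈ 1.1 um at the 378.79 nm pixel size) is divided into `n_bins` equal
angular sectors (default 180, i.e. 2° bins, ≥ ~5 px per bin at typical
radii).  A pixel belongs to the sector containing its center angle —
hard membership, no fractional weighting — so each annulus pixel
contributes to exactly one bin and per-channel means are exactly linear
in the pixel values.  Bins with no in-bounds pixels, or with any pixel
inside another detected ring's disc, are invalid.

Background is a per-channel scalar per vesicle: the median of an exterior
annulus from radius + 3·halfwidth to radius + 5·halfwidth, excluding
pixels inside other rings, falling back to the image-wide 5th percentile
when fewer than 50 exterior pixels remain.  Backgrounds are stored, not
subtracted, in the profile; subtraction happens in the metrics stage so
raw values stay inspectable.  Per-bin backgrounds were rejected: GUV
fields are flat at the relevant scale and per-bin estimates would be
noise-dominated.

## Segmentation

Valid-bin marker means (background-subtracted) are split per vesicle by
exact two-class variance maximization over the sorted values (no
histogram); the threshold is the midpoint of the two class means.  The
exact formulation makes the rule mirror-symmetric, so inverting the
marker contrast swaps the Lo/Ld labels bin for bin — a property the test
suite checks and that a 256-bin histogram Otsu does not guarantee.

A **bimodality gate** protects single-phase vesicles from being split
along their noise: the between-class variance fraction eta² at the chosen
split must reach `min_bimodality` (default 0.75).  Unimodal Gaussian data
tops out near 2/pi ≈ 0.64 (empirical p99 ≈ 0.70 at the default binning),
while genuine two-phase profiles stay above ~0.78 even at SNR 3 thanks to
the ~20:1 marker contrast between phases.  Profiles under the gate are
labeled single-phase (all-LD by convention; coexistence fails either
way).

Labels are then cleaned on the circular sequence of valid bins: maximal
same-label runs shorter than `min_run_bins` (default 5, i.e. 10°) are
absorbed into the longer flanking run (shortest run first, ties to the
first in scan order, flank ties to the preceding run).  Finally
`boundary_guard_bins` (default 1) on each side of every Lo/Ld transition
are relabeled EXCLUDED, because the PSF mixes phases at domain
boundaries and would bias both phase means toward each other.

A vesicle is **coexistent** when each phase holds at least
`min_arc_fraction` (default 10 %) of the labeled arc.

## Metrics

I_Lo and I_Ld are bin-averaged (mean of per-bin means over each phase's
bins) rather than pixel-pooled, equalizing angular weighting when bins
hold unequal pixel counts; the whole-vesicle attachment intensity is the
mean over all valid bins.  Records with a non-coexistent labeling or a
non-positive subtracted phase mean get `qc_pass = False` and NaN ratio
metrics instead of undefined logarithms.  Whether the original analysis
averaged per vesicle or pooled intensities per condition is not
documented; per-GUV values are computed here (a per-GUV heatmap requires
them) and aggregation happens afterwards.  Heatmap sampling is a seeded
uniform draw without replacement among passing records (default 50), with
the seed recorded in the output header.

## Synthetic scenes

Each vesicle is background + amplitude(theta) · exp(−(r−R)²/(2·sigma_m²)),
with amplitude chosen per arc phase; the marker amplitude of Lo arcs is
5 % of Ld (a bleed-through floor rather than exact zero, so segmentation
must tolerate it).  The DNA amplitude ratio rho between Lo and Ld arcs is
the ground-truth partition ratio: true log FC = log2(rho), true
SPI = 100·rho/(1+rho).  The expected image is PSF-blurred (Gaussian,
sigma 1 px by default), then Poisson shot noise is applied to the
photon-count-like expectation and Gaussian read noise added.  SNR is
defined at the membrane peak as A/sqrt(A + background + read_sd²);
`amplitude_for_snr` inverts this.  Default geometry (radii 16–26 px ≈
6–10 um at the confocal pixel size, background 10 counts, membrane sigma
1.5 px) mirrors the imaging regime of the study; the benchmark covers
rho ∈ {¼, ½, 1, 2, 4} × Ld arc fraction ∈ {0.25, 0.5, 0.75} × SNR ∈
{3, 5, 10}, plus noiseless cases, an edge-clipped vesicle, a touching
pair and single-phase controls.  All randomness derives from one seed via
`numpy.random.SeedSequence` splitting, so each case is independently
reproducible and bit-identical across runs.

What the generator does **not** emulate: deformed or tubulated vesicles,
out-of-focus light, spatially varying background, chromatic misalignment
and camera fixed-pattern noise.  Passing tests therefore demonstrate
correctness of the estimators under the stated photometric model, not
robustness to every real-microscope artifact.

## Numerical choices

- **Noiseless exactness.**  With noise and PSF off, the recovered log FC
  equals log2(rho) to ~1e−13 on the suite's noiseless cases.  This is by
  construction: those cases place the ring center on a half-integer pixel
  position and the arc boundaries on the diagonals, making every 90°
  rotation of the pixel grid an exact symmetry with 0.5 px margins, so
  the per-bin radial sampling factors cancel exactly between phases.  At
  generic sub-pixel geometry the hard pixel-to-bin membership leaves a
  small aliasing residual (~1e−2 in log FC for a single vesicle, mean
  zero across vesicles); this is the cost of the exact-linearity sampling
  rule, not a defect of the estimator.
- Tie-breaks are deterministic throughout (first maximal split in the
  Otsu scan; shortest-then-first run in cleaning; preceding flank on
  donor ties), so reruns are byte-identical.
- Degenerate inputs: constant marker profiles yield a single-phase
  labeling; empty scenes yield empty detections; an annulus fully outside
  the image raises.
- Floats are written with 17 significant digits and parsed with
  round-trip precision, so record tables survive CSV I/O exactly.

## Problem sizes in the checked-in validation

The test suite and acceptance script use 160×160 to 220×220 px scenes,
1–3 vesicles each, 54-case benchmark suites and a 30-vesicle parameter
recovery at rho = 3 / SNR 8 — sizes chosen so the whole validation runs
in well under a minute while every stage (including detection on dozens
of noisy scenes) is exercised end to end.  Scaling to full micrograph
batches is linear in scene count and pixel count.

## Known limitations

- Single equatorial sections only: no z-stacks, no tracking, no
  photobleaching or z-attenuation correction.
- Circular geometry is assumed; deformed/tubulated vesicles (as occur at
  high Na⁺) are out of scope and should be excluded upstream.
- The detection and segmentation parameter defaults are documented
  stand-ins chosen for reproducibility on ring-like vesicles; the
  original study's exact workflow internals are not public, so parameter
  parity with it cannot be claimed — only agreement on the defined
  metrics under the stated model.
- Two phases only; no sub-resolution domain inference.
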