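# Methods

## The measurement problem

The retinal pigment epithelium (RPE) internalises the shed tips of
photoreceptor outer segments (OS) every day. In two-channel confocal
cryosections — one channel an opsin immunolabel, one an RPE label — these
internalised OS particles ("phagosomes") appear as small bright spots whose
label overlaps the RPE tissue. The quantity of interest per eye section is

    K = count / L * 10,

the number of detected phagosomes per 10 μm of RPE, where `L` is the length
of the RPE–OS interface in μm measured along a user-traced polyline.
Sections are collected at seven Zeitgeber times (ZT 1, 3, 5, 10, 16, 18, 23;
ZT0 = light onset, ZT14 = light offset) under a normal light–dark cycle (LD)
or constant darkness (DD), and the per-ZT density profiles are compared per
cone subtype (UV, blue, green, red).

## Detection pipeline

1. **Projection and denoising.** Each channel's z-stack is reduced to a
   maximum-intensity projection, then smoothed with a Gaussian (σ = 1 px,
   reflective boundary handling — fixed so results are bit-stable).
   Projection precedes denoising.
2. **RPE region.** Within a user-supplied ROI polygon, the RPE channel is
   thresholded by Li's minimum-cross-entropy method. The criterion — each
   side of the split contributes `-Σg · log(mean g)` — is minimised by an
   exhaustive scan over midpoints between consecutive distinct ROI
   intensities (prefix-sum evaluation, ties toward the lower threshold).
   The scan is exact and cannot stall in a secondary criterion minimum, at
   negligible cost for section-sized ROIs. The binarised image is opened
   with a disc `{(dr,dc): dr²+dc² ≤ r²}` of radius 6 px and intersected with
   the ROI. Binarisation is applied to the whole image before opening so
   the ROI boundary does not erode the mask artificially. An empty mask is
   valid (warned, zero detections).
3. **h-dome transform.** Bright local structure is extracted as
   `f − R_f(f − h)` where `R_f` is grayscale reconstruction-by-dilation of
   the marker `f − h` under mask `f` (8-connectivity). The dome image is
   bounded in `[0, h]`; `h = 15` intensity units by default. The fast
   reconstruction is required — and tested — to equal the naive
   iterate-to-convergence geodesic dilation exactly.
4. **Prominence maxima.** Peaks of the dome image are selected by
   topographic prominence: peak height minus the highest saddle connecting
   it to any higher region, computed by a union-find flood from the top
   level down; the last surviving component takes its prominence from the
   image minimum. Plateau maxima are reported at the plateau centroid
   rounded to the nearest pixel; equal-height twins connected by a lower
   saddle keep one representative (deterministic index tie-break). Edge
   maxima are retained. The default cutoff is 10; values ≥ 20 were found
   unreliable in practice, so the CLI refuses them without an explicit
   override flag.
5. **Masking and density.** Peaks outside the RPE mask are discarded; the
   survivors are counted and normalised per 10 μm of interface length. A
   manual count supplied in the manifest overrides the automated count and
   is flagged.

Detection runs on the full projection and the mask is applied afterwards,
avoiding reconstruction edge artifacts at the mask boundary. Touching
phagosomes are not split and no size/shape scoring is applied: the count is
the number of prominent maxima.

## Detection evaluation

Detections are matched one-to-one to ground-truth peaks within 3 px
(Euclidean), greedily in ascending distance with deterministic tie-breaks.
Matched = TP, unmatched detections = FP, unmatched truth = FN;
precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic mean.
Because spot detection has no true-negative count, the reported
"false-positive rate" is FP/(TP+FP) = 1 − precision; this definition is a
package choice and is stated wherever the value appears. Metrics with zero
denominators are flagged as undefined (`None`), never silently zero. Sweeps
over the default grid h ∈ {5, 15, 25, 50, 100} × prominence ∈
{5, 10, 20, 40, 80} pool TP/FP/FN over sections (micro-averaging — stable
when per-section counts are small). Greedy matching provably attains the
optimal assignment when truth points are separated by more than twice the
match radius; the test suite checks this against a maximum-bipartite-
matching oracle.

## Synthetic sections

`generate_section` renders, deterministically per seed:

- a horizontal RPE band (default rows 60–95 of a 160×256 image at
  0.31 μm/px), optionally bent sinusoidally to exercise the polyline length
  measurement; the RPE channel is bright (150) inside the band and dim (5)
  outside;
- an intact-OS confounder band (intensity 120, 20 rows) directly above the
  RPE band — it produces a large flat dome plateau whose centroid falls
  outside the RPE mask, which is exactly how the real pipeline rejects the
  intact OS layer;
- `n` isotropic 2-D Gaussian spots at integer positions inside the band
  (margin 8 px), amplitudes uniform in [60, 160] over a background of 10
  and widths uniform in [0.8, 1.6] px, emulating the strong size/intensity
  heterogeneity of real phagosomes;
- additive Gaussian noise (default sd 5), clipped at zero;
- two z-slices (the designed image and a 0.6× copy) so that maximum
  projection is exercised and reproduces the designed image exactly.

Spots are placed with ≥ 7 px mutual separation. Anything above 6 px makes
radius-3 matching unambiguous (each detection can match at most one truth
point); 7 px also guarantees every planted spot is a strict local maximum of
the noise-free image. With default amplitudes (≥ 60 > h + prominence = 25)
noise-free recovery is exact, and at noise sd 5 the pooled F1 stays ≥ 0.9 at
the default working point — the acceptance script recomputes both.

What the generator does **not** emulate: non-specific background labelling
and texture, out-of-focus light and PSF anisotropy, phagosome shape
irregularity, photobleaching, and 3-D structure across z. Passing tests
therefore demonstrate the correctness of the algorithmic chain and its
behaviour under additive noise and a bright confounder, not detection
performance on real cryosections, where the prominence threshold is chosen
per image.

## Synthetic time courses

`generate_timecourse` draws per-section densities around study-level means
keyed by (subtype, condition, ZT); the bundled defaults are the published LD
and DD mean-density tables. Each section draws a density from a normal
truncated at zero (inverse-CDF sampling, deterministic per seed) — densities
are non-negative reals, not raw counts — plus an RPE length uniform in
100–200 μm (chosen so per-section totals are comparable to the published
validation counts); the integer count is the nearest consistent value and
the recorded density is recomputed from it. Section-to-section variability
is not published; the default sd of 0.5 densities/10 μm makes the published
LD UV effect sizes detectable at n = 8 (power ≳ 0.99) without being
trivially noiseless, and is flagged as a package choice. Default n = 8
sections per point, the middle of the study's 4–12 range.

## Rhythm statistics

Per subtype and condition: Shapiro–Wilk normality (scipy, cross-validated
against R's `shapiro.test`), one-way ANOVA across the seven ZTs (classical
between/within decomposition; infinite F flagged when within-variance is
zero with unequal means), and Bonferroni post hoc tests using the pooled
within-group error term — all 21 pairs, and separately the six contrasts
against the ZT10 baseline (both reported, since either correction scope is
defensible). LD vs DD uses a condition × ZT factorial ANOVA with Type III
sums of squares on sum-to-zero contrasts (matching the convention of the
major commercial packages for unbalanced designs; verified against R
`car::Anova(type=3)`), followed by Bonferroni-adjusted per-ZT LD-vs-DD
contrasts on the factorial residual error.

Per-ZT mean profiles are normalised by their maximum (so the peak maps
to 1.0 — absolute densities are not comparable across subtypes because
antibody efficiency differs) and the UV, blue and green profiles are stacked
(range [0, 3]). The published combined-average column is reproduced by
`combined_average`, unweighted by default with optional user weights,
because the printed column is not the unweighted mean of the printed
subtype means and the original weights are not recoverable.

## Numerical choices and degenerate inputs

- Coordinates are (row, col), 0-based, everywhere.
- Connectivity is 8-neighbour for reconstruction, maxima and labelling.
- Li thresholding rejects constant ROIs; density rejects non-positive
  lengths; ANOVA requires ≥ 2 groups of ≥ 2; the interaction term requires
  ≥ 2 replicates per design cell and empty cells fail with the cell named.
- All generators use `numpy.random.default_rng(seed)`; identical spec+seed
  gives bit-identical output, and `run_study` reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script use desk-scale inputs: sections of
160×256 px with 25 spots, 200 random ≤ 64×64 images for the reconstruction
oracle, 20 noisy sections for recovery, two sections for the 25-point
parameter sweep, 1000 null simulations for type-I calibration and 200 for
power. These sizes give binomial standard errors of ~0.7 % on the
calibrated rates while keeping a full run under a minute.

## Known limitations

- The prominence threshold is global per image; the original workflow tuned
  it interactively per image, so absolute counts on difficult real images
  (e.g. the noisy red-opsin label, where the published manual-vs-automated
  differences reach 129 %) will require the manual-count override.
- No watershed splitting: two phagosomes closer than their dome merger
  appear as one maximum.
- Sections are treated as independent units (as in the source analysis);
  fish-level clustering is not modelled.
- `.czi` containers are not read; convert to OME-TIFF first (lossless for
  pixel data).
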