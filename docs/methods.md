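# Methods

## Phase-occupancy model

A tumor's cycling cells are assumed asynchronous and in steady state, so a
staining snapshot catches each cycling cell at a position uniform over
`[0, T_c)`. Phase occupancy is then proportional to phase duration, giving
`N_m / N_c = T_m / T_c` and, identifying PhH3 with mitotic cells and MIB-1
with cycling cells, `PhH3 / MIB-1 = T_m / (T_m + T_i)`. The model ignores G0
re-entry kinetics and cell death; both markers are treated as snapshots of
the same instant.

Growth is projected as `N = N0 · (1 + P)^(Δt / T_c)`: over one cycle the
non-proliferating fraction `1 − P` persists and the proliferating fraction
`P` doubles, multiplying the population by `1 + P`. The exponent rescales
elapsed time by cycle length. This form makes explicit that `P` alone
understates growth: P = 0.2 with T_c = 24 h outgrows P = 0.6 with T_c = 72 h
at every horizon, because `1.2^(1/24) > 1.6^(1/72)` per hour.

Marker windows generalize the identity: MIB-1 stains cycling cells with
sensitivity `s` (default 0.95 — the antigen is not expressed perfectly
throughout the cycle), PhH3 occupies a window ending at cytokinesis of
configurable length (default exactly `T_m`; phosphorylation actually begins
in late G2, so the window may exceed `T_m`), and morphologically
recognizable mitotic figures occupy a window of `0.8 · T_m` centered in M
with detection probability 0.9 (manual counting misses early prophases and
late telophases). The window and detection defaults are modeling choices,
config-exposed, not measurements.

## Synthetic cohorts

One tumor = (grade, proliferating fraction `p_cycling`, phase durations, DNA
index, nuclei per 10x field, number of imaged fields). Defaults, all
overridable in `CohortConfig`:

- **Grade mix** 16/43/41 per 100 tumors, the distribution of consecutive
  breast-carcinoma accrual.
- **p_cycling** ~ Gamma per grade with means 0.065/0.115/0.32 and sds
  0.05/0.10/0.22 (right-skewed, clipped at 0.95). With 3000 nuclei per 10x
  field (~0.6 mm² of cellular carcinoma) and MIB-1 sensitivity 0.95 this
  reproduces per-grade MIB-1 means near 181/324/907 per field.
- **DNA index** = 1 + Gamma excess with grade means 1.05/1.25/1.60 (sds
  0.05/0.15/0.30); S phase lengthens by 30% per unit DNA-index excess
  (`t_s = t_s_base · (1 + 0.30 · (DI − 1))`), the reported magnitude for
  aneuploid versus diploid tumors. Mitosis duration is drawn independently
  of ploidy.
- **Phase durations** (hours) ~ Gamma with (mean, sd): G1 (16, 12),
  S base (10, 4), G2 (4, 2), M (1, 0.3). The wide spreads encode the
  severalfold between-tumor variation of cell-cycle time reported across
  tissues and grades; they are the decoupling mechanism itself. Under these
  defaults simulated cohorts show r(mitoses, PhH3) ≈ 0.96 and
  r(MIB-1, PhH3) ≈ 0.78–0.83 — interphase variation, not measurement error,
  separates them.
- **Counts**: expected marker-positive nuclei per field = nuclei per field x
  occupancy fraction; per-field counts are Poisson, averaged over 4–12
  fields per tumor. A 40x high-power field covers 1/16 of a 10x field (4x
  linear magnification), so mitoses per 10 HPF are Poisson with mean
  `E[mitotic per 10x field] · 10/16 · detection`. Under this pinned geometry
  simulated mitotic counts per 10 HPF run lower, relative to PhH3 per field,
  than published tables that count mitoses in activity-selected regions;
  only correlation structure, not the mitotic-count scale, is asserted.
- **IOD fast path**: per tumor, 15 nuclei are sampled from the snapshot
  model; IOD = (OD per unit DNA per pixel, 0.9) x DNA content x area
  (Gaussian, 700 ± 150 px²) x multiplicative noise (cv 8%). This mirrors the
  pixel-route measurement without rasterizing; the pixel route is verified
  separately on rendered fields. IOD units are arbitrary (hematoxylin is not
  stoichiometric to DNA on real slides; the synthetic stain is stoichiometric
  by construction, which is what makes recovery testable).

Per-tumor RNG streams are keyed by `(cohort seed, tumor index)`, so a
tumor's draw is independent of cohort size and ordering.

## Rendering

Nuclei are ellipses (semi-major 7–13 px, eccentricity ≤ 1.6) placed by
rejection sampling with center spacing ≥ 1.6 x max radius (near-touching, as
in tissue; placement fails loudly when a requested density is unpackable).
Edges are anti-aliased by 4x4 subpixel coverage. Pixel color follows
Beer–Lambert mixing: `OD = a_H · DNA · coverage + a_DAB · coverage`
(DAB only on marker-positive nuclei; never in H&E mode), channel intensity
`I0 · 10^(−OD · v)` with Gaussian noise (sd 2) and 8-bit quantization.
Stain vectors default to the standard H-DAB pair, hematoxylin
(0.65, 0.70, 0.29) and DAB (0.27, 0.57, 0.78); the residual is their
normalized cross product kept *signed* — forcing it non-negative makes it
nearly collinear with hematoxylin and the deconvolution numerically
explosive (quantization noise of ~0.005 OD amplified 80-fold). Default frame
2560 x 1920 px (a 10x capture); tests and the pipeline's verification subset
render 300 x 400–1280 x 960 crops, scaling nucleus counts by area.

## Counting chain

1. **Color deconvolution**: per-pixel OD `−log10(max(I,1)/I0)` solved
   against the stain matrix; concentrations clipped at 0.
2. **Minimum filter** (disc erosion, radius 1) on the 8-bit DAB
   transmitted-intensity image `255 · 10^(−c)` — signal dark, so erosion
   smooths and slightly dilates stained objects.
3. **RATS threshold** on the inverted (signal-bright) image: the
   gradient-weighted mean intensity with weights
   `max(g² − λ², 0)`, Sobel magnitude `g`. Edge pixels straddle the
   object/background boundary, so their weighted mean is a robust global
   threshold. λ (default 150 gradient units) sits an order of magnitude
   below true chromogen edge gradients (~900) and above everything a
   marker-negative field produces — sensor noise and hematoxylin
   quantization crosstalk reach ~143 — so blank or H&E-only fields raise a
   no-signal condition and count 0. A simple "3x propagated noise sd" floor
   (~6) fails this: crosstalk rims around counterstained nuclei exceed the
   30 px² area filter and would be counted.
4. **Watershed** on the negated Euclidean distance transform, seeded at
   regional maxima of the lightly smoothed (Gaussian σ = 1) transform with
   maxima merged within 3 px. Without smoothing, anti-aliased ellipse ridges
   oversegment (67 counts from 50 nuclei); with it, 50 separated nuclei
   count exactly 50 and 300 nuclei including 20 touching pairs count 294.
5. **Particle count** with area bounds 30–5000 px² at 10x (speckle and
   confluent sheets excluded; bounds are conventions, config-exposed), holes
   filled first (ring artifacts).

The chain is deterministic given raster and config.

## Statistics

Pearson correlations, least-squares regression of MIB-1 on PhH3, and
pooled-variance t-tests (Welch optional) use standard formulas
(scipy-backed). Tumors strictly above the fitted line (ties count as *not*
above) are cross-tabulated as grades 1–2 versus 3 and tested with a
from-scratch two-sided Fisher exact test: full hypergeometric enumeration,
summing all tables (fixed margins) whose point probability is ≤ the observed
one within a 1e-7 relative tie tolerance; a zero margin returns p = 1.

## Pipeline and problem sizes

`run_experiment` simulates the cohort (Poisson count path), verifies the
image route on a small rendered subset (default 3 tumors, 300 x 400 px
fields, MIB-1 + PhH3 counting and H&E IOD), computes all statistics, and
compares each tumor's observed PhH3/MIB-1 ratio with `T_m/(T_m + T_i)`.
Statistical properties are assessed over 100 seeded replicates of 100-tumor
cohorts (seconds of runtime); full-frame rendering is exercised only where
pixel fidelity is the question, keeping the default suite fast. The observed
ratio carries a ~5% upward bias (MIB-1 sensitivity 0.95 shrinks the
denominator) plus Poisson noise concentrated in low-grade tumors; mean
absolute relative error across a 100-tumor cohort averages ~13%.

## Known limitations

- No stromal texture, tissue folds, focus blur, or uneven illumination: the
  renderer tests algorithmic correctness, not robustness to slide artifacts.
  Passing counts here do not certify accuracy on real slides.
- No G0-exit kinetics, apoptosis, or necrosis; the growth law is a
  steady-state projection.
- Mitotic-figure visibility and PhH3 window parameters are plausible
  conventions, not measured quantities.
- IOD ignores section-truncation of nuclei and non-stoichiometric
  hematoxylin binding — both present on real H&E material.
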