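# Methods

## Tissue segmentation

All images are single-marker grayscale frames on a shared pixel grid with
a physical pixel size (µm/px), in **signal-high** convention: chromogenic
(signal-dark) scans are first inverted, `x → 255 − x`. The segmentation
chain is:

1. **Tissue vs. blank.** A global threshold on a structural channel
   (hematoxylin by default, configurable) separates tissue from empty
   glass; pixels strictly above the threshold are tissue. Methods:
   `otsu` (default), `max_entropy` (Kapur), `triangle`, `fixed`.
   Otsu is the default because the blank class of an inverted chromogenic
   slide clips into a near-degenerate spike at gray level 0; the
   maximum-entropy criterion gains almost nothing from isolating a
   zero-entropy class and instead splits inside the tissue mode (measured
   thresholds of 115–135 on blank-0 / tissue-90 / nuclei-180 mixtures
   whose correct split is below 60, where Otsu and Huang both land at
   30–50). A constant image has no threshold; the contract returns an
   all-tissue mask carrying a warning flag rather than failing.
2. **Mask cleaning** (`clean_mask`), in a fixed, documented order:
   binary closing (disk, radius 5 px default) → fill interior holes
   (unlimited hole area by default; a cap is available) → binary opening
   (disk, radius 3 px default) → removal of connected components smaller
   than 500 px. The growing phase (closing + fill) never removes pixels
   and the shrinking phase (opening + despeckle) never adds any; both are
   asserted on every call. Radii and the minimum object size are free
   parameters; the defaults suit nests tens of pixels across and are all
   recorded in run manifests.
3. **Nest extraction.** The tumor-marker histogram restricted to ROI
   pixels is thresholded with the **Huang minimum-fuzziness method**;
   ROI pixels above the threshold form the raw nest mask, which is cleaned
   and re-intersected with the ROI. If the ROI histogram has a single
   populated level, no threshold exists and the nest mask is empty (the
   whole ROI counts as stroma).
4. **Stroma** is the exact set difference ROI ∖ nest, so
   nest ∪ stroma = ROI and nest ∩ stroma = ∅ hold identically; blank is
   the ROI complement. These partition invariants are asserted at
   construction of every segmentation result.

### Huang thresholding

For a candidate level *t*, level *g* receives a fuzzy membership
`u(g) = 1 / (1 + |g − m| / C)` to the side (≤ *t* background, > *t*
foreground) containing it, where *m* is that side's mean level and *C*
the populated level range. The threshold minimizes total fuzziness
`E(t) = Σ_g h(g)·S(u(g))` with `S(u) = −u ln u − (1−u) ln(1−u)`.
Numerical choices: candidates are restricted to populated levels below
the top populated level — sliding *t* across empty bins moves no mass, so
*E* is exactly constant there, the smallest minimizer always sits on a
populated level, and tie-breaking (smallest *t* wins) stays exact in
floating point. A consequence worth knowing: when the histogram has an
*exactly empty* gap between two modes, every split of the gap ties and
the threshold lands at the gap's lower edge; with any tail mass in the
gap the minimum moves toward the middle. The implementation is a
vectorized exhaustive search over all candidates and is checked against
an independent per-candidate evaluation of the objective.

### ROI selection

High-CD3-density analysis windows are square (side 2.5 mm by default,
i.e. 6.25 mm², shrunk to the frame when the slide is smaller), placed on
a 0.25 mm grid and chosen greedily by integrated CD3 signal over tissue;
candidates overlapping earlier picks or containing no tissue are skipped,
and ties resolve in top-left scan order, which makes selection
deterministic. Coordinates are pixel-indexed, origin top-left, half-open
box extents.

## Image cytometry

Nuclei are detected on the hematoxylin channel inside the ROI: Otsu
threshold over ROI pixels, Euclidean distance transform smoothed with a
σ = 1 px Gaussian (suppresses plateau double-peaks), watershed seeded at
distance-map peaks (minimum separation 5 px default), and an area filter.
Per-cell marker intensity is the mean over the cell footprint (watershed
region, or a fixed-radius disk around the centroid for externally
supplied tables).

Gating walks an ordered rule list, first match wins, unmatched cells are
`other`; a cell is positive for a marker when its mean intensity is at or
above the marker threshold (default 127, the 8-bit midpoint; per-marker
overrides supported). The panel does not publish calibrated positivity
thresholds, so they are deliberately isolated in one config object.
Rule order makes overlapping phenotypes (e.g. CD66b⁺CD68⁺) impossible by
construction rather than an error. T_H1/T_H2 sub-labels apply to helper T
cells only (Tbet wins over GATA3 when both are positive); PD-1 is an
independent boolean flag. The validation-panel variant gates helper T
cells as CD3⁺CD4⁺ instead of CD3⁺CD8⁻.

Region assignment uses rounded-centroid containment, which is
deterministic for boundary cells. Densities are count / region area in
mm²; a zero-area region reports its counts with NaN density. Composition
percentages are per-region shares of CD45⁺ cells (the nine immune
lineages); the tumor-validation metric splits cells into CD45⁺,
tumor-marker⁺ (CD45⁻) and double-negative classes that sum to 100% per
region. Multiple ROIs of one specimen are pooled (counts and areas
summed) before densities are computed.

Polarization of a lineage is the nest/stroma density ratio: > 2.0
nest-polarized, < 0.5 stroma-polarized, boundaries inclusive to balanced;
zero stroma density with positive nest density is nest-polarized by
convention, two zero densities are undefined. A specimen with no T_H2
cells is excluded from the T_H1/T_H2 ratio rather than reported as
infinite.

## Cohort statistics

Kaplan–Meier, log-rank and Cox proportional hazards are delegated to
lifelines; Spearman, Wilcoxon signed-rank and Kruskal–Wallis to scipy;
ROC curves to scikit-learn. Contract choices: Efron tie handling for Cox
(a flag switches to Breslow-style analyses only through lifelines
options); Wald 95% CIs and p-values; convergence failures (monotone
likelihood / separation) are flagged rather than reported as unstable
hazard ratios; Wilcoxon uses the exact null for ≤ 25 non-zero pairs and a
continuity-corrected normal approximation beyond; all tests are two-sided
at α = 0.05. Cutoff rules: cohort mean, median, fixed external value, or
the ROC point maximizing Youden's J against the event label; the high
group includes the cutoff (≥). Two-marker stratification labels patients
`both_high` (high under both rules) vs `other`.

## Synthetic data

The image generator emulates exactly the structure the pipeline measures:
a rectangular tissue sheet with a blank margin, disjoint disk-shaped
nests (radii uniform in 150–400 µm by default), per-lineage cell
placement with Poisson counts (density × compartment area) uniformly
inside each compartment, per-cell marker intensities drawn from lineage
profiles (positive markers mean 200, negative 30, CV 0.1 by default, all
on the 8-bit scale), disk rendering with maximum blending, and Gaussian
channel noise (sd 15) clipped to [0, 255]. Structural signal: the
tumor-marker channel is 200 inside nests and 10 elsewhere in tissue; the
hematoxylin channel is 90 over tissue, ~0 in the blank margin, with
nuclear disks at 180. Default densities skew T_H1, TAM and tumor cells
into nests and helper T, T_H2, B cells, granulocytes and PD-1⁺ T cells
into stroma — the qualitative picture the pipeline is designed to
resolve. Everything is reproducible bit-for-bit from (spec, seed).

What the generator does **not** emulate: staining artifacts, tissue
folds, uneven illumination, coregistration error, real nest morphology
(disks rather than irregular epithelial architecture), nuclear texture,
cell crowding/overlap statistics of real epithelium, or batch effects.
Passing recovery tests therefore demonstrates that the implementation is
correct and well-calibrated on data satisfying its assumptions — not that
those assumptions hold on real slides, where positivity thresholds and
morphology parameters need case-by-case calibration.

The cohort generator draws a log-normal density feature (default
log-mean ln 43.1 − 0.5, log-sd 1.0, so the population mean is
43.1 cells/mm²), splits patients at the cohort mean, multiplies the
exponential event hazard (baseline 0.01/month) by exp(β) for the high
group (default β = ln 3.32), and censors with a Uniform(0, u) time where
u is solved numerically so the expected censored fraction equals the
requested rate (default 0.3). Times are continuous months; an optional
rounding flag introduces ties to exercise tie handling.

## Problem sizes

The canonical synthetic slide is 1.8 × 1.8 mm at 2.0 µm/px (900 × 900 px)
with three nests — large enough that nests at the specified radii fit
comfortably and small enough that a 50-slide recovery study runs in tens
of seconds. The default `ImageSimSpec` pixel size is 0.46 µm/px (a
typical 20× whole-slide scan) for users rendering at native resolution.
Calibration studies use 1000 null cohorts of n = 60 (log-rank type-I
error), n = 2000 (Cox consistency), 100 cohorts of n = 200 (CI coverage)
and 50 pipeline runs of n = 60 (end-to-end power).

## Known limitations

- Nest geometry is circular; morphology parameters tuned here are not
  validated against real epithelial shapes.
- Region assignment by centroid ignores cells straddling the nest
  boundary; with real, ragged boundaries the ±1–2 px agreement measured
  on synthetic disks will degrade.
- Watershed detection undercounts in densely packed nests; the density
  recovery study therefore quantifies marker intensities at known cell
  positions to separate quantification/gating error from detection error.
- The log-rank test is slightly anticonservative at n = 60 with the
  unbalanced (~35/65) high/low split the log-normal mean cutoff produces;
  measured type-I error is ≈ 0.05–0.07 at α = 0.05.
- No multiple-testing correction is applied anywhere, matching the
  analysis design this package implements.
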