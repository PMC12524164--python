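# Methods

## Overview

`fibroquant` quantifies liver fibrosis from registered SHG/TPEF image
pairs. The SHG channel is specific for fibrillar collagen; the TPEF
channel carries hepatocyte autofluorescence and therefore defines tissue.
The pipeline is deterministic given its seeds; every stochastic component
(phantom/cohort generation, cross-validation splits, bootstrap, forests)
takes an explicit seed fanned out from one top-level value through
`numpy.random.SeedSequence`.

## Segmentation

* **Otsu thresholding** is computed on a 256-bin histogram; the returned
  threshold is the smallest bin boundary maximising between-class
  variance, and pixels *above* the boundary are foreground. A
  single-valued histogram has no valid split and raises a degenerate-input
  error.
* **Collagen mask**: Otsu on SHG restricted to the tissue mask; 8-connected
  components with physical area strictly below 15 µm² are removed as noise
  (at the native 0.390625 µm pitch the boundary falls between 98 px =
  14.95 µm² and 99 px = 15.11 µm², asserted exactly in tests); interior
  gaps of at most 2 px are then filled. Components touching a lumen
  boundary are always retained (vessel-wall collagen must survive
  pruning). Order of operations — threshold → area filter → gap fill — is
  a convention; the area boundary cases pin it down.
* **Tissue mask**: Otsu on TPEF; 4-connected components are kept only when
  strictly larger than 0.1 mm² (655,360 px at native pitch). An empty
  result is valid. Collagen uses 8-connectivity because thin diagonal
  fibres must stay connected; tissue is bulky, so 4-connectivity avoids
  spurious diagonal joins. Both are configurable.
* **Lumens** are 8-connected holes in the tissue mask with area ≥ 100 µm²
  (sub-sinusoidal holes are not landmark candidates). Features per lumen:
  area, eccentricity, boundary smoothness (perimeter over equal-area-circle
  perimeter), collagen collar fraction (collagen share of a 4 µm
  morphological ring), and the number of neighbouring lumens within 50 µm.
  Lumens are ordered by centroid (row, col) so labels are stable.

## Zonation

A depth-limited decision tree (CART, depth ≤ 4) classifies lumens into
portal tract / central vein / other. Portal tracts are collagen-collared,
irregular, and accompanied by satellite bile-duct lumens; central veins
are round, smooth and nearly bare. Training data come from phantom ground
truth; on held-out phantom lumens (n ≥ 200) accuracy exceeds 95 %.

The five-region zone map is built as follows: the portal (central-vein)
*core* is the 4 µm collar ring around each portal (central) lumen plus
every collagen component contiguous with it; periportal and pericentral
are bands of geodesic distance — measured inside tissue, so zones flow
around lumens rather than across them — up to a configurable band width
(default 100 µm each; no published value exists, and all q-FP tables
record the bands used). A pixel claimed by both bands goes to the nearer
landmark, with exact ties to periportal because periportal fibrosis
dominates early staging in steatotic liver disease. Remaining tissue is
zone 2; with no classified landmark the whole parenchyma is zone 2 and the
fallback is logged. Zone labels partition the tissue mask exactly (an
invariant asserted on every map).

The "chicken-wire" (perisinusoidal) compartment has no canonical
operational definition; the surrogate used here flags a string when its
majority region is zone 2 or pericentral, its minimum distance to any
landmark-attached collagen exceeds 10 µm, and its ribbon width is below
the thick-string threshold. All three constants are configuration.

## Morphometry

A *string* is an 8-connected collagen component. Length is the skeleton
arc length (straight steps 1 px, diagonal √2, plus one pixel for endpoint
extent) times the pitch; width is area/length (ribbon model, orientation
free); a compact blob whose implied width would exceed its length is
reclassified with length := √area. Strings take the zone holding the
majority of their pixels (tie-break periportal > portal > pericentral >
zone 2 > central vein); splitting components at zone borders was rejected
as unstable — a bridging septum belongs to its majority zone, which is a
known limitation.

Classification thresholds (none published; all recorded in every table):
thick ≥ 3 µm width, long ≥ 40 µm length, aggregation by morphological
closing at 5 µm — a string is aggregated when its closed cluster carries
≥ 200 µm² of collagen. Closed lower bounds throughout (a width exactly at
threshold is thick).

The emitted grid is 11 metrics × 7 regions + `%SHG` = 78 names
(`#Str, #ShortStr, #LongStr, #ThinStr, #ThickStr, StrArea, StrLength,
StrWidth, %Area, %Agg, %Dis` × overall/PT/PeriPortal/ChickenWire/Zone2/
CV/PeriCentral). Count metrics are additionally emitted as per-mm²
densities (`_per_mm2` suffix); percentages use the region's tissue area as
denominator, with ChickenWire — an overlay, not a zone — using the
combined zone 2 + pericentral area. Partition identities
(thin + thick = all, short + long = all, %Agg + %Dis = %Area per region)
hold exactly and are property-tested. Doubling the pitch doubles lengths,
quadruples areas and leaves counts unchanged.

## The qFibrosis model

Features are divided by their training-set maxima (all-zero columns are
dropped with a warning), then forward-selected against stage: at each step
the candidate minimising stage-stratified 5-fold cross-validated residual
sum of squares of the linear fit is added, stopping at `k_max` (default
17, the size of the established international collagen panel) or when CV
error stops improving; a numerically identical RSS (collinear duplicate)
does not count as improvement. The final model is ordinary least squares
of stage (numeric 0–4) on the selected normalized features. The selection
criterion (CV-RSS) is this package's documented choice — published
descriptions state only "sequential feature selection". Scoring new
specimens applies the *stored training maxima*, so a frozen model never
depends on the test set; out-of-sample values may exceed 1 and the output
is not clamped. Modelling uses only size-invariant inputs (densities,
mean geometries, percentages), so a fitted model transfers across tissue
sizes. On noiseless synthetic features the coefficients match the
normal-equations oracle to 10⁻¹⁰.

## NIT calculators

Printed composite-score formulas circulate in variant forms, so each
ambiguous score carries an explicit `variant` switch, with defaults chosen
by internal consistency with the published cohort magnitudes:

* **FIB-4** divides by √ALT by default (`as_printed` divides by ALT): the
  established published form, and the one compatible with the cohort
  median ≈ 1.0.
* **NFS** multiplies the 1.13 coefficient by the binary hyperglycaemia
  indicator by default (`as_printed` uses glucose in mmol/L, which would
  shift the score by ≈ +6 and is incompatible with the published median
  ≈ −2.5).
* **FAST** and **MAST** map their linear predictors through a logistic by
  default, because their published medians (≈ 0.63, ≈ 0.13) lie in (0, 1);
  MAST uses base-10 logarithms (natural logs push the logistic to ≈ 1 at
  cohort-median inputs, log₁₀ gives ≈ 0.10, matching the published scale).

Albumin is accepted in g/dL; `ALB_gL` columns are divided by 10 at ingest.
Missing inputs flag the affected score as missing rather than failing the
panel.

## Diagnostics

AUC is the normalized Mann–Whitney statistic with ties counted ½ (verified
exactly against brute-force pair counting). Confidence intervals use a
class-stratified percentile bootstrap (2,000 replicates, seeded) rather
than DeLong: the bootstrap extends unchanged to cutoff-level metrics.
Candidate cutoffs are the observed score values and a case is positive at
score ≥ cutoff; Youden ties resolve to the smallest cutoff, the
90 %-sensitivity rule returns the largest satisfying cutoff (maximising
specificity under the constraint), the 90 %-specificity rule the smallest;
unattainable targets are flagged, not silently truncated. Se/Sp/PPV/NPV
come from the 2×2 table, with undefined predictive values flagged rather
than imputed. Spearman correlations use mid-ranks, with exact permutation
p-values below n = 10 and the t approximation otherwise, and optional
Bonferroni adjustment over the matrix. Stage-wise testing reports a
Kruskal–Wallis omnibus plus all pairwise Mann–Whitney tests with
Bonferroni-multiplied p (published descriptions name only the pairwise
test; both are reported). Weighted kappa defaults to linear disagreement
weights (the quadratic variant is available; no published choice exists).
Random-forest importance reports out-of-bag permutation ΔMSE (the
classical forest importance; computed by hand because scikit-learn exposes
no OOB permutation importance) and total impurity decrease ("node
purity").

## Synthetic data

**Phantoms.** A wobbly quasi-circular tissue blob (~70 % of the canvas)
carries portal tracts (irregular lumen, radius 10–16 µm, a stage-dependent
stromal collar of 2.5–3.5 µm at F0 growing to 9.5–13 µm at F4, radial
fibrous spurs whose number and reach grow with stage, and 1–2 satellite
bile-duct lumens) and central veins (round lumen with sparse thin
perivenular arcs). Parenchymal collagen strings are rectangles planted
per region to a requested areal density — stage defaults rise
monotonically in the periportal band (0.6 % at F0 to 24 % at F4), follow a
steatohepatitis-like hump in zone 2, and rise slowly pericentrally — with
string length/width distributions growing with stage. F3/F4 phantoms add
slightly curved portal–portal (and at F4 portal–central) bridging septa;
septa are drawn before string planting and strings keep a 3 µm clearance
from lumens, landmark cores and septa, so planted strings are never
absorbed into the landmark-attached stroma and ground truth stays exact.
Channels are rendered as well-separated Gaussians (tissue 0.55 vs
background 0.04 on TPEF; collagen 0.72 vs 0.04 on SHG; σ = 0.015), so
thresholding recovers the planted masks with Jaccard ≥ 0.95. The phantoms
deliberately model **geometry, not optics**: no PSF, photon noise,
steatosis vacuoles or inflammation. Passing tests therefore validate the
measurement pipeline on known geometry; they do not demonstrate robustness
to real acquisition noise, stain variation or biopsy fragmentation. The
default canvas is 1024 px (400 µm, 0.16 mm²) so the 0.1 mm² tissue filter
is exercisable; the test and acceptance studies use 512 px (200 µm)
phantoms with the tissue floor scaled to 0.02 mm², a deliberate
mosaic-scale reduction that keeps the full study tractable (50 phantoms
per stage, 250 total).

**Cohorts.** Each variable is drawn conditionally on stage from the family
matching its published reporting convention: mean (SD) variables are
Gaussian; median (IQR) variables (the skewed labs and stiffness measures)
are log-normal with µ = ln median and σ = (ln q3 − ln q1)/(2 z₀.₇₅); binary
traits are Bernoulli at the per-stage prevalence. Non-positive draws of
physical quantities are redrawn and counted. The default calibration is a
99-patient cohort staged 17/16/32/28/6 with, e.g., qF 0.94 ± 0.38 (F0) to
3.78 ± 0.60 (F4) and MRE-LSM medians 2.44 → 5.13 kPa. Variables are drawn
independently within stage — real lab-lab correlations beyond the shared
stage effect are not modelled, which mildly weakens composite-score
spread relative to a real cohort. Enrolment screening applies the three
exclusions (incomplete data, biopsy–MRI interval > 6 months ≡ 183 days,
concomitant liver disease) in that order, attributing multi-failures to
the first matching reason; the synthetic roster flags are disjoint, which
is the only layout consistent with the published 126 − 27 = 99 arithmetic.

## Numerical conventions and degenerate inputs

0-based (row, col) coordinates; areas in µm² as pixel count × pitch²;
strict inequalities exactly as stated for both area filters; Otsu ties to
the smallest maximising split; empty tissue raises in collagen
segmentation, while an empty tissue *result* is valid; regions absent from
a zone map yield zero-valued metrics with a presence flag; rank-deficient
final designs raise with the collinear feature pairs named.

## Known limitations

Fibre orientation and cross-linking metrics are out of scope, as is the
proprietary full 186-parameter catalogue (the 78-name grid is a versioned,
documented subset). Whole-slide stitching, illumination correction, and
acquisition physics are not modelled. The chicken-wire construction and
the band widths are surrogates whose constants are configuration, not
published values. The synthetic study conditions are cleaner than
clinical reality, so pipeline-level correlations (e.g. qF vs stage
ρ ≈ 0.98 on phantoms) exceed the cohort-level analogues reported in the
literature (≈ 0.84); the tests assert the ordering and threshold
properties, not those clinical point values.
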