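# fibroquant

Quantitative collagen morphometry and non-invasive-test (NIT) evaluation
for liver fibrosis staging on two-channel multiphoton microscopy.

## The problem

In metabolic dysfunction-associated steatotic liver disease (MASLD), the
histological fibrosis stage F0–F4 is the reference prognostic marker, but
visual staging is ordinal and observer-dependent. Second-harmonic
generation (SHG) microscopy images collagen directly in unstained sections,
with two-photon excitation fluorescence (TPEF) providing the tissue
context, which makes fully quantitative, continuous fibrosis scoring
possible. `fibroquant` implements that pipeline end to end:

1. **Segmentation** — Otsu thresholding of the SHG channel within tissue,
   removal of collagen specks < 15 µm², tissue masking on TPEF with a
   > 0.1 mm² component filter, and detection of luminal structures
   (vessels, bile ducts, sinusoids, fissures) as holes in the tissue mask.
2. **Zonation** — a CART classifier assigns lumens to portal tract /
   central vein / other from shape and collagen-collar features; geodesic
   bands around the landmarks partition the tissue into the five lobular
   regions (portal, periportal, zone 2, pericentral, central vein), with a
   perisinusoidal "chicken-wire" overlay.
3. **Morphometry** — each connected collagen component is a *string* with
   skeleton length ℓ, area A and ribbon width w = A/ℓ; strings are counted
   and classified (thin/thick, short/long, aggregated/distributed) per
   region into a named q-FP vector (`#StrPT`, `StrWidthPeriPortal`,
   `%ChickenWire`, `%SHG`, … 78 names).
4. **qFibrosis score** — q-FPs are max-normalized, forward-selected against
   stage by cross-validated RSS, and combined by ordinary least squares
   into the continuous, dimensionless qF value:
   `qF = β₀ + Σᵢ βᵢ · xᵢ / max(xᵢ)`.
5. **NIT calculators** — APRI, AAR, FIB-4, NFS, FAST, MAST (with explicit
   formula variants), alongside measured MRE-LSM and VCTE-LSM.
6. **Diagnostics** — ROC/AUC (Mann–Whitney with bootstrap CI), cutoffs by
   Youden index / 90 % sensitivity / 90 % specificity with Se/Sp/PPV/NPV,
   Spearman correlation matrices, Kruskal–Wallis and Mann–Whitney stage
   tests with Bonferroni post hoc, weighted kappa, and random-forest
   variable importance (OOB permutation ΔMSE and node purity).

Because SHG/TPEF biopsy archives and the matching clinical records are
essentially never public, the package ships a **synthetic module**: tissue
phantoms with exact per-pixel ground truth per fibrosis stage (portal
tracts, central veins, stage-dependent collagen from periportal wisps to
bridging septa) and patient cohorts whose stage-conditional lab and
elastography distributions are calibrated to published per-stage summaries.
Every downstream stage is testable without any data download.

## Worked example

```python
from fibroquant.synthetic import PhantomSpec, generate_phantom
from fibroquant.pipeline import RunConfig, process_image, train_landmark_model_from_phantoms

cfg = RunConfig(canvas_px=512, min_tissue_area_mm2=0.02)
landmarks = train_landmark_model_from_phantoms(cfg, seed=3, n_phantoms=6)

img, truth = generate_phantom(PhantomSpec(stage=3, canvas_px=512, seed=5))
table, parts = process_image(img, landmarks, cfg)
print(f"%SHG          = {table['%SHG']:.2f}")
print(f"StrWidthPT    = {table['StrWidthPT']:.2f} um")
print(f"#StrPeriPortal= {table['#StrPeriPortal']:.0f}")
```

prints (seed 5, stage F3 phantom):

```
%SHG          = 24.50
StrWidthPT    = 3.89 um
#StrPeriPortal= 13
```

i.e. 24.5 % of the tissue area is collagen, the portal/septal strings are
about 4 µm wide, and 13 distinct collagen strings lie in the periportal
band — a typical bridging-fibrosis picture. Fitting the qFibrosis model on
a staged phantom cohort and printing `results.summary()` shows the selected
parameters, their coefficients and the R² against stage; on a 250-phantom
study the fitted qF value tracks the true stage with Spearman ρ ≈ 0.98.

The same objects drive the CLI:

```bash
fibroquant simulate-cohort --seed 3 --out cohort.csv
fibroquant score-nits --cohort cohort.csv --out scored.csv
fibroquant evaluate --cohort scored.csv --out-dir eval/
fibroquant run --seed 11 --out-dir run/     # full simulate->fit->evaluate
```

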