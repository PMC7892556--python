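# Methods

This note documents the models, conventions and parameter defaults behind
`stiffquant`, what the synthetic phantoms do and do not emulate, and the
design choices made where the procedure was genuinely open.

## Elastography model

SWE maps assign each pixel a Young's modulus E in kPa.  For soft, nearly
incompressible, isotropic tissue of constant density ρ, E relates to the
shear-wave speed v<sub>s</sub> as E = 3·ρ·v<sub>s</sub>²;
`young_modulus_from_shear_speed` implements exactly this (ρ must be passed
explicitly — the package assumes no hidden density).  All downstream
analysis operates on the already-converted kPa rasters.

**Geometry convention** (one convention for every module): pixel
coordinates are 0-based, x right, y down, with pixel centers at integer
coordinates.  A pixel belongs to an ROI when its center lies *strictly*
inside the contour polygon (even-odd rule); boundary-center pixels are
excluded.  Contours are ordered vertex lists; orientation is irrelevant.

**Radial analysis.**  The barycenter is the unweighted centroid of the ROI
pixel centers.  Each pixel's normalized radius divides its distance to the
barycenter by the distance from the barycenter to the contour along the
same ray (exact ray–edge intersection per pixel), so the tumor edge sits at
r<sub>norm</sub> = 1 in every direction regardless of tumor shape.  If the
barycenter falls outside the polygon (strongly non-convex ROI) the method
falls back to r<sub>norm</sub> = d/d<sub>max</sub> and flags the result.
The center-to-edge decrease is minus the OLS slope of stiffness on
r<sub>norm</sub> — unbiased for a linear profile and using every pixel;
the tumor "center" mask is r<sub>norm</sub> ≤ 1/√2, which halves the area
of a disk.

**Statistics conventions.**  SD is the sample SD (n−1); percentiles use
linear interpolation; Spearman uses average ranks for ties with a
two-sided large-sample p; all tests are two-sided.  The gel noise floor
(95th percentile of coupling-gel pixels) is used only for frame QC and
never censors tumor pixels.  The soft/stiff cut sits at 40 kPa mean tumor
stiffness with the boundary assigned to "stiff" — 40 kPa separates all
reported soft (≤ 31.8 kPa) and stiff (≥ 42.5 kPa) removal-stiffness
ranges.  Histograms use right-open 1-kPa bins over [0, 200) kPa with the
top bin absorbing ≥ 200, and report percent of tumor area so tumors of
different sizes are comparable; the percentages sum to 100 exactly.

## SWE phantoms

The generators define the study conditions for every simulation-based
test.  A phantom tumor is an axis-aligned ellipse (axis ratio uniform in
[0.7, 1.0], jittered center) on a 256×256 raster at 0.1 mm/px — the
acquisition geometry of the original export is unknown, so these are
documented stand-ins and all geometry is spacing-aware.  Tumor area
follows a growth model (default exponential, 30 → 120 mm² over 10
timepoints at 3.5-day intervals, matching the order of magnitude of the
grafts' caliper follow-up).  Pixel stiffness is

    edge + (center_t − edge) · (1 − r^e) + N(0, σ_px),   clipped to [lo, hi]

with the radial exponent e = 1 by default (the observed gradient is
monotone; its shape is not reported, so linear is the parsimonious
choice).  `center_t` interpolates from the edge value toward the preset
center value in proportion to `stiffness_coupling` × relative area growth,
which is what couples stiffness to growth.  Pixels outside the contour are
coupling-gel draws N(3, 1.5) kPa truncated at 0.  Noise is additive then
clipped (truncation, not rejection), so the soft presets literally satisfy
a 0–40 kPa pixel support.

Preset conditions (magnitudes anchored to the reported ranges — stiff
tumors reaching 120–140 kPa, soft tumors 0–40 kPa, Non-Mesenchymal tumors
never above 60 kPa):

| preset | center → edge (kPa) | noise SD | clip (kPa) | coupling | growth (mm²) |
| --- | --- | --- | --- | --- | --- |
| `mesenchymal_stiff` | 120 → 40 | 6 | [0, 200] | 1.0 | 30 → 120 |
| `mesenchymal_soft` | uniform 18 | 6 | [0, 40] | 0 | 30 → 120 |
| `non_mesenchymal` | uniform 22 | 6 | [0, 40] | 0 | 30 → 60 |

Each timepoint yields 3 replicate maps sharing geometry and differing only
in the noise realization, mirroring the repeat-acquisition protocol whose
per-replicate ROI means are averaged.  Every generator is a pure function
of (parameters, seed) and emits a truth record (true mean, true area from
the contour, true center-to-edge decrease) for parameter-recovery tests.

What the phantoms do *not* emulate: B-mode texture, probe repositioning
artifacts, skin-rim biomechanics, attenuation with depth, non-elliptical
tumor shapes.  Passing recovery tests therefore demonstrates correctness
of the quantification chain, not robustness to acquisition artifacts in
real animals.

## Collagen morphometry

The original fiber measurements were manual (freehand lines along, and
straight lines across, ≥ 100 fibrils).  This package substitutes a
deterministic automated analogue and validates it on synthetic truth —
it is a methodological replacement, not a claim of equivalence with the
manual protocol:

* threshold (Otsu by default) → binary mask → skeleton; the skeleton is
  split at junction pixels and branches shorter than 3 px are pruned; each
  remaining path is one candidate fiber;
* `fiber_length` is the classical chain metric (1 per axial step, √2 per
  diagonal step).  That metric overestimates obliquely oriented fibers by
  up to ~8% (digital staircase), so the pipeline-level measurement
  (`measure_fibers`) reports arc length along a 5-px moving-average
  smoothed centerline instead, which is accurate to ~1.5% across
  orientations and on curved fibers; both estimators are exposed;
* `fiber_thickness` is twice the median medial-axis half-width along the
  path, where the Euclidean distance transform (a center-to-center
  distance) is converted to a boundary distance by subtracting half a
  pixel — a 1-px line measures 1 px, a 6-px bar 5–6 px;
* SHG intensities are never rescaled, mirroring acquisition at constant
  detector voltage and laser power.

Synthetic fibers are smooth random polylines rendered as soft-edged
circular tubes (EDT profile with a ~1 px linear rim) rather than pure
Gaussian cross-sections: a hard-edged tube makes the thresholded mask
width — and hence the thickness contract (±1 px of truth) — independent
of the exact threshold level.  Defaults: 12 non-overlapping fibers of
30–60 µm × 2–4 µm at 0.5 µm/px over 5 slices.

**Trichrome.**  Color deconvolution works in optical-density space,
OD = −log10((I+1)/256) per channel, with a 3×3 unit-norm stain matrix
(default: published Masson-trichrome-like vectors — methyl blue for
collagen, ponceau-fuchsin for cytoplasm/nuclei, residual = their
normalized cross product; the matrix is loadable/exportable as YAML).
The collagen channel is thresholded with one fixed value per batch
(default: Otsu on the batch-pooled channel, then frozen) and summarized as
integrated density = mean gray × area (identically pixel-sum × pixel
area) over the tissue mask, calibrated in mm².  Stroma/epithelium
segmentation of real sections is out of scope; `stroma_percentage`
consumes masks (phantom truth or user annotation).  H-score panels
(fractions of cells at intensity 0–4) are inputs — no cell detection is
performed behind them.  The trichrome phantom synthesizes the image in OD
space, so deconvolution with the same matrix inverts it exactly
(< 1e-6 OD without noise); the collagen mask is carved from a smoothed
Gaussian random field thresholded at the requested quantile, making the
mask fraction exact.

The ambiguity of whether density ROIs should be fiber-masked is resolved
by computing ROI-level density on the raw projection; callers can pass a
masked image to choose the other reading.

## Transcriptomics

The subtype classifier standardizes each gene to mean 0, sample SD 1
*within each dataset* before merging on shared genes — the reading of
"standardization per array" consistent with its stated purpose of removing
cross-platform batch effects (the literal per-array reading contradicts
the parenthetical per-gene definition).  The merged matrix is not
re-standardized.  Samples are clustered on the 36-gene signature
(Euclidean distance, complete linkage) and the dendrogram cut in two; the
cluster with the higher mean expression of the anti-correlated (stromal,
Mesenchymal-up) half is labeled Mesenchymal — the labeling rule is an
inference, as only the cut itself is prescribed.  The 36 gene identities
are not public; the package ships a synthetic placeholder signature and
accepts any user list (plain text with an `#anticorrelated` marker).

Differential expression runs on Log2+1 data with equal-variance Student
t-tests (a Welch flag exists), paired by tumor for center-vs-periphery
within stiff tumors, and keeps genes with P ≤ 0.05 and FC > 1.2 where
FC = 2^|mean log2 difference| with the direction carried separately.  No
multiple-testing correction is applied by default, faithful to the stated
filter; a Benjamini–Hochberg option exists as a clearly labeled extension.

The expression phantom plants the signature (±effect, in units of the
gene noise SD, default 2 SD at noise 0.25) in the human/epithelium matrix
and the DE genes (±1.0 log2, alternating sign, specifically in stiff-tumor
centers) in the mouse/stroma matrix.  The stroma matrix also carries a
per-tumor random offset (SD 0.15) — the tumor-to-tumor variation that
makes the paired center/periphery design more powerful than the unpaired
one; the epithelium matrix has no sample-level offsets, so its subtype
separation is exactly the stated effect size.  Compartments use disjoint
gene universes, as human and mouse arrays do.

## Pipeline

`run_end_to_end` simulates three cohorts (default 4 tumors per preset, 6
timepoints, 3 replicates — sizes chosen so a full report builds in
seconds; all sizes are config options), runs every stage, and writes a
JSON report plus CSVs with a provenance block (version, config hash,
seed).  The global seed fans out to per-stage seeds via
`numpy.random.SeedSequence([seed, stage_code, index])`, so stages can be
re-run in isolation.  Manifest validation reports duplicates, missing
files and inconsistent spacings together rather than one at a time.

## Numerical notes and degenerate inputs

* Tied representative frames resolve to the lowest index; tied ranks get
  average ranks; zero-variance genes are dropped from standardization with
  a logged count; constant inputs leave correlations flagged invalid
  rather than raising.
* `pixels_in_contour` raises on zero-area polygons and on polygons that
  trap no pixel center; `center_to_edge_decrease` requires ≥ 30 pixels
  with an r<sub>norm</sub> spread ≥ 0.5; paired tests require a complete
  pairing (the contrast suite drops incomplete tumors with a warning
  first); caliper axes are never swapped silently.
* Single-pixel ROIs report SD 0.

## Known limitations

* The skeleton-based fiber records are validated on non-intersecting
  synthetic fibers; dense, crossing fiber networks will be fragmented at
  junctions into shorter records.
* The soft/stiff cut, stain vectors, phantom geometry and growth defaults
  are documented stand-ins where the original study reports ranges rather
  than rules; all are exposed as parameters.
* The DICOM import hook expects an already-decoded stiffness raster; the
  scanner's proprietary embedded field is not parsed.
* DE p-values are per-gene and uncorrected by design; lists are exported
  for external enrichment tools rather than analyzed further.
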