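# stiffquant

Quantification pipeline for tumor stiffness and its tissue correlates, built
around shear-wave elastography (SWE) of ovarian-cancer xenografts.

High-grade serous ovarian carcinomas of the Mesenchymal transcriptomic
subtype accumulate a dense, collagen-rich stroma; a central question is
whether that desmoplasia translates into a mechanical phenotype — a stiff
tumor — measurable non-invasively and linked to growth, collagen
architecture, and stiffness-associated gene programs.  `stiffquant`
implements the full quantification chain of such a study for researchers in
tumor mechanobiology:

* **Elastography** — SWE maps report a per-pixel Young's modulus
  E = 3·ρ·v<sub>s</sub>² (kPa) from the shear-wave speed v<sub>s</sub>.
  Inside a hand-drawn tumor contour the package computes ROI statistics,
  replicate-averaged mean stiffness, percent-of-area histograms (1-kPa bins,
  0–200 kPa), radial profiles of stiffness against the normalized distance
  r ∈ [0, 1] from the tumor barycenter (edge = 1 along every ray), the OLS
  center-to-edge stiffness decrease, a soft/stiff dichotomy at 40 kPa mean
  stiffness, Spearman stiffness–area correlations over growth, caliper
  volumes V = a·b²/2, and growth rates.
* **Collagen imaging** — fiber morphometry on maximum-intensity projections
  of SHG z-stacks (threshold → skeleton → junction-split paths; geodesic
  length and 2× medial-axis half-width per fiber), trichrome collagen
  density via optical-density color deconvolution and integrated density
  (mean gray × area), stroma percentages, and H-scores
  (Σ percent-positive × intensity, 0–400).
* **Transcriptomics** — a Mesenchymal/Non-Mesenchymal classifier
  (per-gene standardization, merge on shared genes, hierarchical clustering
  with Euclidean distance and complete linkage on a 36-gene miR-200a
  signature, two-way dendrogram cut) and compartment-split differential
  expression on Log2+1 data (Student t, paired for center-vs-periphery
  within stiff tumors, filtered at P ≤ 0.05 and fold change > 1.2).
* **Phantoms** — every analysis stage is exercised on seeded synthetic
  generators with known ground truth: longitudinal elliptical stiffness
  maps with a linear center-to-edge gradient, fiber images, trichrome
  fields, and two-compartment expression matrices with planted signature
  and DE genes.

## Worked example

Generate a stiff-Mesenchymal phantom at its final growth timepoint and
quantify it:

```python
import stiffquant as sq

smap, contour, truth = sq.generate_stiffness_map(
    sq.PRESETS["mesenchymal_stiff"], timepoint_index=9, seed=1)
roi = sq.TumorROI(contour, smap.shape)

print(sq.summarize_roi(smap, roi)["mean"])                 # 66.799
print(sq.tumor_area(roi, smap.pixel_spacing_mm))           # 119.76
records = sq.radial_records(smap, roi)
print(sq.center_to_edge_decrease(records))                 # 79.96
print(sq.classify_soft_stiff(sq.summarize_roi(smap, roi)["mean"]))  # stiff
print(truth.true_center_to_edge_decrease_kpa)              # 80.0
```

The phantom's stiffness falls linearly from 120 kPa at the barycenter to
40 kPa at the contour with 6 kPa pixel noise, so the mean stiffness lands at
≈ 66.8 kPa (analytic mean 40 + 80/3), the ROI covers ≈ 120 mm² (the final
area of the growth model), and the radial OLS fit recovers the planted
80 kPa center-to-edge decrease to within a tenth of a kPa — comfortably
above the 70 kPa drop that distinguishes stiff tumors.

The same chain is available from the shell:

```bash
stiffquant simulate swe --preset mesenchymal_stiff --seed 1 --out-dir maps/
stiffquant swe analyze --map maps/mesenchymal_stiff_t09_r0.tif \
    --contour maps/mesenchymal_stiff_t09_r0.contour.csv --out-dir out/
stiffquant run-all --seed 1 --out-dir report/
```

`run-all` simulates three cohorts (stiff Mesenchymal, soft Mesenchymal,
Non-Mesenchymal), runs every stage and writes `report.json` plus CSV
tables; with the defaults the stiff cohort shows a stiffness–area Spearman
rho of ≈ 0.97 while the Non-Mesenchymal cohort stays below 23 kPa
throughout.

## Layout

| module | contents |
| --- | --- |
| `stiffquant.elastography` | stiffness-map types, ROI geometry, radial analysis, statistics |
| `stiffquant.collagen` | SHG fiber morphometry, color deconvolution, densities, H-score |
| `stiffquant.transcriptomics` | subtype classifier, differential expression |
| `stiffquant.phantoms` | synthetic generators with ground truth |
| `stiffquant.pipeline` | config, manifest validation, end-to-end runner |
| `stiffquant.io` | TIFF/PNG/CSV/TSV readers and writers, optional DICOM hook |
| `stiffquant.cli` | `stiffquant` command-line entry point |

See `docs/methods.md` for the models, parameter defaults and known
limitations.
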