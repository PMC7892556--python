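"""End-to-end pipeline: simulation -> analysis -> reports.

`run_end_to_end` simulates three phantom cohorts (stiff Mesenchymal, soft
Mesenchymal, Non-Mesenchymal), runs every analysis stage and writes a
single JSON report plus CSV tables mirroring the study's figure panels
(stiffness-area correlations, histograms, radial gradients, fiber metrics,
subtype assignments, differential-expression counts).  The run is fully
reproducible from (config, seed): the global seed fans out to per-stage
seeds through a fixed derivation (``numpy.random.SeedSequence([seed,
stage_code])``), so any stage can be re-run in isolation.

All figure-like outputs are CSV-first; plotting is never on the critical
path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .collagen import (HscorePanel, batch_collagen_threshold, color_deconvolve,
                       hscore, max_intensity_projection, measure_fibers,
                       StainModel, collagen_density, stroma_percentage)
from .elastography import (TumorROI, center_to_edge_decrease, classify_soft_stiff,
                           cohort_stiffness_growth_correlation,
                           mean_tumor_stiffness, radial_records,
                           stiffness_histogram, summarize_roi, tumor_area)
from .phantoms import (GrowthModel, PRESETS, PRESET_CLASS,
                       generate_expression_dataset, generate_growth_series,
                       generate_shg_image, generate_trichrome_image)
from .transcriptomics import (cluster_subtypes, de_contrast_suite, filter_de,
                              log2p1, standardize_genes)

logger = logging.getLogger(__name__)

_STAGE_CODES = {"swe": 1, "shg": 2, "trichrome": 3, "expression": 4}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence([global_seed & 0x7FFFFFFF,
                                 _STAGE_CODES[stage], index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """End-to-end run configuration.  Unknown YAML keys are rejected."""

    out_dir: str = "stiffquant_run"
    seed: int = 0
    n_tumors_per_preset: int = 4
    n_timepoints: int = 6
    n_replicates: int = 3
    soft_stiff_cut_kpa: float = 40.0
    histogram_bin_width_kpa: float = 1.0
    fiber_prune_px: int = 3
    n_shg_images: int = 2
    de_welch: bool = False
    de_bh: bool = False

    def __post_init__(self) -> None:
        for name in ("n_tumors_per_preset", "n_timepoints", "n_replicates",
                     "soft_stiff_cut_kpa", "histogram_bin_width_kpa",
                     "fiber_prune_px", "n_shg_images"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class ManifestError(ValueError):
    """All manifest problems, reported together."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_manifest(manifest: pd.DataFrame | Path) -> pd.DataFrame:
    """Validate a cohort manifest; aggregate every problem before raising.

    Expected columns: tumor_id, timepoint_days, replicate, map_path,
    contour_path, model_label.  Checks duplicates of (tumor, timepoint,
    replicate), missing files, and inconsistent pixel spacings across the
    referenced map sidecars.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = ["tumor_id", "timepoint_days", "replicate",
                "map_path", "contour_path", "model_label"]
    errors: list[str] = []
    missing_cols = [c for c in required if c not in manifest.columns]
    if missing_cols:
        raise ManifestError([f"missing columns: {missing_cols}"])
    if len(manifest) == 0:
        raise ManifestError(["empty manifest"])
    key = manifest[["tumor_id", "timepoint_days", "replicate"]]
    dup = key.duplicated(keep=False)
    if dup.any():
        rows = [int(i) for i in manifest.index[dup]]
        errors.append(f"duplicated (tumor, timepoint, replicate) in rows {rows}")
    spacings = {}
    for i, row in manifest.iterrows():
        for col in ("map_path", "contour_path"):
            p = Path(row[col])
            if not p.exists():
                errors.append(f"row {i}: missing file {p}")
        sidecar = Path(row["map_path"]).with_suffix(".json")
        if sidecar.exists():
            spacing = json.loads(sidecar.read_text()).get("pixel_spacing_mm")
            spacings.setdefault(spacing, []).append(int(i))
    if len(spacings) > 1:
        errors.append(f"inconsistent pixel spacings across rows: "
                      f"{ {k: v for k, v in spacings.items()} }")
    if errors:
        raise ManifestError(errors)
    return manifest.reset_index(drop=True)


def _analyze_cohort(preset_name: str, config: RunConfig) -> dict:
    """Simulate and analyze one phantom cohort."""
    preset = PRESETS[preset_name]
    growth = GrowthModel(area0_mm2=preset.growth.area0_mm2,
                         area_final_mm2=preset.growth.area_final_mm2,
                         n_timepoints=config.n_timepoints,
                         model=preset.growth.model)
    preset = type(preset)(**{**{f.name: getattr(preset, f.name)
                                for f in fields(preset)}, "growth": growth})
    measurements = []
    final_decreases = []
    histogram_sums = []
    for tumor_idx in range(config.n_tumors_per_preset):
        seed = stage_seed(config.seed, "swe", tumor_idx)
        series, _ = generate_growth_series(preset, seed=seed,
                                           n_replicates=config.n_replicates)
        for t, acq in enumerate(series):
            mean_kpa = mean_tumor_stiffness(acq)
            roi = acq.rois[0]
            smap = acq.maps[0]
            area = tumor_area(roi, smap.pixel_spacing_mm)
            hist = stiffness_histogram(smap, roi, config.histogram_bin_width_kpa)
            histogram_sums.append(float(hist.percent_of_area.sum()))
            measurements.append({
                "preset": preset_name,
                "tumor_id": f"{preset_name}_{tumor_idx:02d}",
                "timepoint_days": acq.timepoint_days,
                "mean_kpa": mean_kpa,
                "area_mm2": area,
                "label": classify_soft_stiff(mean_kpa, config.soft_stiff_cut_kpa),
            })
            if t == len(series) - 1:
                final_decreases.append(
                    center_to_edge_decrease(radial_records(smap, roi)))
    df = pd.DataFrame(measurements)
    if len(df) >= 3:
        corr = cohort_stiffness_growth_correlation(df)
    else:                     # minimal cohorts: correlation undefined, not fatal
        from .elastography import CorrResult
        corr = CorrResult(rho=float("nan"), p=float("nan"), valid=False)
    return {
        "measurements": df,
        "summary": {
            "n_measurements": int(len(df)),
            "max_mean_kpa": float(df["mean_kpa"].max()),
            "stiffness_area_spearman_rho": corr.rho if corr.valid else None,
            "stiffness_area_spearman_p": corr.p if corr.valid else None,
            "mean_final_center_to_edge_decrease_kpa": float(np.mean(final_decreases)),
            "labels": df["label"].value_counts().to_dict(),
            "truth_label": PRESET_CLASS[preset_name],
            "histogram_sums_ok": bool(np.allclose(histogram_sums, 100.0)),
        },
    }


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full simulated study and write the report bundle.

    Returns the report dict; writes ``report.json``, ``measurements.csv``,
    ``fibers.csv`` and ``subtype_assignments.csv`` under ``config.out_dir``.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"version": _version(),
                                   "config": asdict(config),
                                   "config_hash": config.config_hash(),
                                   "seed": config.seed}}
    logger.info("run_end_to_end: config hash %s seed %d",
                config.config_hash(), config.seed)

    # --- SWE cohorts ------------------------------------------------------
    all_measurements = []
    try:
        report["swe"] = {}
        for preset_name in ("mesenchymal_stiff", "mesenchymal_soft",
                            "non_mesenchymal"):
            res = _analyze_cohort(preset_name, config)
            report["swe"][preset_name] = res["summary"]
            all_measurements.append(res["measurements"])
    except Exception as exc:
        raise RuntimeError(f"stage 'swe' failed: {exc}") from exc
    pd.concat(all_measurements).to_csv(out / "measurements.csv", index=False)

    # --- SHG fiber morphometry -------------------------------------------
    try:
        fiber_rows = []
        for i in range(config.n_shg_images):
            stack, truth = generate_shg_image(seed=stage_seed(config.seed, "shg", i))
            proj = max_intensity_projection(stack)
            for rec in measure_fibers(proj, stack.pixel_size_um,
                                      prune_px=config.fiber_prune_px):
                fiber_rows.append({"image": i, "fiber_id": rec.fiber_id,
                                   "length_um": rec.length_um,
                                   "thickness_um": rec.thickness_um})
        fibers = pd.DataFrame(fiber_rows)
        fibers.to_csv(out / "fibers.csv", index=False)
        report["shg"] = {"n_fibers": int(len(fibers)),
                         "mean_length_um": float(fibers["length_um"].mean()),
                         "mean_thickness_um": float(fibers["thickness_um"].mean())}
    except Exception as exc:
        raise RuntimeError(f"stage 'shg' failed: {exc}") from exc

    # --- Trichrome collagen density + H-score ----------------------------
    try:
        model = StainModel.masson_trichrome()
        fractions = (0.2, 0.5)
        images = [generate_trichrome_image(f, model,
                                           seed=stage_seed(config.seed, "trichrome", i))
                  for i, f in enumerate(fractions)]
        concs = [color_deconvolve(rgb, model)[..., 0] for rgb, _ in images]
        thr = batch_collagen_threshold(concs)
        tri = {}
        for (rgb, mask), frac in zip(images, fractions):
            tissue = np.ones(mask.shape, dtype=bool)
            dens = collagen_density(rgb, model, thr, tissue, pixel_size_mm=0.002)
            tri[f"fraction_{frac}"] = {
                "integrated_density": dens.integrated_density,
                "stroma_percent": stroma_percentage(mask, tissue)}
        # SMA H-score demo panels: fibroblast staining shifts up with stiffness
        tri["hscore_soft"] = hscore(HscorePanel(np.array([0.35, 0.30, 0.20, 0.10, 0.05])))
        tri["hscore_stiff"] = hscore(HscorePanel(np.array([0.05, 0.10, 0.20, 0.35, 0.30])))
        report["trichrome"] = tri
    except Exception as exc:
        raise RuntimeError(f"stage 'trichrome' failed: {exc}") from exc

    # --- Transcriptomics --------------------------------------------------
    try:
        human, mouse, truth = generate_expression_dataset(
            seed=stage_seed(config.seed, "expression"))
        human_log = standardize_genes(log2p1(human))
        result = cluster_subtypes(human_log, truth.signature)
        agreement = float((result.labels == truth.subtype).mean())
        result.labels.rename("subtype_label").to_frame().assign(
            cluster=result.clusters).to_csv(out / "subtype_assignments.csv")
        de = de_contrast_suite(log2p1(human), log2p1(mouse),
                               welch=config.de_welch, bh=config.de_bh)
        de_counts = {}
        for name, table in de.items():
            up, down = filter_de(table)
            de_counts[name] = {"up": len(up), "down": len(down)}
        report["transcriptomics"] = {
            "n_signature_genes": len(truth.signature.genes),
            "subtype_label_agreement": agreement,
            "de_counts": de_counts,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'expression' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _version() -> str:
    from . import __version__
    return __version__
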