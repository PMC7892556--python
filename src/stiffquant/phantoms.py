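"""Synthetic phantoms with known ground truth for every analysis stage.

Real inputs (in vivo SWE maps of PDX tumors, SHG stacks, trichrome slides,
PDX microarrays) cannot be regenerated at a desk, so each generator here
emulates the corresponding acquisition with a fully known ground truth:

* longitudinal elliptical-tumor stiffness maps with a linear center-to-edge
  stiffness gradient, additive acquisition noise and a coupling-gel
  background;
* SHG-like fiber images rendered from random smooth polylines with known
  per-fiber length and thickness;
* trichrome-like RGB fields synthesized in optical-density space from a
  collagen and a cytoplasm stain, with a known collagen mask;
* two-compartment (human epithelium / mouse stroma) expression matrices
  with a planted 36-gene subtype signature and planted differentially
  expressed genes tied to stiffness and tumor region.

Every generator is a pure function of (parameters, seed): the same call
gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line

from .collagen import SHGStack, StainModel
from .elastography import AcquisitionSet, StiffnessMap, TumorROI
from .transcriptomics import ExpressionDataset, SignatureSet, SIGNATURE_SIZE

__all__ = [
    "GrowthModel",
    "SWEPhantomPreset",
    "PRESETS",
    "PhantomTruth",
    "FiberTruth",
    "ExprTruth",
    "generate_stiffness_map",
    "generate_growth_series",
    "generate_shg_image",
    "generate_trichrome_image",
    "generate_expression_dataset",
]

#: Default SWE raster geometry: 256x256 pixels at 0.1 mm/px.
MAP_SHAPE = (256, 256)
PIXEL_SPACING_MM = 0.1
#: Imaging cadence: twice a week.
TIMEPOINT_INTERVAL_DAYS = 3.5
#: Vertices used to discretize the elliptical tumor contour.
CONTOUR_VERTICES = 64


@dataclass(frozen=True)
class GrowthModel:
    """Tumor area growth over the follow-up.

    Default: exponential area growth from 30 to 120 mm² over 10 timepoints,
    matching the order of magnitude of 30-60 mm³ grafts followed to removal
    size.
    """

    area0_mm2: float = 30.0
    area_final_mm2: float = 120.0
    n_timepoints: int = 10
    model: str = "exponential"

    def __post_init__(self) -> None:
        if not (self.area0_mm2 > 0 and self.area_final_mm2 >= self.area0_mm2):
            raise ValueError("areas must satisfy 0 < area0 <= area_final")
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 timepoints")
        if self.model not in ("linear", "exponential"):
            raise ValueError("growth model must be linear or exponential")

    def area_at(self, timepoint_index: int) -> float:
        """True tumor area (mm²) at a timepoint; non-decreasing in time."""
        if not 0 <= timepoint_index < self.n_timepoints:
            raise ValueError("timepoint index out of range")
        f = timepoint_index / (self.n_timepoints - 1)
        if self.model == "linear":
            return self.area0_mm2 + (self.area_final_mm2 - self.area0_mm2) * f
        return self.area0_mm2 * (self.area_final_mm2 / self.area0_mm2) ** f


@dataclass(frozen=True)
class SWEPhantomPreset:
    """Parameters of one SWE tumor phantom condition.

    The pixel stiffness inside the tumor is
    ``edge + (center_t - edge) * (1 - r_norm**radial_exponent) + noise``
    clipped to ``clip_range``, where ``center_t`` interpolates from
    ``edge_kpa`` toward ``center_kpa`` as ``stiffness_coupling`` times the
    relative area growth; pixels outside the contour are coupling-gel draws
    N(gel_mean, gel_sd) truncated at 0.
    """

    name: str
    center_kpa: float
    edge_kpa: float
    pixel_noise_sd: float = 6.0
    clip_range: tuple[float, float] = (0.0, 200.0)
    gel_mean: float = 3.0
    gel_sd: float = 1.5
    growth: GrowthModel = field(default_factory=GrowthModel)
    stiffness_coupling: float = 1.0
    radial_exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (self.center_kpa >= self.edge_kpa >= 0):
            raise ValueError("require center_kpa >= edge_kpa >= 0")
        lo, hi = self.clip_range
        if not (lo <= self.edge_kpa and hi >= self.center_kpa):
            raise ValueError("clip range must bracket [edge_kpa, center_kpa]")
        if not 0 <= self.stiffness_coupling <= 1:
            raise ValueError("stiffness_coupling must lie in [0, 1]")
        if self.radial_exponent <= 0:
            raise ValueError("radial exponent must be positive")

    def center_kpa_at(self, timepoint_index: int) -> float:
        """Peak (barycenter) stiffness at a timepoint."""
        g = self.growth
        rel = ((g.area_at(timepoint_index) - g.area0_mm2)
               / (g.area_final_mm2 - g.area0_mm2)) \
            if g.area_final_mm2 > g.area0_mm2 else 1.0
        return self.edge_kpa + (self.center_kpa - self.edge_kpa) \
            * self.stiffness_coupling * rel

    def true_mean_kpa_at(self, timepoint_index: int) -> float:
        """Analytic noiseless mean over the elliptical tumor.

        For the radial profile edge + d*(1 - r**e) averaged over an ellipse
        (density 2r dr in normalized radius): mean = edge + d*(1 - 2/(e+2)).
        """
        d = self.center_kpa_at(timepoint_index) - self.edge_kpa
        return self.edge_kpa + d * (1.0 - 2.0 / (self.radial_exponent + 2.0))


#: Default phantom conditions.  The stiff Mesenchymal condition reaches
#: 120 kPa at the tumor center over a 40 kPa edge (pixel support 0-120 kPa
#: plus noise, clipped at 200); the soft conditions are spatially uniform at
#: 18 / 22 kPa with pixel support clipped to the soft 0-40 kPa range.
PRESETS: dict[str, SWEPhantomPreset] = {
    "mesenchymal_stiff": SWEPhantomPreset(
        name="mesenchymal_stiff", center_kpa=120.0, edge_kpa=40.0,
        pixel_noise_sd=6.0, clip_range=(0.0, 200.0), stiffness_coupling=1.0),
    "mesenchymal_soft": SWEPhantomPreset(
        name="mesenchymal_soft", center_kpa=18.0, edge_kpa=18.0,
        pixel_noise_sd=6.0, clip_range=(0.0, 40.0), stiffness_coupling=0.0),
    "non_mesenchymal": SWEPhantomPreset(
        name="non_mesenchymal", center_kpa=22.0, edge_kpa=22.0,
        pixel_noise_sd=6.0, clip_range=(0.0, 40.0), stiffness_coupling=0.0,
        growth=GrowthModel(area0_mm2=30.0, area_final_mm2=60.0)),
}

#: Truth labels implied by the presets (mean >= 40 kPa cut).
PRESET_CLASS = {"mesenchymal_stiff": "stiff",
                "mesenchymal_soft": "soft",
                "non_mesenchymal": "soft"}


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth emitted with every generated stiffness map."""

    preset: str
    timepoint_index: int
    timepoint_days: float
    replicate: int
    seed: int
    true_mean_kpa: float
    true_area_mm2: float
    true_center_to_edge_decrease_kpa: float


def _shoelace_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def generate_stiffness_map(preset: SWEPhantomPreset, timepoint_index: int,
                           seed: int, replicate: int = 0,
                           map_shape: tuple[int, int] = MAP_SHAPE,
                           pixel_spacing_mm: float = PIXEL_SPACING_MM,
                           ) -> tuple[StiffnessMap, np.ndarray, PhantomTruth]:
    """One SWE phantom frame: stiffness map, tumor contour, truth record.

    The tumor is an axis-aligned ellipse (random axis ratio in [0.7, 1.0],
    jittered center) whose area follows the preset growth model.  Geometry
    depends only on (seed, timepoint); the noise realization additionally
    on ``replicate``, so replicate frames share geometry.
    """
    geom_rng = np.random.default_rng([seed & 0x7FFFFFFF, timepoint_index, 101])
    noise_rng = np.random.default_rng([seed & 0x7FFFFFFF, timepoint_index,
                                       replicate, 202])
    area_mm2 = preset.growth.area_at(timepoint_index)
    area_px = area_mm2 / pixel_spacing_mm ** 2
    if area_px <= 0:
        raise ValueError("non-positive tumor area")
    q = geom_rng.uniform(0.7, 1.0)                    # axis ratio b/a
    a = math.sqrt(area_px / (math.pi * q))
    b = q * a
    h, w = map_shape
    cx = w / 2 + geom_rng.uniform(-5, 5)
    cy = h / 2 + geom_rng.uniform(-5, 5)
    if a >= min(cx, w - 1 - cx) or b >= min(cy, h - 1 - cy):
        raise ValueError("tumor ellipse does not fit in the field of view")
    phi = np.linspace(0.0, 2.0 * math.pi, CONTOUR_VERTICES, endpoint=False)
    contour = np.column_stack([cx + a * np.cos(phi), cy + b * np.sin(phi)])

    roi = TumorROI(contour, map_shape)
    yy, xx = np.nonzero(roi.mask)
    r_ell = np.hypot((xx - cx) / a, (yy - cy) / b)
    center_t = preset.center_kpa_at(timepoint_index)
    profile = preset.edge_kpa + (center_t - preset.edge_kpa) \
        * (1.0 - r_ell ** preset.radial_exponent)

    values = np.empty(map_shape, dtype=np.float64)
    gel = noise_rng.normal(preset.gel_mean, preset.gel_sd, size=map_shape)
    values[:] = np.clip(gel, 0.0, None)               # truncated at 0
    noise = noise_rng.normal(0.0, preset.pixel_noise_sd, size=profile.shape)
    values[yy, xx] = np.clip(profile + noise, *preset.clip_range)

    truth = PhantomTruth(
        preset=preset.name,
        timepoint_index=timepoint_index,
        timepoint_days=timepoint_index * TIMEPOINT_INTERVAL_DAYS,
        replicate=replicate,
        seed=seed,
        true_mean_kpa=preset.true_mean_kpa_at(timepoint_index),
        true_area_mm2=_shoelace_area(contour) * pixel_spacing_mm ** 2,
        true_center_to_edge_decrease_kpa=center_t - preset.edge_kpa,
    )
    smap = StiffnessMap(values=values.astype(np.float32),
                        pixel_spacing_mm=pixel_spacing_mm,
                        gel_mask=~roi.mask,
                        frame_id=f"{preset.name}_t{timepoint_index}_r{replicate}_s{seed}")
    return smap, contour, truth


def generate_growth_series(preset: SWEPhantomPreset, seed: int,
                           n_replicates: int = 3,
                           ) -> tuple[list[AcquisitionSet], pd.DataFrame]:
    """A full longitudinal series: one AcquisitionSet per timepoint.

    Each timepoint yields ``n_replicates`` maps (normally 3, mirroring the
    repeat-acquisition protocol) that share geometry and differ only in the
    noise realization.  Returns the series and a truth table with one row
    per generated map.
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    sets: list[AcquisitionSet] = []
    rows: list[PhantomTruth] = []
    for t in range(preset.growth.n_timepoints):
        maps, rois = [], []
        for r in range(n_replicates):
            smap, contour, truth = generate_stiffness_map(
                preset, t, seed, replicate=r)
            maps.append(smap)
            rois.append(TumorROI(contour, smap.shape))
            rows.append(truth)
        sets.append(AcquisitionSet(maps=maps, rois=rois,
                                   timepoint_days=t * TIMEPOINT_INTERVAL_DAYS))
    return sets, pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# SHG fiber phantom
# ---------------------------------------------------------------------------

@dataclass
class FiberTruth:
    """Ground truth for a generated fiber image."""

    table: pd.DataFrame          # fiber_id, slice_index, length_um, thickness_um, intensity
    polylines: list              # per-fiber (N, 2) vertex arrays in px (x, y)
    pixel_size_um: float


def _random_polyline(rng: np.random.Generator, shape: tuple[int, int],
                     length_px: float, step_px: float,
                     curvature_sd: float, margin: float) -> np.ndarray | None:
    """Smooth random polyline of the requested arc length, or None if it
    exits the field."""
    h, w = shape
    n_steps = max(1, int(round(length_px / step_px)))
    x = rng.uniform(margin, w - 1 - margin)
    y = rng.uniform(margin, h - 1 - margin)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    pts = [(x, y)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, curvature_sd)
        x += step_px * math.cos(theta)
        y += step_px * math.sin(theta)
        if not (margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin):
            return None
        pts.append((x, y))
    return np.array(pts)


def _render_polyline(shape: tuple[int, int], polyline: np.ndarray,
                     radius_px: float, amplitude: float) -> np.ndarray:
    """Render a soft-edged tube of the given radius around a polyline.

    Intensity is ``amplitude`` on the tube core and falls linearly to zero
    over about one pixel at the rim, so any threshold below half amplitude
    recovers the nominal width to within a pixel.
    """
    trace = np.zeros(shape, dtype=bool)
    verts = np.round(polyline).astype(int)
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        trace[rr, cc] = True
    d = ndimage.distance_transform_edt(~trace)
    return amplitude * np.clip(radius_px + 0.5 - d, 0.0, 1.0)


def generate_shg_image(n_fibers: int = 12,
                       length_range_um: tuple[float, float] = (30.0, 60.0),
                       thickness_range_um: tuple[float, float] = (2.0, 4.0),
                       pixel_size_um: float = 0.5,
                       n_slices: int = 5,
                       seed: int = 0,
                       shape: tuple[int, int] = (512, 512),
                       curvature_sd: float = 0.05,
                       background_level: float = 0.02,
                       ) -> tuple[SHGStack, FiberTruth]:
    """SHG-like z-stack of non-overlapping collagen fibers with known truth.

    Fibers are smooth random polylines rendered as soft-edged tubes of the
    drawn thickness, each into one random slice over a low-amplitude noise
    background.  The truth table lists the realized per-fiber arc length
    (polyline segment sum), thickness and peak intensity.
    """
    if min(length_range_um) <= 0 or min(thickness_range_um) <= 0:
        raise ValueError("length and thickness ranges must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    if max(thickness_range_um) < pixel_size_um:
        raise ValueError("thickness below one pixel cannot be rendered")
    h, w = shape
    if max(length_range_um) / pixel_size_um > 0.8 * min(h, w):
        raise ValueError("fiber longer than the field of view")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 303])
    stack = np.clip(rng.normal(background_level, background_level / 4,
                               size=(n_slices, h, w)), 0.0, None)
    step_px = 2.0
    occupancy = np.zeros(shape, dtype=bool)
    rows, polylines = [], []
    for i in range(n_fibers):
        length_um = rng.uniform(*length_range_um)
        thickness_um = rng.uniform(*thickness_range_um)
        amplitude = rng.uniform(0.8, 1.0)
        slice_idx = int(rng.integers(0, n_slices))
        radius_px = thickness_um / pixel_size_um / 2.0
        placed = False
        for _ in range(200):
            poly = _random_polyline(rng, shape, length_um / pixel_size_um,
                                    step_px, curvature_sd,
                                    margin=radius_px + 3)
            if poly is None:
                continue
            tube = _render_polyline(shape, poly, radius_px, amplitude)
            footprint = ndimage.binary_dilation(tube > 0, iterations=3)
            if (footprint & occupancy).any():
                continue
            occupancy |= footprint
            stack[slice_idx] = np.maximum(stack[slice_idx], tube)
            seg = np.diff(poly, axis=0)
            realized_um = float(np.hypot(seg[:, 0], seg[:, 1]).sum()
                                * pixel_size_um)
            rows.append({"fiber_id": i, "slice_index": slice_idx,
                         "length_um": realized_um,
                         "thickness_um": thickness_um,
                         "intensity": amplitude})
            polylines.append(poly)
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place fiber {i} without overlap")
    columns = ["fiber_id", "slice_index", "length_um", "thickness_um", "intensity"]
    truth = FiberTruth(table=pd.DataFrame(rows, columns=columns),
                       polylines=polylines, pixel_size_um=pixel_size_um)
    return SHGStack(data=stack, pixel_size_um=pixel_size_um), truth


# ---------------------------------------------------------------------------
# Trichrome phantom
# ---------------------------------------------------------------------------

def generate_trichrome_image(collagen_fraction: float,
                             stain_model: StainModel | None = None,
                             seed: int = 0,
                             shape: tuple[int, int] = (512, 512),
                             smooth_sigma: float = 8.0,
                             od_noise_sd: float = 0.0,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Trichrome-like RGB field with a known collagen mask.

    A smoothed Gaussian random field is thresholded at the requested
    quantile to carve collagen-dominant regions; collagen pixels carry
    mostly the collagen stain, the rest mostly the cytoplasm/nuclei stain.
    The image is synthesized in optical-density space and converted to
    transmitted-light RGB (float, [0, 255]); with ``od_noise_sd=0`` color
    deconvolution with the same stain matrix inverts it exactly.
    """
    if not 0.0 <= collagen_fraction <= 1.0:
        raise ValueError("collagen_fraction must lie in [0, 1]")
    model = stain_model or StainModel.masson_trichrome()
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 404])
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    if collagen_fraction == 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif collagen_fraction == 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = fld >= np.quantile(fld, 1.0 - collagen_fraction)
    conc = np.empty(shape + (3,), dtype=float)
    conc[mask] = (1.0, 0.15, 0.0)
    conc[~mask] = (0.05, 0.9, 0.0)
    if od_noise_sd > 0:
        conc[..., :2] += rng.normal(0.0, od_noise_sd, size=shape + (2,))
        conc = np.clip(conc, 0.0, None)
    od = conc.reshape(-1, 3) @ model.matrix
    rgb = 256.0 * 10.0 ** (-od) - 1.0
    return np.clip(rgb, 0.0, 255.0).reshape(shape + (3,)), mask


# ---------------------------------------------------------------------------
# Expression phantom
# ---------------------------------------------------------------------------

@dataclass
class ExprTruth:
    """Ground truth for a generated two-compartment expression dataset."""

    subtype: pd.Series               # sample -> {Mesenchymal, Non-Mesenchymal}
    signature: SignatureSet
    signature_effects: pd.DataFrame  # gene, half, effect_sd (Mesenchymal shift)
    de_genes: pd.DataFrame           # gene, true_log2fc (stiff-center up/down)
    pairing: dict                    # tumor_id -> (center sample, periphery sample)

    def __post_init__(self) -> None:
        if len(self.signature.genes) != SIGNATURE_SIZE:
            raise ValueError("signature truth must contain 36 genes")
        seen: set[str] = set()
        for c, p in self.pairing.values():
            if c in seen or p in seen:
                raise ValueError("paired sample id repeated")
            seen.update((c, p))


def generate_expression_dataset(n_mes: int = 8, n_nonmes: int = 8,
                                n_genes: int = 2000,
                                signature_effect_sd: float = 2.0,
                                n_de: int = 50,
                                de_log2fc: float = 1.0,
                                noise_sd: float = 0.25,
                                tumor_effect_sd: float = 0.15,
                                baseline_log2: float = 8.0,
                                seed: int = 0,
                                ) -> tuple[ExpressionDataset, ExpressionDataset, ExprTruth]:
    """Paired human-epithelium / mouse-stroma expression matrices with truth.

    Tumors: ``n_mes`` Mesenchymal (the first half stiff, the rest soft) and
    ``n_nonmes`` Non-Mesenchymal (all soft).  Every tumor contributes a
    center sample; stiff tumors also a periphery sample, giving the paired
    center/periphery design.  The human matrix carries the 36-gene subtype
    signature shifted by ``signature_effect_sd`` noise-SDs between subtypes
    (half the genes up in Non-Mesenchymal, half up in Mesenchymal); the
    mouse matrix carries ``n_de`` planted genes shifted by ``de_log2fc``
    specifically in stiff-tumor centers (alternating sign).  The stroma
    matrix additionally carries a per-tumor random offset (SD
    ``tumor_effect_sd``), reflecting tumor-to-tumor stromal content; it is
    what makes the paired center/periphery design more powerful than the
    unpaired one.  The epithelium matrix has no sample-level offsets: its
    subtype separation is specified purely in units of the gene noise SD.
    Values are emitted on the linear scale (Log2+1 is applied downstream).
    """
    if n_genes < SIGNATURE_SIZE + n_de:
        raise ValueError("n_genes must be >= 36 + n_de")
    if n_mes < 0 or n_nonmes < 0 or n_mes + n_nonmes < 2:
        raise ValueError("need at least two tumors in total")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 505])

    n_stiff = math.ceil(n_mes / 2)
    tumors, rows = [], []
    for i in range(n_mes):
        tid = f"MES{i + 1:02d}"
        cls = "stiff" if i < n_stiff else "soft"
        tumors.append((tid, "Mesenchymal", cls))
    for i in range(n_nonmes):
        tumors.append((f"NON{i + 1:02d}", "Non-Mesenchymal", "soft"))
    pairing = {}
    for tid, subtype, cls in tumors:
        rows.append({"sample_id": f"{tid}_C", "subtype": subtype,
                     "stiffness_class": cls, "region": "center", "tumor_id": tid})
        if cls == "stiff":
            rows.append({"sample_id": f"{tid}_P", "subtype": subtype,
                         "stiffness_class": cls, "region": "periphery",
                         "tumor_id": tid})
            pairing[tid] = (f"{tid}_C", f"{tid}_P")
    ann = pd.DataFrame(rows).set_index("sample_id")
    samples = list(ann.index)
    tumor_offset = {tid: rng.normal(0.0, tumor_effect_sd)
                    for tid, _, _ in tumors}
    offsets = np.array([tumor_offset[ann.loc[s, "tumor_id"]] for s in samples])

    # --- human (epithelium) matrix with the subtype signature -------------
    n_half = SIGNATURE_SIZE // 2
    cor = tuple(f"HS_SIG_COR_{i + 1:02d}" for i in range(n_half))
    ant = tuple(f"HS_SIG_ANT_{i + 1:02d}" for i in range(n_half))
    signature = SignatureSet(correlated=cor, anticorrelated=ant)
    hs_fillers = [f"HS_G{i + 1:04d}" for i in range(n_genes - SIGNATURE_SIZE)]
    hs_genes = list(cor) + list(ant) + hs_fillers
    effect = signature_effect_sd * noise_sd
    is_mes = (ann["subtype"] == "Mesenchymal").to_numpy()
    hs_log = np.full((len(hs_genes), len(samples)), baseline_log2)
    for gi, g in enumerate(cor):          # correlated with miR-200a: up in Non-Mes
        hs_log[gi, :] += np.where(is_mes, -effect / 2, effect / 2)
    for gi, g in enumerate(ant, start=n_half):   # stromal program: up in Mes
        hs_log[gi, :] += np.where(is_mes, effect / 2, -effect / 2)
    hs_log += rng.normal(0.0, noise_sd, size=hs_log.shape)

    # --- mouse (stroma) matrix with the planted stiffness DE genes --------
    mm_de = [f"MM_DE_{i + 1:03d}" for i in range(n_de)]
    mm_fillers = [f"MM_G{i + 1:04d}" for i in range(n_genes - n_de)]
    mm_genes = mm_de + mm_fillers
    stiff_center = ((ann["stiffness_class"] == "stiff")
                    & (ann["region"] == "center")).to_numpy()
    mm_log = np.full((len(mm_genes), len(samples)), baseline_log2)
    mm_log += offsets[None, :]
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    for gi in range(n_de):
        mm_log[gi, stiff_center] += signs[gi] * de_log2fc
    mm_log += rng.normal(0.0, noise_sd, size=mm_log.shape)

    def _linear(log_mat, genes, compartment):
        expr = pd.DataFrame(2.0 ** log_mat - 1.0, index=genes, columns=samples)
        a = ann.copy()
        a["compartment"] = compartment
        return ExpressionDataset(expr=expr, annotations=a, log_scale=False,
                                 compartment=compartment)

    human = _linear(hs_log, hs_genes, "epithelium")
    mouse = _linear(mm_log, mm_genes, "stroma")
    truth = ExprTruth(
        subtype=ann["subtype"].copy(),
        signature=signature,
        signature_effects=pd.DataFrame({
            "gene": list(cor) + list(ant),
            "half": ["correlated"] * n_half + ["anticorrelated"] * n_half,
            "effect_sd": [-signature_effect_sd] * n_half
                         + [signature_effect_sd] * n_half,
        }),
        de_genes=pd.DataFrame({"gene": mm_de, "true_log2fc": signs * de_log2fc}),
        pairing=pairing,
    )
    return human, mouse, truth
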