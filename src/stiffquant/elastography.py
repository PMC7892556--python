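"""Quantification of shear-wave elastography (SWE) stiffness maps.

A stiffness map assigns each pixel a Young's modulus E in kPa, obtained on
the scanner from the local shear-wave speed vs via E = 3·rho·vs² (soft
tissue is treated as incompressible and isotropic with constant density
rho).  Analysis proceeds from a hand-drawn tumor contour: ROI statistics,
replicate averaging over repeated acquisitions, percent-of-area stiffness
histograms, radial profiles of stiffness versus normalized distance from the
tumor barycenter, a soft/stiff dichotomy on mean stiffness, and rank
correlations between stiffness and tumor area during growth.

Geometry convention (shared by the whole package): pixel coordinates are
0-based with x to the right and y down; a pixel's center sits at integer
coordinates; a pixel belongs to an ROI when its center lies strictly inside
the contour polygon (even-odd rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Point, Polygon

__all__ = [
    "StiffnessMap",
    "ShearParams",
    "TumorROI",
    "AcquisitionSet",
    "StiffnessHistogram",
    "CaliperMeasure",
    "CorrResult",
    "young_modulus_from_shear_speed",
    "pixels_in_contour",
    "summarize_roi",
    "select_representative_frame",
    "estimate_noise_floor",
    "mean_tumor_stiffness",
    "tumor_area",
    "caliper_volume",
    "stiffness_histogram",
    "barycenter",
    "radial_records",
    "center_to_edge_decrease",
    "spearman",
    "classify_soft_stiff",
    "partition_center_periphery",
    "cohort_stiffness_growth_correlation",
    "growth_rate",
    "welch_t",
    "mann_whitney",
]

#: Mean-stiffness cut (kPa) separating soft from stiff tumors.  Soft tumors
#: occupy the 0-40 kPa range; every boundary value is assigned to "stiff".
SOFT_STIFF_CUT_KPA = 40.0

#: Histogram support in kPa: 1-kPa right-open bins over [0, 200); the top
#: bin absorbs any value >= 200.
HISTOGRAM_RANGE_KPA = (0.0, 200.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StiffnessMap:
    """Single-frame SWE stiffness raster in kPa.

    Parameters
    ----------
    values
        2D array of per-pixel Young's modulus (kPa); finite and >= 0.
    pixel_spacing_mm
        Isotropic pixel spacing in mm.
    gel_mask
        Optional boolean mask marking coupling-gel background pixels, used
        for frame QC (the gel carries no true SWE signal, so its apparent
        stiffness is noise).
    """

    values: np.ndarray
    pixel_spacing_mm: float
    gel_mask: np.ndarray | None = None
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("stiffness map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stiffness map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("stiffness values must be >= 0 kPa")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel spacing must be positive")
        if self.gel_mask is not None:
            self.gel_mask = np.asarray(self.gel_mask, dtype=bool)
            if self.gel_mask.shape != self.values.shape:
                raise ValueError("gel mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ShearParams:
    """Shear-wave speed vs (m/s) and tissue density rho (kg/m³)."""

    vs: float
    rho: float

    def __post_init__(self) -> None:
        if self.vs < 0:
            raise ValueError("shear-wave speed must be >= 0")
        if not self.rho > 0:
            raise ValueError("density must be positive")


class TumorROI:
    """Tumor region of interest defined by a hand-drawn closed contour.

    The contour is an ordered (N, 2) vertex array in pixel coordinates
    (x, y).  The pixel set contains every grid pixel whose center falls
    strictly inside the polygon; the barycenter is the unweighted centroid
    of those pixel centers.
    """

    def __init__(self, contour: np.ndarray, grid_shape: tuple[int, int]):
        contour = np.asarray(contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
            raise ValueError("contour must be an (N>=3, 2) vertex array")
        poly = Polygon(contour)
        if not poly.is_simple:
            raise ValueError("contour polygon is self-intersecting")
        if poly.area == 0:
            raise ValueError("degenerate contour polygon (zero area)")
        self.contour = contour
        self.grid_shape = tuple(grid_shape)
        self.polygon = poly
        self.mask = pixels_in_contour(contour, grid_shape)
        yy, xx = np.nonzero(self.mask)
        # pixel centers as (x, y)
        self.pixels = np.column_stack([xx, yy]).astype(float)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def barycenter(self) -> tuple[float, float]:
        xb, yb = self.pixels.mean(axis=0)
        return float(xb), float(yb)


@dataclass
class AcquisitionSet:
    """Replicate SWE acquisitions of one tumor at one timepoint.

    The acquisition protocol repositions the probe and replaces the coupling
    gel between replicates (normally 3), so replicate maps share geometry
    but differ in noise.
    """

    maps: list
    rois: list
    timepoint_days: float = 0.0

    def __post_init__(self) -> None:
        if len(self.maps) < 1:
            raise ValueError("at least one replicate is required")
        if len(self.maps) != len(self.rois):
            raise ValueError("one ROI per replicate map is required")
        spacings = {m.pixel_spacing_mm for m in self.maps}
        if len(spacings) != 1:
            raise ValueError("replicates must share pixel spacing")


@dataclass
class StiffnessHistogram:
    """Percent-of-tumor-area stiffness histogram (1-kPa bins, 0-200 kPa)."""

    bin_edges: np.ndarray
    percent_of_area: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.percent_of_area < 0):
            raise ValueError("negative histogram percentage")
        if abs(self.percent_of_area.sum() - 100.0) > 1e-9:
            raise ValueError("histogram percentages must sum to 100")


@dataclass(frozen=True)
class CaliperMeasure:
    """Caliper tumor diameters: a = major (mm), b = minor (mm)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("minor diameter must be positive")
        if self.a < self.b:
            raise ValueError("major diameter a must be >= minor diameter b "
                             "(axes are not swapped silently)")


@dataclass(frozen=True)
class CorrResult:
    """Correlation result; ``valid`` is False when rho is undefined."""

    rho: float
    p: float
    valid: bool = True


# ---------------------------------------------------------------------------
# Stiffness physics and ROI statistics
# ---------------------------------------------------------------------------

def young_modulus_from_shear_speed(p: ShearParams) -> float:
    """Young's modulus E = 3·rho·vs² in kPa.

    With vs in m/s and rho in kg/m³ the product is in Pa; divide by 1000.
    """
    return 3.0 * p.rho * p.vs ** 2 / 1000.0


def pixels_in_contour(contour: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of grid pixels whose centers lie strictly inside the polygon.

    Even-odd rule; pixel centers exactly on the boundary are excluded.
    Raises ``ValueError`` for degenerate polygons or when no pixel center
    falls inside.
    """
    contour = np.asarray(contour, dtype=float)
    poly = Polygon(contour)
    if poly.area == 0:
        raise ValueError("degenerate contour polygon (zero area)")
    h, w = grid_shape
    x0 = max(0, int(math.floor(contour[:, 0].min())))
    x1 = min(w - 1, int(math.ceil(contour[:, 0].max())))
    y0 = max(0, int(math.floor(contour[:, 1].min())))
    y1 = min(h - 1, int(math.ceil(contour[:, 1].max())))
    mask = np.zeros(grid_shape, dtype=bool)
    if x1 >= x0 and y1 >= y0:
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        mask[gy.ravel()[inside], gx.ravel()[inside]] = True
    if not mask.any():
        raise ValueError("no pixel center falls inside the contour")
    return mask


def _roi_values(smap: StiffnessMap, roi: TumorROI) -> np.ndarray:
    if roi.mask.shape != smap.shape:
        raise ValueError("ROI grid shape does not match the map")
    return smap.values[roi.mask].astype(float)


def summarize_roi(smap: StiffnessMap, roi: TumorROI) -> dict:
    """Min, max, mean and sample SD (ddof=1) of stiffness inside the ROI."""
    vals = _roi_values(smap, roi)
    if vals.size == 0:
        raise ValueError("empty ROI")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": sd,
    }


def select_representative_frame(frames: list, gel_mask: np.ndarray) -> int:
    """Index of the frame with the least apparent gel signal.

    The coupling gel should generate no SWE signal; the representative frame
    of a cine loop is the one minimizing mean stiffness over the gel mask.
    Ties resolve to the lowest index.
    """
    if len(frames) == 0:
        raise ValueError("empty frame list")
    gel_mask = np.asarray(gel_mask, dtype=bool)
    if not gel_mask.any():
        raise ValueError("empty gel mask")
    gel_means = [float(f.values[gel_mask].mean()) for f in frames]
    return int(np.argmin(gel_means))


def estimate_noise_floor(gel_pixels: np.ndarray) -> float:
    """Noise threshold (kPa) as the 95th percentile of gel-pixel stiffness.

    Linear-interpolation percentile; requires at least 30 gel pixels. Used
    only for frame quality control, never to censor tumor pixels.
    """
    gel_pixels = np.asarray(gel_pixels, dtype=float).ravel()
    if gel_pixels.size < 30:
        raise ValueError("need >= 30 gel pixels to estimate the noise floor")
    return float(np.percentile(gel_pixels, 95))


def mean_tumor_stiffness(acq: AcquisitionSet) -> float:
    """Global tumor stiffness: unweighted mean of per-replicate ROI means."""
    means = [summarize_roi(m, r)["mean"] for m, r in zip(acq.maps, acq.rois)]
    return float(np.mean(means))


def tumor_area(roi: TumorROI, pixel_spacing_mm: float) -> float:
    """ROI area in mm²: pixel count × spacing²."""
    if not pixel_spacing_mm > 0:
        raise ValueError("pixel spacing must be positive")
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    return roi.n_pixels * pixel_spacing_mm ** 2


def caliper_volume(m: CaliperMeasure) -> float:
    """Caliper tumor volume V = a·b²/2 in mm³."""
    return m.a * m.b ** 2 / 2.0


def stiffness_histogram(smap: StiffnessMap, roi: TumorROI,
                        bin_width_kpa: float = 1.0) -> StiffnessHistogram:
    """Percent-of-area histogram over [0, 200) kPa, right-open bins.

    The top bin absorbs values >= 200 kPa (cannot occur after default
    clipping but keeps the histogram total at exactly 100%).
    """
    vals = _roi_values(smap, roi)
    if vals.size == 0:
        raise ValueError("empty ROI")
    lo, hi = HISTOGRAM_RANGE_KPA
    n_bins = int(round((hi - lo) / bin_width_kpa))
    idx = np.floor((vals - lo) / bin_width_kpa).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    edges = lo + bin_width_kpa * np.arange(n_bins + 1)
    return StiffnessHistogram(bin_edges=edges,
                              percent_of_area=counts / vals.size * 100.0)


# ---------------------------------------------------------------------------
# Radial (barycenter) analysis
# ---------------------------------------------------------------------------

def barycenter(roi: TumorROI) -> tuple[float, float]:
    """Unweighted centroid (x̄, ȳ) of the ROI pixel centers."""
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    return roi.barycenter


def _ray_boundary_distances(origin: np.ndarray, contour: np.ndarray,
                            directions: np.ndarray) -> np.ndarray:
    """Distance from origin to the first contour crossing along each ray.

    directions: (P, 2) unit vectors.  Returns (P,) distances (inf where the
    ray misses the polygon, which cannot happen for interior origins).
    """
    p1 = contour
    p2 = np.roll(contour, -1, axis=0)
    e = p2 - p1                       # (E, 2) edge vectors
    w = p1 - origin                   # (E, 2)
    # ray origin + t*u meets edge p1 + s*e:  t = cross(w, e)/cross(u, e)
    cross_we = w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]          # (E,)
    cross_ue = (directions[:, 0, None] * e[None, :, 1]
                - directions[:, 1, None] * e[None, :, 0])     # (P, E)
    cross_wu = (w[None, :, 0] * directions[:, 1, None]
                - w[None, :, 1] * directions[:, 0, None])     # (P, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_we[None, :] / cross_ue
        s = cross_wu / cross_ue
    valid = (np.abs(cross_ue) > 1e-12) & (t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def _radial_geometry(roi: TumorROI) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-pixel distance (px) to barycenter and normalized radius.

    r_norm divides the pixel distance by the distance from the barycenter to
    the contour along the same ray, so the tumor edge sits at r_norm = 1 in
    every direction.  When the barycenter falls outside the polygon
    (strongly non-convex ROI) the method falls back to r_norm = d/d_max and
    flags it.
    """
    bc = np.array(roi.barycenter)
    d = np.hypot(roi.pixels[:, 0] - bc[0], roi.pixels[:, 1] - bc[1])
    fallback = not roi.polygon.contains(Point(*bc))
    if fallback:
        warnings.warn("barycenter lies outside the contour; "
                      "falling back to r_norm = d/d_max", stacklevel=2)
        dmax = d.max() if d.max() > 0 else 1.0
        return d, d / dmax, True
    r_norm = np.zeros_like(d)
    nz = d > 0
    u = (roi.pixels[nz] - bc) / d[nz, None]
    edge_dist = _ray_boundary_distances(bc, roi.contour, u)
    r_norm[nz] = d[nz] / edge_dist
    return d, r_norm, False


def radial_records(smap: StiffnessMap, roi: TumorROI) -> pd.DataFrame:
    """Per-pixel radial table: distance to barycenter (mm), r_norm, stiffness.

    One row per ROI pixel.  ``df.attrs["barycenter_fallback"]`` is True when
    the d/d_max fallback was used.
    """
    vals = _roi_values(smap, roi)
    d_px, r_norm, fallback = _radial_geometry(roi)
    df = pd.DataFrame({
        "x_px": roi.pixels[:, 0],
        "y_px": roi.pixels[:, 1],
        "distance_mm": d_px * smap.pixel_spacing_mm,
        "r_norm": r_norm,
        "stiffness_kpa": vals,
    })
    df.attrs["barycenter_fallback"] = fallback
    return df


def center_to_edge_decrease(records: pd.DataFrame) -> float:
    """Stiffness drop (kPa) from tumor center to edge.

    Ordinary least-squares fit of stiffness on r_norm over all pixels; the
    decrease is minus the slope, i.e. the fitted drop across r_norm 0 -> 1.
    Requires >= 30 records with an r_norm spread of at least 0.5.
    """
    r = np.asarray(records["r_norm"], dtype=float)
    s = np.asarray(records["stiffness_kpa"], dtype=float)
    if r.size < 30:
        raise ValueError("need >= 30 radial records")
    if r.max() - r.min() < 0.5:
        raise ValueError("r_norm spread < 0.5: radial design too degenerate")
    slope = np.polyfit(r, s, 1)[0]
    return float(-slope)


def spearman(x: np.ndarray, y: np.ndarray) -> CorrResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the large-sample t approximation.  A constant input
    leaves rho undefined; the result is returned flagged invalid rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrResult(rho=float("nan"), p=float("nan"), valid=False)
    rho, p = stats.spearmanr(x, y)
    return CorrResult(rho=float(rho), p=float(p), valid=True)


def classify_soft_stiff(mean_kpa: float, cut_kpa: float = SOFT_STIFF_CUT_KPA) -> str:
    """Soft/stiff dichotomy on mean tumor stiffness.

    Soft tumors live in the 0-40 kPa range; a mean below the cut is "soft",
    anything at or above it (boundary included) is "stiff".
    """
    if not np.isfinite(mean_kpa) or mean_kpa < 0:
        raise ValueError("mean stiffness must be finite and >= 0")
    return "soft" if mean_kpa < cut_kpa else "stiff"


def partition_center_periphery(roi: TumorROI) -> tuple[np.ndarray, np.ndarray]:
    """Split an ROI into center and periphery masks of (near) equal area.

    Center pixels satisfy r_norm <= 1/sqrt(2), which encloses half the area
    of a disk; the periphery is the remainder.  Masks are disjoint and union
    to the ROI mask.
    """
    if roi.n_pixels < 8:
        raise ValueError("ROI too small to split (< 8 pixels)")
    _, r_norm, _ = _radial_geometry(roi)
    center_sel = r_norm <= 1.0 / math.sqrt(2.0)
    center = np.zeros(roi.grid_shape, dtype=bool)
    periphery = np.zeros(roi.grid_shape, dtype=bool)
    xs = roi.pixels[:, 0].astype(int)
    ys = roi.pixels[:, 1].astype(int)
    center[ys[center_sel], xs[center_sel]] = True
    periphery[ys[~center_sel], xs[~center_sel]] = True
    return center, periphery


# ---------------------------------------------------------------------------
# Longitudinal / cohort analysis
# ---------------------------------------------------------------------------

def cohort_stiffness_growth_correlation(measurements: pd.DataFrame) -> CorrResult:
    """Spearman correlation between mean stiffness and tumor area.

    ``measurements`` needs columns ``mean_kpa`` and ``area_mm2``; every row
    is one tumor measurement at one timepoint, pooled across the tumors of
    one model.
    """
    return spearman(measurements["mean_kpa"].to_numpy(),
                    measurements["area_mm2"].to_numpy())


def growth_rate(days: np.ndarray, areas_mm2: np.ndarray) -> float:
    """Tumor growth rate in mm²/day: OLS slope of area on day."""
    days = np.asarray(days, dtype=float)
    areas = np.asarray(areas_mm2, dtype=float)
    if days.size < 2:
        raise ValueError("need >= 2 timepoints")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing (no duplicates)")
    return float(np.polyfit(days, areas, 1)[0])


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances)."""
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test."""
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)
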