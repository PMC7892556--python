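"""Collagen morphometry from SHG microscopy and trichrome histology.

Second-harmonic generation (SHG) is specific to fibrillar collagen; fiber
geometry is quantified on maximum-intensity projections of z-stacks.  Where
the original protocol traced fibrils by hand, this module substitutes a
deterministic automated analogue: threshold, skeletonize, split the
skeleton at junctions, and measure each retained path's geodesic length and
2x the medial-axis half-width.  This is a methodological replacement
validated against synthetic ground truth, not a claim of equivalence with
manual tracing.

Trichrome collagen density uses color deconvolution in optical-density
space (OD = -log10 transmittance) with unit-norm stain vectors, a single
fixed threshold per batch, and the integrated density (area x mean gray
value) over the tissue area.  The H-score summarizes immunostaining as
percent-positive x intensity on a 0-4 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "SHGStack",
    "FiberRecord",
    "RoiDensity",
    "StainModel",
    "HscorePanel",
    "max_intensity_projection",
    "segment_fibers",
    "fiber_length",
    "smoothed_path_length",
    "fiber_thickness",
    "measure_fibers",
    "integrated_density",
    "sample_rois",
    "color_deconvolve",
    "batch_collagen_threshold",
    "collagen_density",
    "stroma_percentage",
    "hscore",
    "compare_center_periphery",
]

#: Skeleton branches shorter than this many pixels are pruned.
DEFAULT_PRUNE_PX = 3


@dataclass
class SHGStack:
    """SHG z-stack: (slices, rows, cols) intensities with spatial calibration.

    Intensities are never rescaled by any operation here: acquisitions at
    constant detector voltage and laser power are directly comparable, and
    the analysis preserves that.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be 3D with >= 1 slice")
        if np.any(self.data < 0):
            raise ValueError("negative intensities")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")


@dataclass
class FiberRecord:
    """One measured collagen fiber."""

    fiber_id: int
    path: np.ndarray          # (N, 2) skeleton pixels as (row, col)
    length_um: float
    thickness_um: float
    region: str = "NA"        # {center, periphery, NA}

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise ValueError("fiber length must be positive")
        if not self.thickness_um > 0:
            raise ValueError("fiber thickness must be positive")


@dataclass
class RoiDensity:
    """ROI intensity summary; integrated density = mean gray x area."""

    roi_id: str
    area_mm2: float
    mean_gray: float

    @property
    def integrated_density(self) -> float:
        return self.mean_gray * self.area_mm2


@dataclass
class StainModel:
    """3x3 optical-density stain matrix, rows = unit-norm stain vectors.

    Row order: collagen stain, cytoplasm/nuclei stain, residual.
    """

    matrix: np.ndarray
    names: tuple = ("collagen", "cytoplasm", "residual")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(self.matrix, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain vectors must be unit-norm")
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("singular stain matrix")

    @classmethod
    def masson_trichrome(cls) -> "StainModel":
        """Default Masson-trichrome-like stain vectors.

        Methyl/aniline blue (collagen) and ponceau-fuchsin (cytoplasm/
        nuclei) OD triplets as published for ImageJ-style color
        deconvolution; the residual is their normalized cross product.
        """
        collagen = np.array([0.7995107, 0.5913521, 0.10528667])
        cytoplasm = np.array([0.09997159, 0.73738605, 0.6680326])
        residual = np.cross(collagen, cytoplasm)
        m = np.vstack([collagen / np.linalg.norm(collagen),
                       cytoplasm / np.linalg.norm(cytoplasm),
                       residual / np.linalg.norm(residual)])
        return cls(matrix=m)

    @classmethod
    def from_yaml(cls, path) -> "StainModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(matrix=np.array(cfg["matrix"], dtype=float),
                   names=tuple(cfg.get("names", ("collagen", "cytoplasm", "residual"))))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"names": list(self.names),
                            "matrix": self.matrix.tolist()}, fh)


@dataclass
class HscorePanel:
    """Fractions of cells at staining intensity 0..4 (sum to 1)."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (5,):
            raise ValueError("need fractions for intensity levels 0..4")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")


# ---------------------------------------------------------------------------
# SHG fiber morphometry
# ---------------------------------------------------------------------------

def max_intensity_projection(stack: SHGStack) -> np.ndarray:
    """Element-wise maximum over the z-slices."""
    return stack.data.max(axis=0)


def _skeleton_paths(skel: np.ndarray) -> list[np.ndarray]:
    """Split a skeleton into ordered junction-free paths.

    Junction pixels (>= 3 skeleton neighbors) are removed; each remaining
    8-connected component is ordered from one endpoint to the other.
    """
    nbr = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                           mode="constant") - skel.astype(int)
    junctions = skel & (nbr >= 3)
    branches = skel & ~junctions
    labels, n = ndimage.label(branches, structure=np.ones((3, 3), int))
    paths = []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    for lab in range(1, n + 1):
        pix = set(map(tuple, np.argwhere(labels == lab)))
        if len(pix) == 1:
            paths.append(np.array(sorted(pix)))
            continue
        deg = {p: sum(((p[0] + dr, p[1] + dc) in pix) for dr, dc in offsets)
               for p in pix}
        ends = sorted(p for p, d in deg.items() if d <= 1)
        start = ends[0] if ends else min(pix)   # cycles: arbitrary start
        path = [start]
        visited = {start}
        cur = start
        while True:
            nxt = [q for dr, dc in offsets
                   if (q := (cur[0] + dr, cur[1] + dc)) in pix and q not in visited]
            if not nxt:
                break
            # prefer 4-neighbors so the walk does not cut corners
            nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
            cur = nxt[0]
            path.append(cur)
            visited.add(cur)
        paths.append(np.array(path))
    return paths


def segment_fibers(image: np.ndarray, threshold: float | str = "auto",
                   prune_px: int = DEFAULT_PRUNE_PX
                   ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Threshold and skeletonize a projected SHG image into fiber paths.

    Returns the binary foreground mask and ordered skeleton paths, one per
    candidate fiber (skeleton split at junctions, branches shorter than
    ``prune_px`` pixels discarded).  ``threshold="auto"`` uses Otsu.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or np.any(image < 0):
        raise ValueError("expected a 2D non-negative image")
    thr = float(threshold_otsu(image)) if threshold == "auto" else float(threshold)
    mask = image > thr
    if not mask.any():
        raise ValueError("no foreground after threshold")
    skel = skeletonize(mask)
    paths = [p for p in _skeleton_paths(skel) if len(p) >= prune_px]
    return mask, paths


def fiber_length(path: np.ndarray, pixel_size_um: float) -> float:
    """Geodesic path length in µm: steps count 1 (axial) or sqrt(2) (diagonal)."""
    path = np.asarray(path)
    if len(path) < 2:
        raise ValueError("single-point path has no length")
    steps = np.abs(np.diff(path, axis=0))
    step_len = np.where(steps.sum(axis=1) == 2, math.sqrt(2.0), 1.0)
    return float(step_len.sum() * pixel_size_um)


def smoothed_path_length(path: np.ndarray, pixel_size_um: float,
                         window: int = 5) -> float:
    """Fiber length along a moving-average-smoothed centerline, in µm.

    A raw 8-connected pixel chain overestimates the length of obliquely
    oriented fibers by up to ~8% (digital staircase); smoothing the chain
    with a short moving average and summing Euclidean segment lengths
    suppresses that bias while leaving genuinely curved fibers intact
    (curvature radii well above the window are preserved).  This is the
    estimator :func:`measure_fibers` reports; :func:`fiber_length` gives
    the raw chain metric.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValueError("single-point path has no length")
    if len(path) <= window:
        seg = np.diff(path, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * pixel_size_um)
    pad = window // 2
    padded = np.pad(path, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    smooth = np.column_stack([np.convolve(padded[:, 0], kernel, mode="valid"),
                              np.convolve(padded[:, 1], kernel, mode="valid")])
    seg = np.diff(smooth, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * pixel_size_um)


def fiber_thickness(mask: np.ndarray, path: np.ndarray,
                    pixel_size_um: float) -> float:
    """Fiber thickness in µm: twice the median medial-axis half-width.

    The Euclidean distance transform gives, at each skeleton pixel, the
    center-to-center distance to the nearest background pixel; subtracting
    half a pixel converts it to the distance to the mask boundary, so the
    width is 2·(EDT − ½) — the automated analogue of a manual cross-fiber
    line (a one-pixel line measures 1 px, a 6-pixel bar 5-6 px).
    """
    path = np.asarray(path)
    if not mask[path[:, 0], path[:, 1]].all():
        raise ValueError("skeleton path leaves the fiber mask")
    edt = ndimage.distance_transform_edt(mask)
    half = np.median(edt[path[:, 0], path[:, 1]]) - 0.5
    return float(max(2.0 * half, 1.0) * pixel_size_um)


def measure_fibers(projection: np.ndarray, pixel_size_um: float,
                   threshold: float | str = "auto",
                   prune_px: int = DEFAULT_PRUNE_PX,
                   region: str = "NA") -> list[FiberRecord]:
    """Segment a projection and measure every candidate fiber."""
    mask, paths = segment_fibers(projection, threshold, prune_px)
    records = []
    for i, path in enumerate(paths):
        if len(path) < 2:
            continue
        records.append(FiberRecord(
            fiber_id=i,
            path=path,
            length_um=smoothed_path_length(path, pixel_size_um),
            thickness_um=fiber_thickness(mask, path, pixel_size_um),
            region=region,
        ))
    return records


# ---------------------------------------------------------------------------
# Density / trichrome quantification
# ---------------------------------------------------------------------------

def integrated_density(image: np.ndarray, roi_mask: np.ndarray,
                       pixel_size_mm: float, roi_id: str = "roi") -> RoiDensity:
    """Integrated density of an ROI: mean gray value x calibrated area.

    Numerically identical to (sum of pixel values) x pixel area.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    area = n * pixel_size_mm ** 2
    return RoiDensity(roi_id=roi_id, area_mm2=area,
                      mean_gray=float(np.asarray(image, dtype=float)[roi_mask].mean()))


def sample_rois(image: np.ndarray, n: int, roi_size: int, seed: int,
                min_foreground: float = 0.05,
                max_tries: int = 5000) -> list[np.ndarray]:
    """Sample n non-overlapping square ROI masks over foreground-rich positions.

    Candidate positions must carry a foreground fraction (Otsu on the image;
    a constant image counts as all-foreground) of at least
    ``min_foreground``.  Seeded and deterministic.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if n < 1:
        raise ValueError("n must be >= 1")
    if roi_size > min(h, w):
        raise ValueError("ROI size exceeds image")
    if np.ptp(image) == 0:
        fg = np.ones_like(image, dtype=bool)
    else:
        fg = image > threshold_otsu(image)
    rng = np.random.default_rng(seed)
    taken = np.zeros_like(fg, dtype=bool)
    rois: list[np.ndarray] = []
    tries = 0
    while len(rois) < n:
        if tries >= max_tries:
            raise ValueError(f"could not place {n} non-overlapping ROIs "
                             f"(placed {len(rois)})")
        tries += 1
        r = int(rng.integers(0, h - roi_size + 1))
        c = int(rng.integers(0, w - roi_size + 1))
        win = (slice(r, r + roi_size), slice(c, c + roi_size))
        if taken[win].any():
            continue
        if fg[win].mean() < min_foreground:
            continue
        mask = np.zeros_like(fg, dtype=bool)
        mask[win] = True
        taken[win] = True
        rois.append(mask)
    return rois


def color_deconvolve(rgb: np.ndarray, model: StainModel) -> np.ndarray:
    """Unmix an RGB image into per-stain concentrations (OD units).

    Optical density OD = -log10((I + 1)/256) per channel; concentrations
    solve OD = C @ M for the stain matrix M and are clamped at zero.
    Returns an (H, W, 3) array ordered like the stain rows.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    od = -np.log10((rgb + 1.0) / 256.0)
    conc = od.reshape(-1, 3) @ np.linalg.inv(model.matrix)
    return np.clip(conc, 0.0, None).reshape(rgb.shape)


def batch_collagen_threshold(concentration_images: list[np.ndarray]) -> float:
    """One Otsu threshold for a whole batch, from the pooled collagen channel.

    Computed once per batch and then frozen, so every picture of the batch
    is thresholded identically.
    """
    pooled = np.concatenate([np.asarray(c, dtype=float).ravel()
                             for c in concentration_images])
    return float(threshold_otsu(pooled))


def collagen_density(rgb: np.ndarray, model: StainModel,
                     threshold: float, tissue_mask: np.ndarray,
                     pixel_size_mm: float, roi_id: str = "tumor") -> RoiDensity:
    """Collagen density: integrated density of the thresholded collagen channel.

    The collagen concentration image (stain row 0) is zeroed below the
    batch threshold and summarized over the tissue mask with area in mm².
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValueError("empty tissue mask")
    collagen = color_deconvolve(rgb, model)[..., 0]
    collagen = np.where(collagen >= threshold, collagen, 0.0)
    return integrated_density(collagen, tissue_mask, pixel_size_mm, roi_id)


def stroma_percentage(stroma_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Percent of the tissue area occupied by stroma."""
    stroma_mask = np.asarray(stroma_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValueError("empty tissue mask")
    if np.any(stroma_mask & ~tissue_mask):
        raise ValueError("stroma mask extends outside the tissue mask")
    return 100.0 * stroma_mask.sum() / tissue_mask.sum()


def hscore(panel: HscorePanel) -> float:
    """H-score in [0, 400]: sum over intensities i of (percent at i) x i."""
    return float(np.sum(100.0 * panel.fractions * np.arange(5)))


def compare_center_periphery(table: pd.DataFrame,
                             metrics: list[str] | None = None) -> pd.DataFrame:
    """Paired center-vs-periphery statistics, pairing by tumor.

    ``table`` needs columns ``tumor_id``, ``region`` ({center, periphery})
    and one column per metric.  Every tumor must contribute both regions.
    Returns one row per metric with paired t, two-sided p and the mean
    center-minus-periphery difference; a zero-variance difference leaves t
    flagged as NaN.
    """
    if metrics is None:
        metrics = [c for c in table.columns if c not in ("tumor_id", "region")]
    rows = []
    for metric in metrics:
        wide = table.pivot_table(index="tumor_id", columns="region",
                                 values=metric, aggfunc="mean")
        if "center" not in wide.columns or "periphery" not in wide.columns \
                or wide[["center", "periphery"]].isna().any().any():
            raise ValueError(f"unpaired tumor present for metric {metric!r}")
        diff = wide["center"] - wide["periphery"]
        if np.ptp(diff.to_numpy()) == 0:
            t_stat, p = float("nan"), float("nan")
        else:
            t_stat, p = stats.ttest_rel(wide["center"], wide["periphery"])
        rows.append({"metric": metric, "t": float(t_stat), "p": float(p),
                     "mean_difference": float(diff.mean()),
                     "n_pairs": int(len(wide))})
    return pd.DataFrame(rows)
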