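"""Stiffness-map quantification: geometry, statistics and radial analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stiffquant.elastography import (AcquisitionSet, CaliperMeasure,
                                     ShearParams, StiffnessMap, TumorROI,
                                     barycenter, caliper_volume,
                                     center_to_edge_decrease,
                                     classify_soft_stiff,
                                     cohort_stiffness_growth_correlation,
                                     estimate_noise_floor, growth_rate,
                                     mean_tumor_stiffness,
                                     partition_center_periphery,
                                     pixels_in_contour, radial_records,
                                     select_representative_frame, spearman,
                                     stiffness_histogram, summarize_roi,
                                     tumor_area, young_modulus_from_shear_speed)
from stiffquant.phantoms import generate_stiffness_map

from conftest import circle_contour


# ---------------------------------------------------------------- oracles

def brute_inside(px: float, py: float, poly: np.ndarray) -> bool:
    """Crossing-number point-in-polygon test (even-odd rule)."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_ranks(v: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit sorting and tie-group averaging."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0   # average of ranks i+1..j
        i = j
    return ranks


def brute_spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = brute_ranks(x), brute_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def brute_ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc ** 2).sum())


# ---------------------------------------------------------------- physics

@pytest.mark.parametrize("vs,rho,expected", [
    (1.0, 1000.0, 3.0),
    (0.0, 500.0, 0.0),
    (5.0, 1000.0, 75.0),
])
def test_young_modulus_from_shear_speed(vs, rho, expected):
    assert young_modulus_from_shear_speed(ShearParams(vs=vs, rho=rho)) \
        == pytest.approx(expected)


def test_shear_params_reject_invalid():
    with pytest.raises(ValueError):
        ShearParams(vs=-1.0, rho=1000.0)
    with pytest.raises(ValueError):
        ShearParams(vs=1.0, rho=0.0)


# ---------------------------------------------------------------- geometry

def test_pixels_in_contour_square_interior():
    square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
    mask = pixels_in_contour(square, (20, 20))
    assert mask.sum() == 81          # strictly interior centers: 9 x 9


def test_pixels_in_contour_orientation_invariant():
    poly = circle_contour(15.0, 15.0, 8.5, n=40)
    mask_fwd = pixels_in_contour(poly, (32, 32))
    mask_rev = pixels_in_contour(poly[::-1], (32, 32))
    assert np.array_equal(mask_fwd, mask_rev)


def test_pixels_in_contour_matches_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(10):
        cx, cy = rng.uniform(10, 22, 2)
        r = rng.uniform(3, 8)
        poly = circle_contour(cx, cy, r, n=17)
        mask = pixels_in_contour(poly, (32, 32))
        for y in range(32):
            for x in range(32):
                assert mask[y, x] == brute_inside(x, y, poly)


def test_pixels_in_contour_degenerate_cases():
    with pytest.raises(ValueError):
        pixels_in_contour(np.array([[0, 0], [5, 0], [10, 0]]), (20, 20))
    # tiny triangle squeezed between pixel centers: no interior center
    tri = np.array([[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]])
    with pytest.raises(ValueError):
        pixels_in_contour(tri, (20, 20))


# ---------------------------------------------------------------- ROI stats

def test_summarize_roi_constant_and_example(flat_map, disk_roi):
    s = summarize_roi(flat_map, disk_roi)
    assert s["mean"] == pytest.approx(10.4, rel=1e-6)
    assert s["sd"] == pytest.approx(0.0, abs=1e-9)
    assert s["min"] == s["max"] == pytest.approx(10.4, rel=1e-6)


def test_summarize_roi_matches_brute_force(disk_roi):
    rng = np.random.default_rng(5)
    for _ in range(20):
        vals = np.zeros((64, 64))
        vals[disk_roi.mask] = rng.uniform(0, 150, disk_roi.n_pixels)
        smap = StiffnessMap(values=vals, pixel_spacing_mm=0.1)
        s = summarize_roi(smap, disk_roi)
        pix = [float(smap.values[int(y), int(x)]) for x, y in disk_roi.pixels]
        n = len(pix)
        mean = sum(pix) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in pix) / (n - 1))
        assert s["mean"] == pytest.approx(mean, rel=1e-9)
        assert s["sd"] == pytest.approx(sd, rel=1e-9)
        assert s["min"] == pytest.approx(min(pix))
        assert s["max"] == pytest.approx(max(pix))


def test_select_representative_frame_min_gel_and_ties():
    gel = np.zeros((8, 8), dtype=bool)
    gel[:2] = True
    frames = []
    for gel_level in (4.0, 2.0, 9.0):
        v = np.full((8, 8), 30.0)
        v[:2] = gel_level
        frames.append(StiffnessMap(values=v, pixel_spacing_mm=0.1))
    assert select_representative_frame(frames, gel) == 1
    assert select_representative_frame([frames[0]], gel) == 0
    assert select_representative_frame([frames[0], frames[0]], gel) == 0


def test_estimate_noise_floor():
    assert estimate_noise_floor(np.zeros(50)) == 0.0
    assert estimate_noise_floor(np.arange(1.0, 101.0)) == pytest.approx(95.05)
    base = np.arange(1.0, 101.0)
    bumped = base.copy()
    bumped[40] += 30.0
    assert estimate_noise_floor(bumped) >= estimate_noise_floor(base)
    with pytest.raises(ValueError):
        estimate_noise_floor(np.zeros(10))


def test_mean_tumor_stiffness_replicate_average(disk_roi):
    maps = [StiffnessMap(values=np.full((64, 64), v), pixel_spacing_mm=0.1)
            for v in (10.0, 20.0, 30.0)]
    acq = AcquisitionSet(maps=maps, rois=[disk_roi] * 3)
    assert mean_tumor_stiffness(acq) == pytest.approx(20.0, rel=1e-6)
    reordered = AcquisitionSet(maps=maps[::-1], rois=[disk_roi] * 3)
    assert mean_tumor_stiffness(reordered) == pytest.approx(20.0, rel=1e-6)
    single = AcquisitionSet(maps=maps[:1], rois=[disk_roi])
    assert mean_tumor_stiffness(single) == pytest.approx(10.0, rel=1e-6)


def test_tumor_area_scaling_and_ellipse(disk_roi):
    a1 = tumor_area(disk_roi, 0.1)
    assert a1 == pytest.approx(disk_roi.n_pixels * 0.01)
    assert tumor_area(disk_roi, 0.2) == pytest.approx(4 * a1)
    # rasterized disk area vs analytic pi r^2
    assert disk_roi.n_pixels == pytest.approx(math.pi * 20 ** 2, rel=0.02)


@pytest.mark.parametrize("a,b,expected", [(4, 2, 8), (3, 3, 13.5), (6, 3, 27)])
def test_caliper_volume(a, b, expected):
    assert caliper_volume(CaliperMeasure(a=a, b=b)) == pytest.approx(expected)


def test_caliper_rejects_swapped_axes():
    with pytest.raises(ValueError):
        CaliperMeasure(a=2, b=4)


# ---------------------------------------------------------------- histogram

def test_histogram_uniform_map(flat_map, disk_roi):
    h = stiffness_histogram(flat_map, disk_roi)
    assert h.percent_of_area[10] == pytest.approx(100.0)
    assert h.percent_of_area.sum() == pytest.approx(100.0, abs=1e-9)


def test_histogram_two_values(disk_roi):
    vals = np.zeros((64, 64))
    half = disk_roi.n_pixels // 2
    coords = disk_roi.pixels.astype(int)
    vals[coords[:half, 1], coords[:half, 0]] = 10.0
    vals[coords[half:, 1], coords[half:, 0]] = 50.0
    smap = StiffnessMap(values=vals, pixel_spacing_mm=0.1)
    h = stiffness_histogram(smap, disk_roi)
    assert h.percent_of_area[10] + h.percent_of_area[50] == pytest.approx(100.0)
    assert h.percent_of_area[10] == pytest.approx(100.0 * half / disk_roi.n_pixels)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=500.0,
                          allow_nan=False), min_size=1, max_size=200),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_histogram_sums_to_100_and_is_permutation_invariant(values, perm_seed):
    """Any pixel population yields percentages summing to 100, regardless
    of pixel order; values >= 200 land in the top bin."""
    roi = TumorROI(circle_contour(16.0, 16.0, 9.0), (32, 32))
    vals = np.resize(np.asarray(values), roi.n_pixels)
    grid = np.zeros((32, 32))
    coords = roi.pixels.astype(int)
    grid[coords[:, 1], coords[:, 0]] = vals
    h0 = stiffness_histogram(StiffnessMap(values=grid, pixel_spacing_mm=0.1), roi)
    assert h0.percent_of_area.sum() == pytest.approx(100.0, abs=1e-9)
    permuted = np.random.default_rng(perm_seed).permutation(vals)
    grid[coords[:, 1], coords[:, 0]] = permuted
    h1 = stiffness_histogram(StiffnessMap(values=grid, pixel_spacing_mm=0.1), roi)
    np.testing.assert_allclose(h0.percent_of_area, h1.percent_of_area,
                               atol=1e-9)


def test_histogram_rotation_invariant():
    smap, contour, _ = generate_stiffness_map(
        __import__("stiffquant").PRESETS["mesenchymal_stiff"], 5, seed=3)
    roi = TumorROI(contour, smap.shape)
    h0 = stiffness_histogram(smap, roi)
    h, w = smap.shape
    rot_vals = np.rot90(smap.values)
    rot_contour = np.column_stack([contour[:, 1], w - 1 - contour[:, 0]])
    rot_map = StiffnessMap(values=rot_vals, pixel_spacing_mm=smap.pixel_spacing_mm)
    rot_roi = TumorROI(rot_contour, rot_vals.shape)
    h1 = stiffness_histogram(rot_map, rot_roi)
    np.testing.assert_allclose(h0.percent_of_area, h1.percent_of_area, atol=1e-9)


# ---------------------------------------------------------------- radial

def test_barycenter_properties(disk_roi):
    bx, by = barycenter(disk_roi)
    assert abs(bx - 32.0) <= 0.5 and abs(by - 32.0) <= 0.5
    shifted = TumorROI(disk_roi.contour + [5.0, 3.0], (64, 64))
    sx, sy = barycenter(shifted)
    assert sx - bx == pytest.approx(5.0, abs=0.1)
    assert sy - by == pytest.approx(3.0, abs=0.1)


def test_radial_records_disk(flat_map, disk_roi):
    rec = radial_records(flat_map, disk_roi)
    assert len(rec) == disk_roi.n_pixels
    assert rec["r_norm"].max() <= 1.0 + 0.05
    assert rec["distance_mm"].min() == pytest.approx(0.0, abs=0.1)
    # boundary-adjacent pixels (4-neighbor touching outside) sit near r_norm 1
    mask = disk_roi.mask
    inner = mask & np.roll(mask, 1, 0) & np.roll(mask, -1, 0) \
        & np.roll(mask, 1, 1) & np.roll(mask, -1, 1)
    boundary = mask & ~inner
    sel = np.array([boundary[int(y), int(x)] for x, y in disk_roi.pixels])
    assert rec.loc[sel, "r_norm"].min() >= 0.9


def test_center_to_edge_decrease_noiseless_gradient(noiseless_stiff_preset):
    smap, contour, truth = generate_stiffness_map(noiseless_stiff_preset,
                                                  9, seed=2)
    roi = TumorROI(contour, smap.shape)
    rec = radial_records(smap, roi)
    dec = center_to_edge_decrease(rec)
    assert truth.true_center_to_edge_decrease_kpa == pytest.approx(80.0)
    assert dec == pytest.approx(80.0, abs=1.0)
    # sign flips under map complement
    flipped = StiffnessMap(values=200.0 - smap.values,
                           pixel_spacing_mm=smap.pixel_spacing_mm)
    assert center_to_edge_decrease(radial_records(flipped, roi)) \
        == pytest.approx(-dec, abs=1e-6)


def test_center_to_edge_decrease_constant_field(flat_map, disk_roi):
    assert center_to_edge_decrease(radial_records(flat_map, disk_roi)) \
        == pytest.approx(0.0, abs=1e-9)


def test_partition_center_periphery(disk_roi):
    center, periphery = partition_center_periphery(disk_roi)
    assert not (center & periphery).any()
    assert np.array_equal(center | periphery, disk_roi.mask)
    frac = center.sum() / disk_roi.n_pixels
    assert abs(frac - 0.5) <= 0.05
    bx, by = barycenter(disk_roi)
    assert center[int(round(by)), int(round(bx))]


# ---------------------------------------------------------------- statistics

def test_spearman_examples():
    x = np.arange(10.0)
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman(x, -x).rho == pytest.approx(-1.0)
    r = spearman(np.array([1, 2, 3, 4.0]), np.array([2, 1, 4, 3.0]))
    assert r.rho == pytest.approx(0.6)
    assert not spearman(np.ones(5), np.arange(5.0)).valid


def test_spearman_matches_brute_force_with_ties():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(4, 15))
        x = rng.integers(0, 6, n).astype(float)   # heavy ties
        y = rng.integers(0, 6, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        assert spearman(x, y).rho == pytest.approx(brute_spearman_rho(x, y),
                                                   abs=1e-12)


def test_classify_soft_stiff():
    assert classify_soft_stiff(15.0) == "soft"     # soft removal range 8.5-22.6
    assert classify_soft_stiff(60.0) == "stiff"    # stiff removal range 54.6-78
    assert classify_soft_stiff(40.0) == "stiff"    # boundary rule
    with pytest.raises(ValueError):
        classify_soft_stiff(-1.0)


def test_growth_rate():
    assert growth_rate([0, 10], [10, 30]) == pytest.approx(2.0)
    assert growth_rate([0, 5, 10], [7, 7, 7]) == pytest.approx(0.0)
    rng = np.random.default_rng(23)
    for _ in range(100):
        n = int(rng.integers(2, 12))
        days = np.sort(rng.choice(np.arange(100), n, replace=False)).astype(float)
        areas = rng.uniform(0, 200, n)
        assert growth_rate(days, areas) == pytest.approx(
            brute_ols_slope(days, areas), rel=1e-9)
    with pytest.raises(ValueError):
        growth_rate([0, 0, 5], [1, 2, 3])


def test_cohort_correlation_order_invariant():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"mean_kpa": rng.uniform(10, 100, 30),
                       "area_mm2": rng.uniform(20, 120, 30)})
    r1 = cohort_stiffness_growth_correlation(df)
    r2 = cohort_stiffness_growth_correlation(df.sample(frac=1, random_state=0))
    assert r1.rho == pytest.approx(r2.rho, abs=1e-12)


def test_mean_shift_monotonicity(noiseless_stiff_preset):
    """Adding c to tumor pixels raises the mean by c, leaves radial rho fixed."""
    smap, contour, _ = generate_stiffness_map(noiseless_stiff_preset, 9, seed=8)
    roi = TumorROI(contour, smap.shape)
    base = summarize_roi(smap, roi)["mean"]
    shifted_vals = smap.values.copy()
    shifted_vals[roi.mask] += 7.5
    shifted = StiffnessMap(values=shifted_vals, pixel_spacing_mm=0.1)
    assert summarize_roi(shifted, roi)["mean"] == pytest.approx(base + 7.5,
                                                                abs=1e-4)
    r0 = radial_records(smap, roi)
    r1 = radial_records(shifted, roi)
    rho0 = spearman(r0["r_norm"], r0["stiffness_kpa"]).rho
    rho1 = spearman(r1["r_norm"], r1["stiffness_kpa"]).rho
    assert rho0 == pytest.approx(rho1, abs=1e-9)
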