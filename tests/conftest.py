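"""Shared fixtures: small geometric ROIs and noiseless phantom presets."""

import math

import numpy as np
import pytest

from stiffquant.elastography import StiffnessMap, TumorROI
from stiffquant.phantoms import GrowthModel, SWEPhantomPreset


def circle_contour(cx: float, cy: float, r: float, n: int = 128) -> np.ndarray:
    phi = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])


@pytest.fixture
def disk_roi() -> TumorROI:
    """Rasterized disk of radius 20 px centered in a 64x64 grid."""
    return TumorROI(circle_contour(32.0, 32.0, 20.0), (64, 64))


@pytest.fixture
def flat_map(disk_roi) -> StiffnessMap:
    """Uniform 10.4 kPa map matching the disk ROI grid."""
    return StiffnessMap(values=np.full((64, 64), 10.4),
                        pixel_spacing_mm=0.1)


@pytest.fixture
def noiseless_stiff_preset() -> SWEPhantomPreset:
    """Stiff gradient preset with zero pixel noise (deterministic field)."""
    return SWEPhantomPreset(name="noiseless_stiff", center_kpa=120.0,
                            edge_kpa=40.0, pixel_noise_sd=0.0, gel_sd=0.0,
                            clip_range=(0.0, 200.0), stiffness_coupling=1.0)


@pytest.fixture
def flat_noiseless_preset() -> SWEPhantomPreset:
    """Degenerate preset: center == edge and no noise -> flat tumor field."""
    return SWEPhantomPreset(name="flat", center_kpa=30.0, edge_kpa=30.0,
                            pixel_noise_sd=0.0, gel_sd=0.0,
                            clip_range=(0.0, 40.0), stiffness_coupling=0.0,
                            growth=GrowthModel(area0_mm2=30.0,
                                               area_final_mm2=60.0))
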