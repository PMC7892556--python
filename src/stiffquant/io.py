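"""Readers and writers for the pipeline's on-disk formats.

Stiffness maps travel as 32-bit float TIFF (kPa) with a JSON sidecar
(pixel spacing, preset, timepoint, replicate, seed) and a contour CSV of
polygon vertices; SHG stacks as multi-page TIFF; trichrome fields as RGB
PNG; expression data as TSV (first column gene_id) with an annotation TSV
and a plain-text signature list.  The same readers accept user-supplied
files in these formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .collagen import SHGStack
from .elastography import StiffnessMap
from .transcriptomics import ExpressionDataset

__all__ = [
    "write_stiffness_map",
    "read_stiffness_map",
    "write_contour_csv",
    "read_contour_csv",
    "write_shg_stack",
    "read_shg_stack",
    "write_rgb_png",
    "read_rgb_image",
    "write_expression_tsv",
    "read_expression_tsv",
    "read_stiffness_dicom",
]


def write_stiffness_map(path: Path, smap: StiffnessMap, meta: dict | None = None) -> Path:
    """Write a map as float32 TIFF plus a ``.json`` sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, smap.values.astype(np.float32))
    sidecar = {"pixel_spacing_mm": smap.pixel_spacing_mm,
               "frame_id": smap.frame_id, **(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_stiffness_map(path: Path) -> tuple[StiffnessMap, dict]:
    """Read a TIFF + JSON sidecar pair written by :func:`write_stiffness_map`."""
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    smap = StiffnessMap(values=values,
                        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
                        frame_id=str(meta.get("frame_id", path.stem)))
    return smap, meta


def write_contour_csv(path: Path, contour: np.ndarray) -> Path:
    path = Path(path)
    pd.DataFrame(contour, columns=["x_px", "y_px"]).to_csv(path, index=False)
    return path


def read_contour_csv(path: Path) -> np.ndarray:
    """Closed polygon implied: vertices are listed once, unclosed."""
    df = pd.read_csv(path)
    return df[["x_px", "y_px"]].to_numpy(dtype=float)


def write_shg_stack(path: Path, stack: SHGStack) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     metadata={"pixel_size_um": stack.pixel_size_um,
                               "z_step_um": stack.z_step_um})
    return path


def read_shg_stack(path: Path, pixel_size_um: float, z_step_um: float = 1.0) -> SHGStack:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None, ...]
    return SHGStack(data=data, pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def write_rgb_png(path: Path, rgb: np.ndarray) -> Path:
    path = Path(path)
    iio.imwrite(path, np.clip(np.round(rgb), 0, 255).astype(np.uint8))
    return path


def read_rgb_image(path: Path) -> np.ndarray:
    rgb = iio.imread(Path(path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    return rgb.astype(float)


def write_expression_tsv(prefix: Path, ds: ExpressionDataset) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (gene_id + sample columns) and
    ``<prefix>.annotations.tsv``."""
    prefix = Path(prefix)
    expr_path = prefix.with_suffix(".tsv")
    ann_path = prefix.with_suffix(".annotations.tsv")
    ds.expr.rename_axis("gene_id").to_csv(expr_path, sep="\t")
    ds.annotations.rename_axis("sample_id").to_csv(ann_path, sep="\t")
    return expr_path, ann_path


def read_expression_tsv(expr_path: Path, annotations_path: Path,
                        log_scale: bool = False,
                        compartment: str = "NA") -> ExpressionDataset:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return ExpressionDataset(expr=expr, annotations=ann,
                             log_scale=log_scale, compartment=compartment)


def read_stiffness_dicom(path: Path, pixel_spacing_mm: float | None = None) -> StiffnessMap:
    """Optional DICOM import hook for a single-frame stiffness raster.

    Accepts a DICOM whose pixel array already holds stiffness in kPa
    (rescale slope/intercept applied when present).  Decoding the scanner's
    proprietary embedded stiffness field is out of scope; this hook is for
    rasters extracted upstream.  Requires ``pydicom``.
    """
    import pydicom

    dcm = pydicom.dcmread(str(path))
    values = dcm.pixel_array.astype(float)
    slope = float(getattr(dcm, "RescaleSlope", 1.0))
    intercept = float(getattr(dcm, "RescaleIntercept", 0.0))
    values = values * slope + intercept
    if pixel_spacing_mm is None:
        spacing = getattr(dcm, "PixelSpacing", None)
        if spacing is None:
            raise ValueError("pixel spacing absent from DICOM; pass it explicitly")
        pixel_spacing_mm = float(spacing[0])
    return StiffnessMap(values=values, pixel_spacing_mm=pixel_spacing_mm,
                        frame_id=Path(path).stem)
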