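"""Reading and writing images, boundary curves, truths and configs.

Curves travel as CSV with a ``column_index`` column followed by one
column per boundary name in anatomical order — the same layout for
segmentation output and phantom truth, so the two can be compared
directly.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import BOUNDARY_ORDER, BScan, ValidationError, Volume
from .identify import Segmentation
from .phantom import PhantomConfig, PhantomTruth
from .pipeline import PipelineConfig


def _to_unit_range(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:  # other integer encodings
        arr = arr / arr.max()
    return arr


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def read_bscan(
    path: Union[str, Path], axial_um: float = 3.9, lateral_um: float = 6.0
) -> BScan:
    """Read an 8/16-bit grayscale TIFF/PNG as a B-scan in [0, 1]."""
    arr = iio.imread(Path(path))
    return BScan(_to_unit_range(_to_gray(arr)), axial_um, lateral_um)


def read_volume(
    path: Union[str, Path], axial_um: float = 3.9, lateral_um: float = 6.0
) -> Volume:
    """Read a multi-page TIFF or a directory of ordered slices."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise ValidationError(f"no TIFF/PNG slices in {path}")
        slices = [_to_unit_range(_to_gray(iio.imread(p))) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValidationError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        return Volume(np.stack(slices), axial_um, lateral_um)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    return Volume(_to_unit_range(arr), axial_um, lateral_um)


def write_image(path: Union[str, Path], pixels: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    data = (np.clip(np.asarray(pixels, float), 0, 1) * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_volume(path: Union[str, Path], volume: Volume) -> None:
    data = (np.clip(volume.pixels, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


# -- curves -----------------------------------------------------------------


def curves_to_csv(curves: dict[str, np.ndarray], path: Union[str, Path]) -> None:
    w = len(next(iter(curves.values())))
    data = {"column_index": np.arange(w)}
    for name in BOUNDARY_ORDER:
        if name in curves:
            data[name] = np.asarray(curves[name], float)
    pd.DataFrame(data).to_csv(path, index=False)


def curves_from_csv(path: Union[str, Path]) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "column_index"]
    unknown = set(names) - set(BOUNDARY_ORDER)
    if unknown:
        raise ValidationError(f"unknown boundary columns in {path}: {sorted(unknown)}")
    return {n: df[n].to_numpy(float) for n in names}


def save_segmentation(seg: Segmentation, out_dir: Union[str, Path], stem: str = "segmentation") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves_to_csv(seg.curves, out / f"{stem}.csv")
    payload = {
        "source": seg.source,
        "shape": list(seg.shape),
        "boundaries": {n: seg.curves[n].tolist() for n in BOUNDARY_ORDER},
    }
    (out / f"{stem}.json").write_text(json.dumps(payload))


def save_truth(truth: PhantomTruth, out_dir: Union[str, Path], stem: str = "truth") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves_to_csv(truth.boundaries, out / f"{stem}.csv")
    payload = {
        "boundaries": {n: truth.boundaries[n].tolist() for n in BOUNDARY_ORDER},
        "shadow_columns": sorted(truth.shadow_columns),
        "pvf_rows": truth.pvf_rows.tolist() if truth.pvf_rows is not None else None,
        "config": truth.config.to_dict(),
    }
    (out / f"{stem}.json").write_text(json.dumps(payload))


# -- configs ----------------------------------------------------------------


def save_configs(
    path: Union[str, Path],
    phantom: Optional[PhantomConfig] = None,
    pipeline: Optional[PipelineConfig] = None,
) -> None:
    doc: dict = {}
    if phantom is not None:
        doc["phantom"] = phantom.to_dict()
    if pipeline is not None:
        doc["pipeline"] = pipeline.to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_phantom_config(path: Union[str, Path]) -> PhantomConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return PhantomConfig.from_dict(doc.get("phantom", doc))


def load_pipeline_config(path: Union[str, Path]) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(doc.get("pipeline", doc))
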