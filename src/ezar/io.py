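"""File I/O: volumes as PNG/TIFF B-scan directories, surfaces as long CSV,
masks as 0/255 PNG, feature tables as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import (
    LAYERS,
    BScanMask,
    FormatError,
    LayerSurfaces,
    OCTVolume,
    ScanGeometry,
    ValidationError,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_surfaces",
    "write_surfaces",
    "read_mask",
    "write_mask",
]

GEOMETRY_FILENAME = "geometry.json"
_IMAGE_EXTS = (".png", ".tif", ".tiff")


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as one 8-bit grayscale PNG per B-scan plus geometry.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / GEOMETRY_FILENAME).write_text(
        json.dumps(volume.geometry.to_dict(), indent=2)
    )
    width = len(str(volume.geometry.n_bscans - 1))
    for i, img in enumerate(volume.bscans):
        arr8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(path / f"bscan_{i:0{width}d}.png")
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume from a directory of B-scan images plus geometry.json.

    Images are taken in lexicographic filename order, which must equal
    B-scan index order; intensities are rescaled to [0, 1].
    """
    path = Path(path)
    geom_file = path / GEOMETRY_FILENAME
    if not geom_file.is_file():
        raise FormatError(f"missing geometry descriptor {geom_file}")
    geometry = ScanGeometry.from_dict(json.loads(geom_file.read_text()))
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS
    )
    if len(files) != geometry.n_bscans:
        raise ValidationError(
            f"found {len(files)} B-scan images, geometry says "
            f"{geometry.n_bscans}"
        )
    stack = []
    for p in files:
        arr = np.asarray(Image.open(p).convert("L"), dtype=float) / 255.0
        if arr.shape != geometry.bscan_shape:
            raise ValidationError(
                f"{p.name}: image shape {arr.shape} != geometry "
                f"{geometry.bscan_shape}"
            )
        stack.append(arr)
    return OCTVolume(geometry, np.stack(stack))


_SURFACE_COLUMNS = ["bscan", "ascan", *LAYERS]


def write_surfaces(surfaces: LayerSurfaces, path: str | Path) -> Path:
    """Write surfaces as a long-format CSV with empty cells for absence."""
    n_b, n_a = surfaces.shape
    bb, aa = np.meshgrid(np.arange(n_b), np.arange(n_a), indexing="ij")
    df = pd.DataFrame({"bscan": bb.ravel(), "ascan": aa.ravel()})
    for name in LAYERS:
        df[name] = surfaces.layer(name).ravel()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_surfaces(path: str | Path) -> LayerSurfaces:
    """Read a long-format surface CSV into dense per-layer arrays.

    The table needs columns (bscan, ascan, onl, ez, rpe, bm); empty cells
    mark absent surfaces.  The anatomical ordering invariant is checked and
    a violation reports the offending coordinates.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SURFACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"surface table missing columns {missing}")
    n_b = int(df["bscan"].max()) + 1
    n_a = int(df["ascan"].max()) + 1
    arrays = {name: np.full((n_b, n_a), np.nan) for name in LAYERS}
    bi = df["bscan"].to_numpy(dtype=int)
    ai = df["ascan"].to_numpy(dtype=int)
    for name in LAYERS:
        arrays[name][bi, ai] = df[name].to_numpy(dtype=float)
    surfaces = LayerSurfaces(**arrays)
    return surfaces.validate()


def write_mask(mask: BScanMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def read_mask(path: str | Path) -> BScanMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return BScanMask(arr >= 128)
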