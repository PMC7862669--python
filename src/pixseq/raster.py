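"""Raster I/O: multiband TIFF and PNG images, integer label rasters.

Images are held in memory as ``(H, W, bands)`` float arrays.  TIFF goes
through :mod:`tifffile`; PNG (grayscale or RGB, 8-bit) through Pillow.
Label rasters are single-band integer TIFF/PNG with codes
``{0: h, 1: c, 2: o, 255: nodata}``; the code mapping is written to a
sidecar JSON next to the raster.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .labels import LABEL_NAMES, MASKED

__all__ = ["read_image", "write_image", "read_label_raster", "write_label_raster"]

NODATA_CODE = 255


def read_image(path, nodata: float | None = None):
    """Read a TIFF/PNG into ``(H, W, bands)`` float64 plus a validity mask.

    ``nodata`` marks pixels (equal in every band) to exclude; returns
    ``(image, valid)`` where ``valid`` is None when nothing is masked.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] < arr.shape[2] and arr.shape[0] <= 16:
            arr = np.moveaxis(arr, 0, -1)  # (bands, H, W) layouts
    else:
        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    valid = None
    if nodata is not None:
        valid = ~(arr == nodata).all(axis=2)
        if valid.all():
            valid = None
    return arr, valid


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32), photometric="minisblack")
    else:
        arr = image
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.dtype != np.uint8:
            lo, hi = float(arr.min()), float(arr.max())
            scale = 255.0 / (hi - lo) if hi > lo else 1.0
            arr = ((arr - lo) * scale).round().astype(np.uint8)
        Image.fromarray(arr).save(path)


def write_label_raster(path, labels: np.ndarray) -> None:
    """Write classes as uint8 codes with 255 = nodata, plus sidecar JSON."""
    path = Path(path)
    arr = np.asarray(labels)
    out = np.where(arr == MASKED, NODATA_CODE, arr).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        Image.fromarray(out).save(path)
    mapping = {str(k): v for k, v in LABEL_NAMES.items() if k <= 2}
    mapping[str(NODATA_CODE)] = "nodata"
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(mapping, indent=2))


def read_label_raster(path) -> np.ndarray:
    """Read a label raster back to int64 with MASKED at nodata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    arr = arr.astype(np.int64)
    return np.where(arr == NODATA_CODE, MASKED, arr)
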