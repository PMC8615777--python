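"""Reading and writing the pipeline's file formats.

Images: single-page grayscale TIFF (8/16-bit) or PNG; masks: 16-bit TIFF
label images (background 0); tables: CSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import ParameterError
from .segmentation import CalibratedImage


def read_image(
    path,
    scale: float,
    *,
    experiment: str = "",
    culture: str = "",
    time_h: float = 0.0,
) -> CalibratedImage:
    """Load a grayscale micrograph (TIFF or PNG); RGB input is averaged to gray."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ParameterError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return CalibratedImage(arr, scale, experiment=experiment, culture=culture, time_h=time_h)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a grayscale image; TIFF keeps the dtype, PNG is written 8-bit."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        Image.fromarray(pixels.astype(np.uint8)).save(path)


def write_mask(path, labels: np.ndarray) -> None:
    """Write a label mask as 16-bit single-page TIFF (background 0)."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ParameterError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)
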