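"""Raster and table I/O (8-bit grayscale PNG/TIFF, CSV schemas)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .segmentation import GrayscaleImage, to_grayscale8

__all__ = ["read_image", "write_image"]


def read_image(path, scale: float | None = None,
               laterality: str = "unknown") -> GrayscaleImage:
    """Read a PNG/TIFF raster and convert to 8-bit grayscale.

    ``scale`` (mm/px) defaults to a 6-mm field of view over the raster
    width.
    """
    arr = iio.imread(Path(path))
    return to_grayscale8(arr, scale=scale, laterality=laterality)


def write_image(path, raster: np.ndarray | GrayscaleImage) -> None:
    """Write an 8-bit grayscale raster as PNG or TIFF (by extension)."""
    arr = raster.pixels if isinstance(raster, GrayscaleImage) else np.asarray(raster)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(Path(path), arr.astype(np.uint8))
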