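"""Super-resolution image reconstruction from localization tables.

Localizations are binned into a 2-D count histogram at a reconstruction
pixel size (default 10 nm) over the table's bounding box padded by one
pixel, then optionally blurred by an isotropic Gaussian whose sigma is the
dataset's NeNA precision.  Binning uses half-open pixels ``[k p, (k+1) p)``
aligned to the global nm grid, so translating all localizations by one pixel
size translates the image by exactly one pixel, and blurring uses reflective
borders, so total counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import ImageStack, LocalizationTable

__all__ = ["RenderedImage", "render_histogram", "blur_gaussian", "to_uint16"]


@dataclass
class RenderedImage:
    """2-D reconstruction with its pixel grid metadata."""

    pixels: np.ndarray
    pixel_size: float                 # nm
    origin: Tuple[float, float]       # nm of the top-left image corner (x, y)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def to_image_stack(self) -> ImageStack:
        return ImageStack(self.pixels[None], pixel_size=self.pixel_size)


def render_histogram(table: LocalizationTable,
                     pixel_size: float = 10.0) -> RenderedImage:
    """2-D count histogram of the table (total counts = table size).

    A localization exactly on a bin boundary falls into the higher-index
    bin.  An empty table renders to a 1x1 zero image.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if len(table) == 0:
        return RenderedImage(np.zeros((1, 1)), pixel_size, (0.0, 0.0))
    ix = np.floor(table.x / pixel_size).astype(np.int64)
    iy = np.floor(table.y / pixel_size).astype(np.int64)
    x0, y0 = ix.min() - 1, iy.min() - 1   # one-pixel pad
    ncols = int(ix.max() - x0) + 2
    nrows = int(iy.max() - y0) + 2
    img = np.zeros((nrows, ncols))
    np.add.at(img, (iy - y0, ix - x0), 1.0)
    return RenderedImage(img, pixel_size,
                         (float(x0 * pixel_size), float(y0 * pixel_size)))


def blur_gaussian(image: Union[RenderedImage, np.ndarray], sigma_nm: float,
                  pixel_size: float = None):
    """Convolve with an isotropic Gaussian of sd ``sigma_nm`` (reflective
    borders; the image sum is preserved).

    ``sigma_nm`` is typically the dataset's NeNA precision.  Accepts either
    a :class:`RenderedImage` (pixel size taken from it) or a raw array plus
    ``pixel_size``; returns the same type.
    """
    if sigma_nm < 0:
        raise ValueError("sigma_nm must be >= 0")
    if isinstance(image, RenderedImage):
        blurred = blur_gaussian(image.pixels, sigma_nm, image.pixel_size)
        return RenderedImage(blurred, image.pixel_size, image.origin)
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("pixel_size must be > 0 for array input")
    if sigma_nm == 0:
        return np.array(image, float, copy=True)
    return gaussian_filter(np.asarray(image, float),
                           sigma=sigma_nm / pixel_size,
                           mode="reflect", truncate=6.0)


def to_uint16(image: Union[RenderedImage, np.ndarray]) -> np.ndarray:
    """Display-only 16-bit normalization (never used for quantification)."""
    pixels = image.pixels if isinstance(image, RenderedImage) else image
    peak = pixels.max()
    if peak <= 0:
        return np.zeros_like(pixels, np.uint16)
    return np.round(pixels / peak * 65535).astype(np.uint16)
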