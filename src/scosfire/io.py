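"""Image input/output.

Images are held internally in the math frame (``img[iy, ix]`` with y up),
normalized to [0, 1]; the vertical flip to/from raster order happens only
here.  Color inputs are converted to grayscale by luminance.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "load_image",
    "save_image",
    "save_response_tiff",
    "save_stack_tiff",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as a [0, 1] grayscale array in the math frame."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / 255.0 if arr.max() <= 255 else arr / arr.max()
    return np.flipud(arr).copy()


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] math-frame array as an 8-bit grayscale image."""
    raster = np.flipud(np.clip(img, 0.0, 1.0))
    iio.imwrite(path, (raster * 255).round().astype(np.uint8))


def save_response_tiff(path: str | Path, response: np.ndarray) -> None:
    """Write a response map as 16-bit TIFF (scaled to the map maximum)."""
    m = float(response.max())
    scaled = response / m if m > 0 else response
    raster = np.flipud(np.clip(scaled, 0.0, 1.0))
    tifffile.imwrite(str(path), (raster * 65535).round().astype(np.uint16))


def save_stack_tiff(path: str | Path, stack) -> None:
    """Write a Gabor energy stack as a multi-page 16-bit TIFF, one page per
    (wavelength, orientation) channel."""
    pages = []
    for key in stack.channels:
        ch = stack.channel(*key)
        m = float(ch.max())
        scaled = ch / m if m > 0 else ch
        pages.append(np.flipud(np.clip(scaled, 0, 1)))
    arr = (np.stack(pages) * 65535).round().astype(np.uint16)
    tifffile.imwrite(str(path), arr)
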