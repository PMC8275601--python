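"""Image reading/writing: PNG/TIFF/JPEG to float [0, 1] grayscale and back.

Color inputs are collapsed to luminance with the ITU-R BT.601 weights;
integer bit depths are scaled to [0, 1] on read and re-quantized on write
(8-bit for PNG/JPEG, 16-bit or float32 for TIFF).  Arrays are row-major
with the origin at the top-left pixel.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import ParameterError, UsblurError

__all__ = ["read_image", "write_image"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read an image file as a float64 grayscale array in [0, 1]."""
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except (OSError, ValueError) as exc:
        raise UsblurError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(float) @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ParameterError(f"unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ParameterError(f"unsupported image dimensionality {arr.ndim}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.bits not in (8, 16):
            raise ParameterError(f"unsupported bit depth {info.bits}")
        arr = arr.astype(float) / info.max
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0 + 1e-9:  # float image stored on a 0..255 scale
            arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def write_image(image, path, bits: int | None = None):
    """Write a [0, 1] float image; format chosen from the file suffix.

    PNG/JPEG quantize to 8 bits (or 16 for PNG with ``bits=16``); ``.tif``
    and ``.tiff`` default to float32, or integer when ``bits`` is given.
    """
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff") and bits is None:
        iio.imwrite(path, img.astype(np.float32))
        return
    if bits is None:
        bits = 8
    if bits == 8:
        iio.imwrite(path, np.round(img * 255).astype(np.uint8))
    elif bits == 16:
        iio.imwrite(path, np.round(img * 65535).astype(np.uint16))
    else:
        raise ParameterError(f"unsupported bit depth {bits}")
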