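"""Image-quality scoring: full-reference SSIM and a block acutance map.

SSIM follows the standard definition (11x11 Gaussian window, sigma 1.5,
K1=0.01, K2=0.03, dynamic range 1) via scikit-image.  Acutance -- an
edge-contrast sharpness measure -- has no single canonical formula; the one
used here is the RMS gradient magnitude of each block over its stabilized
mean intensity, a deliberately simple, non-canonical choice (blocks with
higher acutance are sharper; a flat block scores 0).
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .exceptions import ParameterError

__all__ = ["ssim", "acutance_map"]


def ssim(a, b) -> float:
    """Structural similarity index in [-1, 1] for two [0, 1] images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ParameterError("SSIM needs two 2-D images of identical shape")
    return float(
        structural_similarity(
            a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def acutance_map(image, grid: tuple[int, int] = (10, 10)):
    """Per-block acutance and its per-row profile.

    The image is divided into ``grid = (rows, cols)`` blocks; each block's
    acutance is ``rms(|grad|) / (mean(block) + 0.01)`` -- the additive
    Weber-style constant (1% of full scale) keeps the measure finite and
    small on nearly-empty blocks (e.g. outside the scan sector), and an
    empty block scores exactly 0.  The profile is the mean over each block
    row, the vertical sharpness distribution.

    Returns ``(block_map, profile)`` with shapes ``grid`` and ``(rows,)``.
    """
    img = np.asarray(image, dtype=float)
    rows, cols = grid
    if img.ndim != 2 or rows < 1 or cols < 1:
        raise ParameterError("need a 2-D image and a positive block grid")
    if img.shape[0] < rows or img.shape[1] < cols:
        raise ParameterError("image smaller than the block grid")
    gy, gx = np.gradient(img)
    gsq = gx**2 + gy**2
    ys = np.linspace(0, img.shape[0], rows + 1).astype(int)
    xs = np.linspace(0, img.shape[1], cols + 1).astype(int)
    amap = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            blk = img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            rms = np.sqrt(gsq[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].mean())
            amap[i, j] = rms / (blk.mean() + 0.01)
    return amap, amap.mean(axis=1)
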