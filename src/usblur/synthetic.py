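"""Synthetic ultrasound-like phantoms and the forward degradation model.

``generate_phantom`` emulates the appearance of a log-compressed B-scan:
smooth anatomy-like structures (random ellipses and annuli), multiplicative
gamma speckle, logarithmic compression, and a dark sector-style border so
that essentially all image mass sits away from the frame edges.  The border
matters: it makes periodic (circular) convolution numerically identical to
linear convolution for the blur lengths of interest, so the moment and
spectrum identities used elsewhere hold to high precision in tests.

``degrade`` applies the classic degradation model

    g = f * h + n

with ``h`` the subpixel motion PSF and ``n`` additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError, SizeError
from .psf import MotionBlurParams, RasterMode, embed_kernel, make_motion_psf

__all__ = ["PhantomSpec", "generate_phantom", "degrade"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a reproducible ultrasound-like phantom.

    Defaults give a 256x256 scan with 8 structures and 4-look speckle
    (moderately compounded B-scan texture); ``border_margin`` is the width of
    the dark frame border (soft elliptical field-of-view mask).
    """

    width: int = 256
    height: int = 256
    n_structures: int = 8
    speckle_looks: float = 4.0
    seed: int = 0
    border_margin: int = 36

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ParameterError("phantom sides must be >= 64 pixels")
        if self.speckle_looks <= 0:
            raise ParameterError("speckle_looks must be positive")
        if self.n_structures < 0:
            raise ParameterError("n_structures must be >= 0")


def _anatomy(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sum of random filled ellipses / annuli, smoothed: the 'tissue' field."""
    h, w = spec.height, spec.width
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    bg = np.full((h, w), 0.25)
    for _ in range(spec.n_structures):
        cx = rng.uniform(0.25 * w, 0.75 * w)
        cy = rng.uniform(0.25 * h, 0.75 * h)
        ax = rng.uniform(0.06, 0.22) * w
        ay = rng.uniform(0.06, 0.22) * h
        phi = rng.uniform(0.0, np.pi)
        amp = rng.uniform(0.25, 0.9)
        dx, dy = xs - cx, ys - cy
        u = (dx * np.cos(phi) + dy * np.sin(phi)) / ax
        v = (-dx * np.sin(phi) + dy * np.cos(phi)) / ay
        r2 = u * u + v * v
        blob = (r2 <= 1.0).astype(float)
        if rng.uniform() < 0.35:  # hollow it into an annulus (cyst wall)
            blob -= (r2 <= rng.uniform(0.15, 0.5)).astype(float) * rng.uniform(0.6, 1.0)
        bg += amp * blob
    return ndimage.gaussian_filter(bg, sigma=4.0)


def _fov_mask(spec: PhantomSpec) -> np.ndarray:
    """Soft elliptical field-of-view: ~1 inside, 0 within the border margin."""
    h, w, m = spec.height, spec.width, spec.border_margin
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    u = (xs - (w - 1) / 2) / ((w - 1) / 2 - m)
    v = (ys - (h - 1) / 2) / ((h - 1) / 2 - m)
    r = np.sqrt(u * u + v * v)
    # cosine taper over the last 15% of the field radius
    t = np.clip((1.0 - r) / 0.15, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> np.ndarray:
    """Generate a deterministic ultrasound-like phantom in [0, 1].

    Pipeline: anatomy field -> multiplicative unit-mean gamma speckle with
    shape ``speckle_looks`` -> log compression -> rescale to [0, 1] ->
    soft dark border.  Same spec (including seed) always returns the same
    array.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = _anatomy(spec, rng)
    speckle = rng.gamma(shape=spec.speckle_looks, scale=1.0 / spec.speckle_looks,
                        size=tissue.shape)
    img = tissue * speckle
    # log compression (display dynamic-range mapping used by scanners)
    mu = 60.0
    img = np.log1p(mu * img) / np.log1p(mu * max(img.max(), 1e-12))
    img = np.clip(img, 0.0, None)
    img = img / max(img.max(), 1e-12)
    return img * _fov_mask(spec)


def degrade(
    image: np.ndarray,
    params: MotionBlurParams,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    boundary: str = "periodic",
) -> np.ndarray:
    """Apply motion blur plus additive Gaussian noise: ``g = f * h + n``.

    Convolution uses the subpixel PSF.  ``boundary="periodic"`` (default)
    performs circular convolution via the FFT, under which the spectral and
    moment identities used by the estimators are exact; ``"replicate"``
    extends edge values (more realistic visually, excluded from exactness
    tests).  ``noise_sigma`` is the noise standard deviation on the [0, 1]
    intensity scale; the result is clipped to [0, 1].
    """
    f = np.asarray(image, dtype=float)
    if f.ndim != 2:
        raise ParameterError("expected a single-channel 2-D image")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    psf = make_motion_psf(params, RasterMode.SUBPIXEL)
    if psf.shape[0] > f.shape[0] or psf.shape[1] > f.shape[1]:
        raise SizeError(f"kernel {psf.shape} exceeds image {f.shape}")
    if boundary == "periodic":
        otf = np.fft.fft2(embed_kernel(psf, f.shape[1], f.shape[0]))
        g = np.fft.ifft2(np.fft.fft2(f) * otf).real
    elif boundary == "replicate":
        g = ndimage.convolve(f, psf.weights, mode="nearest")
    else:
        raise ParameterError(f"unknown boundary mode {boundary!r}")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sigma, size=g.shape)
    return np.clip(g, 0.0, 1.0)
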