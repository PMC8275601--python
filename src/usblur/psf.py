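"""Discrete linear-motion point-spread functions and their frequency response.

A uniform straight-line camera/probe motion of length ``L`` pixels at angle
``theta`` (degrees, counterclockwise from the horizontal image axis) smears
every point of the scene into a line segment.  The continuous PSF is the
normalized line measure

    h(x, y) = (1/L) * delta-line of length L through the origin at angle theta,

whose Fourier transform is a sinc ridge: ``H`` equals 1 at DC and vanishes on
a family of parallel lines perpendicular to the motion direction.  This module
builds discrete versions of ``h`` (two rasterization modes), evaluates the
analytic optical transfer function (OTF) on a DFT grid, and provides the
numerical OTF of a kernel embedded in a frame.

Coordinate convention
---------------------
Arrays are indexed ``[row, col]`` with ``x = col`` and ``y = row``; the angle
is measured counterclockwise in that (x, y) frame.  Because the row axis
points down on screen, a displayed kernel appears mirrored vertically
relative to the mathematical plane; all estimators in this package use the
same frame, so angles round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .exceptions import ParameterError, SizeError

__all__ = [
    "MotionBlurParams",
    "PSFKernel",
    "FrequencyResponse",
    "RasterMode",
    "make_motion_psf",
    "analytic_otf",
    "psf_otf",
    "sinc",
    "save_kernel_txt",
    "load_kernel_txt",
    "save_kernel_tiff",
    "load_kernel_tiff",
]


def sinc(x):
    """Unnormalized sinc, ``sin(x)/x`` with ``sinc(0) = 1``.

    The first positive zero is at ``x = pi``.  (numpy's ``np.sinc`` is the
    normalized variant ``sin(pi x)/(pi x)``; this wrapper hides the factor.)
    """
    return np.sinc(np.asarray(x) / np.pi)


class RasterMode(str, Enum):
    """How the continuous line segment is committed to the pixel grid."""

    #: one entry per unit step along the dominant axis, snapped to the
    #: nearest pixel -- reproduces the printed-matrix style of kernel
    MATRIX = "matrix"
    #: area-weighted coverage of the segment by each pixel footprint --
    #: centrosymmetric, accurate moments and OTF
    SUBPIXEL = "subpixel"


@dataclass(frozen=True)
class MotionBlurParams:
    """The (L, theta) pair parameterizing a linear motion blur.

    Parameters
    ----------
    length : float
        Blur extent ``L`` in pixels (probe speed x exposure time).  Must be
        positive; ``L <= 1`` means the motion stays within one pixel and the
        blur degenerates to the identity kernel.
    angle : float
        Motion direction ``theta`` in degrees, normalized into [0, 180):
        a symmetric segment is invariant under ``theta -> theta + 180``.
    """

    length: float
    angle: float

    def __post_init__(self):
        if not np.isfinite(self.length) or self.length <= 0:
            raise ParameterError(f"blur length must be positive, got {self.length}")
        if not np.isfinite(self.angle):
            raise ParameterError(f"blur angle must be finite, got {self.angle}")
        object.__setattr__(self, "angle", float(self.angle) % 180.0)
        object.__setattr__(self, "length", float(self.length))

    @property
    def direction(self) -> tuple[float, float]:
        """Unit vector (cos theta, sin theta) of the motion."""
        t = np.deg2rad(self.angle)
        return float(np.cos(t)), float(np.sin(t))


@dataclass(frozen=True)
class PSFKernel:
    """A small nonnegative kernel summing to 1 with an explicit center."""

    weights: np.ndarray
    center: tuple[int, int]  # (row, col) of the kernel origin
    mode: RasterMode = RasterMode.SUBPIXEL
    params: MotionBlurParams | None = field(default=None, compare=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ParameterError("kernel weights must be a 2-D array")
        if np.any(w < 0):
            raise ParameterError("kernel weights must be nonnegative")
        s = w.sum()
        if s <= 0:
            raise ParameterError("kernel weights must not be all zero")
        object.__setattr__(self, "weights", w / s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def _kernel_side(length: float, cos_t: float, sin_t: float) -> int:
    """Odd square side covering the segment endpoints plus 2 px padding."""
    side = int(np.ceil(length * max(abs(cos_t), abs(sin_t)))) + 2
    return side if side % 2 == 1 else side + 1


def _matrix_weights(length: float, cos_t: float, sin_t: float) -> np.ndarray:
    """Nearest-pixel rasterization, one sample per dominant-axis step.

    ``round(L)`` samples are placed at unit spacing along the dominant axis
    with the minor coordinate snapped to the nearest pixel.  At 45 degrees
    with L = 7 this yields the classic 7x7 diagonal kernel with seven equal
    entries of 1/7.  Collisions (shallow angles) stack weight; the kernel is
    renormalized so the sum is always exactly 1.
    """
    k = max(1, int(round(length)))
    if k == 1:
        return np.ones((1, 1))
    steps = np.arange(k, dtype=float) - (k - 1) / 2.0
    if abs(cos_t) >= abs(sin_t):  # x-major
        xs = steps
        ys = steps * (sin_t / cos_t)
    else:  # y-major
        ys = steps
        xs = steps * (cos_t / sin_t)
    xi = np.floor(xs + 0.5).astype(int)
    yi = np.floor(ys + 0.5).astype(int)
    half = max(np.max(np.abs(xi)), np.max(np.abs(yi)))
    side = 2 * int(half) + 1
    w = np.zeros((side, side))
    np.add.at(w, (yi + half, xi + half), 1.0)
    return w


def _subpixel_weights(length: float, cos_t: float, sin_t: float) -> np.ndarray:
    """Area-weighted coverage of a unit-width segment of length L.

    Each pixel footprint is treated separably in the rotated frame: with
    ``t`` the along-motion and ``s`` the across-motion coordinate of the
    pixel center, the weight is the overlap of a unit box centered at ``t``
    with ``[-L/2, L/2]`` times the overlap of a unit box centered at ``s``
    with ``[-1/2, 1/2]``.  The result is exactly centrosymmetric, so all
    odd-order central moments vanish.
    """
    side = _kernel_side(length, cos_t, sin_t)
    c = (side - 1) // 2
    ys, xs = np.mgrid[0:side, 0:side]
    x = xs - c
    y = ys - c
    t = x * cos_t + y * sin_t
    s = -x * sin_t + y * cos_t
    wt = np.clip(np.minimum(t + 0.5, length / 2) - np.maximum(t - 0.5, -length / 2), 0.0, 1.0)
    ws = np.clip(np.minimum(s + 0.5, 0.5) - np.maximum(s - 0.5, -0.5), 0.0, 1.0)
    return wt * ws


def make_motion_psf(
    params: MotionBlurParams, mode: RasterMode | str = RasterMode.SUBPIXEL
) -> PSFKernel:
    """Construct the discrete linear-motion PSF kernel.

    Parameters
    ----------
    params : MotionBlurParams
        Blur length (pixels) and angle (degrees, [0, 180)).
    mode : {"matrix", "subpixel"}
        ``matrix`` snaps line samples to the nearest pixel (printed-matrix
        style); ``subpixel`` uses anti-aliased area coverage and should be
        preferred for simulation, moments and deconvolution.

    Returns
    -------
    PSFKernel
        Odd-sided square kernel, entries >= 0 summing to 1, origin at the
        central pixel.  ``L <= 1`` returns the 1x1 identity kernel in either
        mode.
    """
    mode = RasterMode(mode)
    if params.length <= 1.0:
        return PSFKernel(np.ones((1, 1)), (0, 0), mode, params)
    cos_t, sin_t = params.direction
    if mode is RasterMode.MATRIX:
        w = _matrix_weights(params.length, cos_t, sin_t)
    else:
        w = _subpixel_weights(params.length, cos_t, sin_t)
    c = (w.shape[0] - 1) // 2
    return PSFKernel(w, (c, c), mode, params)


def analytic_otf(params: MotionBlurParams, u, v, width: int, height: int):
    """Analytic OTF of the motion PSF on the (M x N) DFT grid.

    Evaluates ``sinc(pi * L * (u cos(theta)/M + v sin(theta)/N))`` with the
    unnormalized sinc, so the zero lines fall at

        u cos(theta)/M + v sin(theta)/N = +/- k / L,   k = 1, 2, ...

    in cycles-per-pixel units -- i.e. the first zero along the motion
    direction sits at ``L * omega / 2 = pi`` in radian units.  The value is
    real, lies in [-0.2173, 1] and equals 1 at (u, v) = (0, 0).

    ``u`` indexes the horizontal (width M) frequency axis, ``v`` the
    vertical (height N) axis; both are plain (unshifted) DFT bin indices and
    may be arrays.
    """
    if width < 1 or height < 1:
        raise ParameterError("frame dimensions must be >= 1")
    cos_t, sin_t = params.direction
    omega = np.asarray(u) * cos_t / width + np.asarray(v) * sin_t / height
    return sinc(np.pi * params.length * omega)


@dataclass(frozen=True)
class FrequencyResponse:
    """Numerical OTF of a kernel embedded in an (M x N) frame."""

    values: np.ndarray  # complex, unshifted DFT layout, indexed [v, u]
    width: int
    height: int

    @property
    def dc(self) -> complex:
        return complex(self.values[0, 0])


def embed_kernel(psf: PSFKernel, width: int, height: int) -> np.ndarray:
    """Zero-embed a kernel in an (height x width) frame, center at index (0, 0)."""
    kh, kw = psf.shape
    if kh > height or kw > width:
        raise SizeError(f"kernel {psf.shape} larger than frame ({height}, {width})")
    big = np.zeros((height, width))
    big[:kh, :kw] = psf.weights
    return np.roll(big, (-psf.center[0], -psf.center[1]), axis=(0, 1))


def psf_otf(psf: PSFKernel, width: int, height: int) -> FrequencyResponse:
    """DFT of the kernel zero-embedded in an M x N frame (center-at-origin).

    The DC coefficient equals the kernel sum (1 by construction); for
    subpixel-mode kernels the response tracks :func:`analytic_otf` closely at
    low frequencies (the pixel-footprint transfer function only bites near
    Nyquist).
    """
    return FrequencyResponse(np.fft.fft2(embed_kernel(psf, width, height)), width, height)


# -- plain-text / TIFF kernel exchange ---------------------------------------

def save_kernel_txt(psf: PSFKernel, path):
    np.savetxt(path, psf.weights, fmt="%.17g")


def load_kernel_txt(path, mode: RasterMode | str = RasterMode.SUBPIXEL) -> PSFKernel:
    w = np.atleast_2d(np.loadtxt(path))
    c = ((w.shape[0] - 1) // 2, (w.shape[1] - 1) // 2)
    return PSFKernel(w, c, RasterMode(mode))


def save_kernel_tiff(psf: PSFKernel, path):
    import imageio.v3 as iio

    iio.imwrite(Path(path), psf.weights.astype(np.float32), extension=".tiff")


def load_kernel_tiff(path, mode: RasterMode | str = RasterMode.SUBPIXEL) -> PSFKernel:
    import imageio.v3 as iio

    w = np.asarray(iio.imread(Path(path)), dtype=float)
    c = ((w.shape[0] - 1) // 2, (w.shape[1] - 1) // 2)
    return PSFKernel(w, c, RasterMode(mode))
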