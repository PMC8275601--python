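"""Geometric moments, the moment convolution theorem, and moment-based
motion-blur estimation.

For an image ``f`` the geometric moment of order (p+q) is

    m_pq = sum_{x,y} f(y, x) x^p y^q            (x = column, y = row)

Moments of a convolution ``g = f * h`` are binomial combinations of the
factors' moments; with the centered symmetric motion PSF all odd-order PSF
moments vanish and the even ones have the closed form

    m_pq(h) = (L/2)^(p+q) cos^p(theta) sin^q(theta) / (p + q + 1).

From the second-order relations the blur direction and length follow:

    theta = atan( sqrt( (mu02_g - mu02_f) / (mu20_g - mu20_f) ) )
    L     = 2 sqrt(3) sqrt( (mu20_g + mu02_g - mu20_f - mu02_f) / m00 )

All estimator formulas are applied to CENTRAL moments: blurring with a
centered kernel preserves the centroid, so the central-moment versions hold
regardless of where the image sits in the frame (the raw-moment forms would
depend on the arbitrary coordinate origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .exceptions import (
    DegenerateImageError,
    InconsistentMomentsError,
    NoBlurDetectedError,
    ParameterError,
)
from .psf import MotionBlurParams

__all__ = [
    "MomentTable",
    "MomentInvariantSet",
    "geometric_moments",
    "psf_moments_closed_form",
    "psf_moment_table",
    "convolve_moments",
    "deconvolve_moments",
    "estimate_angle_moments",
    "estimate_length_moments",
    "invariant_set",
]


@dataclass(frozen=True)
class MomentTable:
    """All moments m_pq with p+q <= max_order for one image or PSF."""

    values: dict
    max_order: int
    origin: str = "raw"  # "raw" (pixel-grid origin) or "central" (centroid)
    source: str = "image"

    def m(self, p: int, q: int) -> float:
        return self.values[(p, q)]

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("p,q,value\n")
            for (p, q), v in sorted(self.values.items()):
                fh.write(f"{p},{q},{v!r}\n")


@dataclass(frozen=True)
class MomentInvariantSet:
    """Blur-invariant values M_r by order r = 0..max_order."""

    values: dict
    params_est: MotionBlurParams | None = None

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("order,value\n")
            for r, v in sorted(self.values.items()):
                fh.write(f"{r},{v!r}\n")


def geometric_moments(image, max_order: int = 4, origin: str = "raw") -> MomentTable:
    """Geometric moments of a 2-D nonnegative image up to ``max_order``.

    ``origin="raw"`` takes x^p y^q about the pixel-grid origin (0-based pixel
    centers at integers); ``origin="central"`` about the intensity centroid
    (m10/m00, m01/m00), which makes the result translation invariant.
    """
    f = np.asarray(image, dtype=float)
    if f.ndim != 2:
        raise ParameterError("expected a 2-D image")
    if max_order < 0 or max_order > 6:
        raise ParameterError("max_order must be in 0..6")
    if origin not in ("raw", "central"):
        raise ParameterError(f"unknown origin {origin!r}")
    h, w = f.shape
    x = np.arange(w, dtype=float)
    y = np.arange(h, dtype=float)
    total = f.sum()
    if origin == "central":
        if total <= 0:
            raise DegenerateImageError("central moments of an all-zero image")
        xc = float((f.sum(axis=0) * x).sum() / total)
        yc = float((f.sum(axis=1) * y).sum() / total)
        x = x - xc
        y = y - yc
    xp = np.vander(x, max_order + 1, increasing=True).T  # (p, x)
    yq = np.vander(y, max_order + 1, increasing=True).T  # (q, y)
    # m[p, q] = yq_q . f . xp_p
    grid = yq @ f @ xp.T  # (q, p)
    values = {
        (p, q): float(grid[q, p])
        for p in range(max_order + 1)
        for q in range(max_order + 1)
        if p + q <= max_order
    }
    return MomentTable(values, max_order, origin)


def psf_moments_closed_form(params: MotionBlurParams, p: int, q: int) -> float:
    """Closed-form moment of the continuous centered line PSF.

    ``(L/2)^(p+q) cos^p(theta) sin^q(theta) / (p+q+1)`` for even p+q, zero
    for odd p+q (the segment is symmetric about the origin).
    """
    if p < 0 or q < 0:
        raise ParameterError("moment orders must be nonnegative")
    if (p + q) % 2 == 1:
        return 0.0
    c, s = params.direction
    return (params.length / 2.0) ** (p + q) * c**p * s**q / (p + q + 1)


def psf_moment_table(params: MotionBlurParams, max_order: int = 4) -> MomentTable:
    values = {
        (p, q): psf_moments_closed_form(params, p, q)
        for p in range(max_order + 1)
        for q in range(max_order + 1)
        if p + q <= max_order
    }
    return MomentTable(values, max_order, origin="raw", source="psf")


def _check_compatible(a: MomentTable, b: MomentTable):
    if a.max_order != b.max_order:
        raise ParameterError(
            f"moment tables have different max_order ({a.max_order} vs {b.max_order})"
        )


def convolve_moments(f_moments: MomentTable, h_moments: MomentTable) -> MomentTable:
    """Moments of ``g = f * h`` from the factors' moments (exact identity).

    Both tables must share the origin convention: image moments about the
    pixel-grid origin (or centroid) and PSF moments about the kernel center.
    """
    _check_compatible(f_moments, h_moments)
    out = {}
    for (p, q) in f_moments.values:
        acc = 0.0
        for k in range(p + 1):
            for l in range(q + 1):
                if k + l > h_moments.max_order:
                    continue
                acc += comb(p, k) * comb(q, l) * h_moments.m(k, l) * f_moments.m(p - k, q - l)
        out[(p, q)] = acc
    return MomentTable(out, f_moments.max_order, f_moments.origin, source="image")


def deconvolve_moments(g_moments: MomentTable, h_moments: MomentTable) -> MomentTable:
    """Invert the moment convolution identity: recover f's moments from g's.

    Solved recursively in increasing total order; the (k, l) = (0, 0) term
    contains the unknown m_pq(f) with coefficient m00(h) = 1, every other
    term involves strictly lower-order f moments already recovered.
    """
    _check_compatible(g_moments, h_moments)
    out = {}
    for r in range(g_moments.max_order + 1):
        for p in range(r + 1):
            q = r - p
            acc = g_moments.m(p, q)
            for k in range(p + 1):
                for l in range(q + 1):
                    if (k, l) == (0, 0) or k + l > h_moments.max_order:
                        continue
                    acc -= comb(p, k) * comb(q, l) * h_moments.m(k, l) * out[(p - k, q - l)]
            out[(p, q)] = acc / h_moments.m(0, 0)
    return MomentTable(out, g_moments.max_order, g_moments.origin, source="image")


_REL_EPS = 1e-9


def estimate_angle_moments(g_moments: MomentTable, f_moments: MomentTable) -> float:
    """Blur direction (degrees in [0, 90]) from second-order central moments."""
    if g_moments.origin != "central" or f_moments.origin != "central":
        raise ParameterError("angle estimation requires central moments")
    d20 = g_moments.m(2, 0) - f_moments.m(2, 0)
    d02 = g_moments.m(0, 2) - f_moments.m(0, 2)
    scale = max(abs(f_moments.m(2, 0)), abs(f_moments.m(0, 2)), 1e-300)
    tol = _REL_EPS * scale
    if d20 <= tol and d02 <= tol:
        raise NoBlurDetectedError("second-order moments show no blur spread")
    if d20 < -tol or d02 < -tol:
        raise InconsistentMomentsError(
            "moment differences have mixed signs inconsistent with motion blur"
        )
    d20, d02 = max(d20, 0.0), max(d02, 0.0)
    if d20 == 0.0:
        return 90.0
    return float(np.rad2deg(np.arctan(np.sqrt(d02 / d20))))


def estimate_length_moments(g_moments: MomentTable, f_moments: MomentTable) -> float:
    """Blur length (pixels) from the second-order central-moment excess."""
    if g_moments.origin != "central" or f_moments.origin != "central":
        raise ParameterError("length estimation requires central moments")
    num = (
        g_moments.m(2, 0) + g_moments.m(0, 2) - f_moments.m(2, 0) - f_moments.m(0, 2)
    )
    m00 = f_moments.m(0, 0)
    if m00 <= 0:
        raise DegenerateImageError("clean image has no mass")
    if num <= _REL_EPS * (abs(f_moments.m(2, 0)) + abs(f_moments.m(0, 2))):
        raise NoBlurDetectedError("no second-order spread excess: no blur to measure")
    return float(2.0 * np.sqrt(3.0) * np.sqrt(num / m00))


def invariant_set(image, blurred, max_order: int = 4) -> MomentInvariantSet:
    """Blur-invariant moment features M_0..M_max_order of a (clean, blurred) pair.

    M_0 is the total mass m00 and M_1 the magnitude of the raw first-order
    moment vector (m10, m01); both are preserved exactly by a centered,
    normalized blur.  For r >= 2 the blur parameters are first estimated from
    the second-order moment excess, the closed-form PSF moments are formed,
    and the clean image's central moments are reconstructed by inverting the
    moment convolution identity; M_r is the Euclidean norm of the order-r
    vector of reconstructed central moments.  Computed on the clean image
    itself (or an unblurred copy) the same values fall out directly.

    Odd orders are invariant for free: the centered PSF's odd moments vanish
    and first-order central moments are zero, so every order-3 correction
    term in the convolution identity is identically zero.
    """
    f = np.asarray(image, dtype=float)
    g = np.asarray(blurred, dtype=float)
    if f.shape != g.shape:
        raise ParameterError("image pair must share a shape")
    g_raw = geometric_moments(g, max_order, "raw")
    g_cen = geometric_moments(g, max_order, "central")
    f_cen = geometric_moments(f, max_order, "central")
    values = {0: g_raw.m(0, 0), 1: float(np.hypot(g_raw.m(1, 0), g_raw.m(0, 1)))}
    try:
        theta = estimate_angle_moments(g_cen, f_cen)
        length = estimate_length_moments(g_cen, f_cen)
        params = MotionBlurParams(length, theta)
        rec = deconvolve_moments(g_cen, psf_moment_table(params, max_order))
    except NoBlurDetectedError:
        params = None
        rec = g_cen
    for r in range(2, max_order + 1):
        vec = [rec.m(p, r - p) for p in range(r + 1)]
        values[r] = float(np.sqrt(np.sum(np.square(vec))))
    return MomentInvariantSet(values, params)
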