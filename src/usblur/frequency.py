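"""Frequency-domain blur invariants and (theta, L) recovery from spectrum ratios.

In the noiseless model the degraded spectrum is ``G = F . H`` with the sinc
OTF of the motion PSF, so the ratio ``G/F`` at the two lowest nonzero DFT
bins identifies the blur:

    a = sinc^-1( G(0,1) / F(0,1) )      (v = 1 bin: vertical frequency)
    b = sinc^-1( G(1,0) / F(1,0) )      (u = 1 bin: horizontal frequency)

With the conventions of :mod:`usblur.psf`, ``a = pi L sin(theta) / N`` and
``b = pi L cos(theta) / M``, hence

    tan(theta) = (a N) / (b M),   L = sqrt((a N)^2 + (b M)^2) / pi,

and the ratio at EVERY frequency is predicted by the single invariant form

    xi(u, v) = sinc(a v + b u),

independent of the image content.  The inversion lives on the principal
(first-lobe) branch of sinc, [0, pi): blurs long enough to push the (0,1) or
(1,0) ratio past the first zero are outside the method's validity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import DegenerateImageError, OutOfBranchError, ParameterError
from .psf import MotionBlurParams, sinc

__all__ = [
    "SpectrumPair",
    "ABPair",
    "InvariantRecord",
    "FrequencyEstimate",
    "sinc_inverse",
    "compute_ab",
    "angle_length_from_ab",
    "xi",
    "invariant_table",
    "invariant_table_to_csv",
    "estimate_params_from_pair",
]

_IMAG_TOL = 1e-6


@dataclass(frozen=True)
class SpectrumPair:
    """Unshifted 2-D DFTs of a clean image F and its degraded version G."""

    F: np.ndarray
    G: np.ndarray
    width: int
    height: int

    @classmethod
    def from_images(cls, clean, degraded) -> "SpectrumPair":
        f = np.asarray(clean, dtype=float)
        g = np.asarray(degraded, dtype=float)
        if f.shape != g.shape or f.ndim != 2:
            raise ParameterError("clean/degraded images must be 2-D and share a shape")
        if abs(f.sum()) < 1e-12:
            raise DegenerateImageError("clean image is (near) black: F(0,0) ~ 0")
        return cls(np.fft.fft2(f), np.fft.fft2(g), f.shape[1], f.shape[0])


@dataclass(frozen=True)
class ABPair:
    """Principal-branch sinc inverses of the two low-frequency ratios."""

    a: float  # from G(0,1)/F(0,1): pi L sin(theta) / N
    b: float  # from G(1,0)/F(1,0): pi L cos(theta) / M
    width: int
    height: int


@dataclass(frozen=True)
class InvariantRecord:
    u: int
    v: int
    amplitude: float
    phase: float  # radians in (-pi, pi]
    valid: bool = True


@dataclass(frozen=True)
class FrequencyEstimate:
    """(theta, L) recovered from an ABPair; length 0 flags 'no blur'."""

    length: float
    angle: float
    no_blur: bool = False

    def to_params(self) -> MotionBlurParams:
        if self.no_blur:
            raise ParameterError("no blur detected: no PSF parameters to build")
        return MotionBlurParams(self.length, self.angle)


def sinc_inverse(r: float) -> float:
    """Invert sin(x)/x on the principal branch [0, pi).

    ``r`` must lie in (0, 1]; solved by scalar root bracketing to 1e-12.
    """
    if not np.isfinite(r):
        raise OutOfBranchError(f"ratio {r} is not finite")
    if r > 1.0 + 1e-9 or r <= 0.0:
        raise OutOfBranchError(
            f"ratio {r:.6g} outside the principal sinc branch (0, 1]"
        )
    if r >= 1.0:
        return 0.0
    return float(brentq(lambda x: sinc(x) - r, 0.0, np.pi - 1e-12, xtol=1e-12))


def _real_ratio(pair: SpectrumPair, v: int, u: int) -> float:
    fv = pair.F[v % pair.height, u % pair.width]
    gv = pair.G[v % pair.height, u % pair.width]
    fscale = np.abs(pair.F[0, 0])
    if np.abs(fv) < 1e-9 * fscale:
        raise DegenerateImageError(
            f"clean spectrum coefficient F({u},{v}) is (near) zero"
        )
    r = gv / fv
    if np.abs(r.imag) > _IMAG_TOL * max(np.abs(r), 1e-12) + _IMAG_TOL:
        raise OutOfBranchError(
            f"ratio at (u={u}, v={v}) is not real (imag {r.imag:.3g}); "
            "PSF not centered/symmetric?"
        )
    return float(r.real)


def compute_ab(pair: SpectrumPair) -> ABPair:
    """Measure a and b from the (0,1) and (1,0) spectrum ratios."""
    ra = _real_ratio(pair, v=1, u=0)
    rb = _real_ratio(pair, v=0, u=1)
    return ABPair(
        a=sinc_inverse(min(ra, 1.0)),
        b=sinc_inverse(min(rb, 1.0)),
        width=pair.width,
        height=pair.height,
    )


def angle_length_from_ab(ab: ABPair) -> FrequencyEstimate:
    """Recover (theta, L) in degrees/pixels from an ABPair.

    ``a N`` and ``b M`` are the components of ``pi L (sin theta, cos theta)``,
    so the angle is their arctangent and the length their norm over pi.
    ``a = b = 0`` signals no blur (L = 0 sentinel with the ``no_blur`` flag);
    ``b = 0`` alone maps to vertical motion (theta = 90 degrees).
    """
    ay = ab.a * ab.height
    bx = ab.b * ab.width
    if ay == 0.0 and bx == 0.0:
        return FrequencyEstimate(length=0.0, angle=0.0, no_blur=True)
    theta = float(np.rad2deg(np.arctan2(ay, bx)))
    length = float(np.hypot(ay, bx) / np.pi)
    return FrequencyEstimate(length=length, angle=theta)


def estimate_params_from_pair(clean, degraded) -> FrequencyEstimate:
    """Convenience: images -> spectra -> (a, b) -> (theta, L)."""
    return angle_length_from_ab(compute_ab(SpectrumPair.from_images(clean, degraded)))


def xi(u, v, ab: ABPair):
    """The frequency blur invariant: predicted ratio G/F at any (u, v).

    ``xi(u, v) = sinc(a v + b u)``; equals 1 at DC and matches the measured
    ratio across frequencies for a consistent linear motion blur.
    """
    return sinc(ab.a * np.asarray(v) + ab.b * np.asarray(u))


def invariant_table(pair: SpectrumPair, freqs) -> list[InvariantRecord]:
    """Measured amplitude/phase of G/F at selected (u, v) frequencies.

    Frequencies where the clean spectrum is numerically zero are returned
    flagged invalid (amplitude/phase NaN) rather than raised.
    """
    freqs = list(freqs)
    if not freqs:
        raise ParameterError("freqs must be nonempty")
    fscale = np.abs(pair.F[0, 0])
    records = []
    for u, v in freqs:
        fv = pair.F[v % pair.height, u % pair.width]
        gv = pair.G[v % pair.height, u % pair.width]
        if np.abs(fv) < 1e-9 * fscale:
            records.append(InvariantRecord(int(u), int(v), np.nan, np.nan, valid=False))
            continue
        r = gv / fv
        records.append(
            InvariantRecord(int(u), int(v), float(np.abs(r)), float(np.angle(r)))
        )
    return records


def invariant_table_to_csv(records, path):
    with open(path, "w") as fh:
        fh.write("u,v,amplitude,phase_rad\n")
        for rec in records:
            fh.write(f"{rec.u},{rec.v},{rec.amplitude!r},{rec.phase!r}\n")
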