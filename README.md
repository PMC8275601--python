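# usblur

Linear motion-blur modelling, blur invariants, blind PSF estimation and
Wiener restoration for ultrasound B-scans.

Freehand ultrasound is acquired while the probe moves. When the motion is
fast relative to the frame (or frames are compounded), the scan is degraded
by a *linear motion blur*: every point is smeared into a line segment of
length `L` pixels at angle `θ`. The usual model is

    g = f * h + n

with `f` the sharp scan, `h` the motion point-spread function (PSF), `n`
additive noise. For uniform straight-line motion,

    h(x, y) = (1/L) ∫_{-L/2}^{L/2} δ(x − t cos θ) δ(y − t sin θ) dt,

whose Fourier transform is a sinc ridge, `H(u, v) =
sinc(π L (u cos θ / M + v sin θ / N))` on an M×N DFT grid: `H(0,0) = 1` and
`H` vanishes on parallel lines perpendicular to the motion — the geometry
every estimator in this package exploits.

The package is aimed at people working on ultrasound image quality:
it lets you **simulate** the degradation on synthetic speckled phantoms,
**identify** `(θ, L)` from data, and **restore** the scan.

Three independent routes to the blur parameters are implemented:

* **frequency invariants** (needs the clean image): from
  `a = sinc⁻¹[G(0,1)/F(0,1)]` and `b = sinc⁻¹[G(1,0)/F(1,0)]` follow
  `tan θ = aN/(bM)`, `L = √((aN)² + (bM)²)/π`, and the ratio at *every*
  frequency is predicted by the single invariant `ξ(u,v) = sinc(av + bu)`;
* **moment invariants** (needs the clean image): geometric moments of a
  convolution are binomial combinations of the factors' moments; the
  centered line PSF has closed-form moments
  `m_pq(h) = (L/2)^{p+q} cos^p θ sin^q θ / (p+q+1)` (zero for odd `p+q`), so
  second-order central moments give
  `θ = atan √((μ02_g − μ02_f)/(μ20_g − μ20_f))` and
  `L = 2√3 √((μ20_g + μ02_g − μ20_f − μ02_f)/m00)`, and orders 0–4 yield
  blur-invariant features `M_r`;
* **blind spectral estimation** (single image): the log power spectrum of
  the image gradient shows periodic dark "zero lines"; a Radon-transform
  orientation search reads `θ`, the line spacing `d` gives `L = N/d`
  (square frame), and a ringing-minimization polish refines both before
  Wiener deconvolution.

## Worked example

Everything below runs on synthetic data; no scans are required.

```console
$ usblur synth --seed 7 -o phantom.png
$ usblur blur phantom.png -l 20 -a 30 -o blurred.png
$ usblur estimate blurred.png
angle: 30.50 deg  length: 19.76 px (ratio 4.32, 16 minima)
$ usblur deblur blurred.png --blind -o restored.png
estimated angle 30.00 deg, length 19.98 px
$ usblur quality blurred.png --ref phantom.png
SSIM: 0.6850
mean acutance: 0.0721
BRISQUE: n/a (needs a pretrained natural-scene model)
$ usblur quality restored.png --ref phantom.png
SSIM: 0.8569
mean acutance: 0.2118
BRISQUE: n/a (needs a pretrained natural-scene model)
```

The blind estimate lands within 0.5° and 0.3 px of the true (30°, 20 px)
blur; the polish used inside `deblur --blind` tightens it to (30.00°,
19.98 px). Restoration raises SSIM against the clean phantom from 0.685 to
0.857 (0.91 when the pipeline is run in floating point rather than through
8-bit PNGs) and roughly triples the mean block acutance of the blurred
input. The `ratio` diagnostic is the orientation-energy score; values below
2 mean "no blur detected", in which case `deblur --blind` returns the image
unchanged.

The same operations are available as functions:

```python
import usblur as ub

clean   = ub.generate_phantom(ub.PhantomSpec(seed=7))
blurred = ub.degrade(clean, ub.MotionBlurParams(length=20, angle=30))
restored, est = ub.blind_deblur(blurred)
print(est.angle, est.length, ub.ssim(restored, clean))
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the DC gain and energy normalization of generated
PSF kernels over an (L, θ) grid; the nonzero count of the printed-style
matrix kernel at L=7, 45°; the moment-route recovery of (θ, L) on a
256×256 phantom blurred at (30 px, 60°); and the blind spectral recovery of
the angle at (40 px, 45°) and of the length at (60 px, 30°). Results are
written as JSON, one entry per quantity.

## Layout

| module | contents |
| --- | --- |
| `usblur.psf` | `MotionBlurParams`, kernel rasterization (matrix/subpixel), analytic and numeric OTF |
| `usblur.frequency` | spectrum ratios, `sinc⁻¹`, the ξ invariant, (θ, L) from (a, b) |
| `usblur.moments` | geometric moments, convolution theorem, closed-form PSF moments, estimators, invariant set |
| `usblur.blind` | gradient spectrum map, Radon angle search, zero-spacing length, full pipeline |
| `usblur.restore` | Wiener deconvolution, ringing-minimization refinement, blind deblurring |
| `usblur.quality` | SSIM, block acutance map |
| `usblur.synthetic` | speckled phantom generator, forward degradation model |
| `usblur.io`, `usblur.cli` | image I/O and the `usblur` command |

See `docs/methods.md` for the model details, parameter defaults, numerical
choices and known limitations.
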