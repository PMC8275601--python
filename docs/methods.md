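# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `usblur`, and what the synthetic tests do and do
not establish.

## Degradation model and conventions

A scan `g` is modelled as `g = f * h + n`: circular (FFT) convolution of
the sharp scan `f` with the normalized linear-motion PSF `h(L, θ)` plus
additive Gaussian noise. Arrays are indexed `[row, col]` with `x = col`,
`y = row`; the angle θ is counterclockwise in that (x, y) frame and
normalized into [0, 180) (the symmetric kernel is invariant under
θ → θ + 180°). Because the row axis points down on screen, a displayed
kernel appears vertically mirrored relative to the blackboard convention;
all estimators use the same frame, so angles round-trip exactly. `L ≤ 1`
(motion within one pixel) is the identity kernel by definition.

### Kernel rasterization

* **subpixel** (default): each pixel's weight is the separable overlap of
  its unit footprint with the length-L, unit-width segment in the rotated
  frame. The kernel is exactly centrosymmetric (all odd-order central
  moments vanish at machine precision), entries are renormalized to sum
  exactly to 1, and the side is the odd integer ≥ `ceil(L·max(|cosθ|,
  |sinθ|)) + 2`.
* **matrix**: `round(L)` samples at unit spacing along the dominant axis,
  minor coordinate snapped to the nearest pixel — the style in which such
  kernels are usually printed (at L=7, 45° this is the 7×7 diagonal of
  1/7). Collisions at shallow angles stack weight; the sum is still
  renormalized to 1. Published examples of the 30°/60°/85° variants follow
  rasterization rules that differ between sources (some do not even sum to
  1); only the 45° form is treated as canonical.

The discrete subpixel kernel is the continuous line *convolved with the
pixel footprint*: its second moments exceed the continuous closed form by
≈ 1/12 px² along the line and ≈ 1/6 px² across it. Relative to the natural
scale of order-(p+q) moments, `(L/2)^{p+q}/(p+q+1)`, this bias is O(1/L²):
about 10% at L = 8 and under 2% from L ≈ 15 up, which is where the
closed-form-vs-numeric agreement is asserted in the tests. The moment
estimators are nevertheless accurate well below L = 15 because the bias
largely cancels in the g−f moment differences.

### OTF convention

`analytic_otf` evaluates `sinc(π L (u cosθ/M + v sinθ/N))` with the
unnormalized `sinc(x) = sin(x)/x`, so zero lines fall at
`u cosθ/M + v sinθ/N = ±k/L` in cycles-per-pixel units — for a square
frame, a spacing of `N/L` frequency bins along the motion direction. The
numeric OTF (`psf_otf`) is the DFT of the kernel embedded center-at-origin;
its DC value equals the kernel sum (exactly 1) and it tracks the analytic
form at low frequencies, departing near Nyquist by the pixel-footprint
transfer function.

## Frequency-domain identification

With spectra `F`, `G` of the clean and blurred images, `a = sinc⁻¹` of the
ratio at the (0,1) bin and `b` at (1,0) give `θ = atan2(aN, bM)` and
`L = √((aN)² + (bM)²)/π`. The inversion uses Brent root-bracketing on the
principal branch [0, π) to 1e-12; ratios outside (0, 1] are rejected
(`OutOfBranchError`) — blurs long enough to push the first-bin ratio past
the first sinc zero (`L sinθ > N` or `L cosθ > M`) are outside the method's
validity range. The ratios are theoretically real for a centered symmetric
PSF; the imaginary part is checked against a 1e-6 relative tolerance before
being discarded. The invariant `ξ(u,v) = sinc(av + bu)` then predicts the
ratio at every frequency; on noiseless synthetic phantoms the median
|prediction − measurement| over the 11×11 lowest bins is below 0.005.

## Moment-domain identification

The moment convolution theorem and the closed-form line moments give the
second-order relations; the estimators apply them to **central** moments of
`f` and `g`. As printed in raw-moment form the relations hold only when the
PSF is centered at the coordinate origin; a centered kernel preserves the
centroid, so the central-moment version is origin-independent — the package
computes it that way throughout. The blur-invariant set is

* `M₀ = m00`, `M₁ = |(m10, m01)|` (raw moments, preserved exactly by any
  centered normalized blur with periodic boundaries),
* `M₂..M₄`: the clean image's central moments are reconstructed from the
  blurred ones by inverting the convolution theorem (a triangular recursion
  over increasing order) using the closed-form PSF moments at the (θ̂, L̂)
  estimated from second-order differences; `M_r` is the Euclidean norm of
  the order-r vector of reconstructed moments. Order 3 is invariant for
  free: with first-order central moments zero and odd PSF moments zero, all
  its correction terms vanish.

On four blurs spanning (20 px, 30°) to (50 px, 85°) the spread of each
`M_r` across versions is below 0.01%.

## Blind spectral estimation

The pipeline (single blurred image, no reference):

1. **Spectrum map**: sum of the power spectra of the two central-difference
   gradient components, Hann-windowed, log-compressed, DC-centered. The
   gradient must remain *linear* — a gradient-magnitude map destroys the
   spectral zeros (this failure mode is easy to reproduce). Radial
   whitening (subtracting the per-radius mean) removes the isotropic
   spectral falloff; maps are confined to the inscribed disc so all Radon
   projections share a support.
2. **Angle**: Radon projection variance of the bilateral-smoothed whitened
   map, coarse 1° sweep refined at 0.25°, maximum at projection angle
   `φ = 180° − θ` (bin coordinates; non-square frames stretch the angle and
   are converted). Blur detection uses the binarized map (threshold = the
   per-radius mean, i.e. a radially adaptive threshold): the max/median
   variance ratio is ≥ ~2.5 for blurred phantoms and ≤ ~1.6 for sharp ones
   or white noise; the no-blur threshold is fixed at 2.0.
3. **Length**: the *unsmoothed* whitened map (bilateral smoothing at
   σ_spatial = 3 bins erases line combs spaced ≲ 4 bins) is upsampled 2×
   and projected along the lines; the projection angle is re-optimized
   within ±2° for maximal oscillation contrast. Minima of the detrended
   projection below its 25th percentile, merged within 2 bins and refined
   parabolically, mark the zero lines; the spacing is the median gap
   stabilized by a least-squares fit of position against line index, and
   `L̂ = S/d` with the effective extent
   `S = MN/√((N cosθ)² + (M sinθ)²)` (= N for square frames).

Fixed defaults: bilateral σ_spatial = 3 bins, σ_range = 10% of dynamic
range; detrend σ = 8 bins; minima prominence = 0.2 standard deviations of
the detrended projection. On the noiseless 256² grid L ∈ {20,30,40,60} ×
θ ∈ {0°,30°,45°,60°,85°} the estimator is within 2° and 10% in every cell
(max observed error 1.75°, 2.8%). The validity floor is reached when fewer
than two zero lines fit in the usable radius (roughly L < 2·frame/usable
radius, e.g. L = 3 on a 64² frame → `LengthIndeterminateError`).

## Restoration

Wiener deconvolution in its constant noise-to-signal form,
`F̂ = conj(H)·G/(|H|² + nsr)`, clipped to [0, 1]. The full spectral-prior
form is stated in terms of the (unknown in practice) signal and noise power
spectra; `nsr="auto"` provides a crude estimate (top-decile-radius power
over total power). Optional edge tapering blends the borders toward the
circularly blurred image to suppress ringing for non-periodic scenes.

Blind deblurring is acutely sensitive to sub-pixel errors in L̂ (the
restoration divides by a model OTF whose zero lines must coincide with the
data's). A **refinement stage** therefore polishes (θ̂, L̂) by minimizing
the out-of-range energy of the *unclipped* restoration (a local grid of
θ ± 1°, L ± 7% followed by Nelder-Mead): a correct noiseless model restores
to an in-range image, while mismatch produces over/undershoot. On the
synthetic grid this polish typically lands within 0.1 px and 0.1° of the
truth and is what makes restoration beat the blurred input in every cell.
The default `nsr = 3e-4` for blind restoration balances sharpening against
ringing from residual parameter error; noisy inputs need a noise-matched
value (e.g. 3e-3 at ~40 dB SNR).

## Quality metrics

SSIM is the standard Gaussian-window form (11×11, σ = 1.5, K1 = 0.01,
K2 = 0.03, dynamic range 1). The acutance map divides the image into a
block grid (default 10×10) and scores each block `rms(|∇g|)/(mean + 0.01)`;
the additive constant keeps nearly-empty blocks (outside the scan sector)
finite and small. Acutance has no canonical definition; this one is chosen
for simplicity and is labelled non-canonical. Blockwise, blur never
increases it where blocks contain tissue. BRISQUE is deliberately excluded:
it requires a pretrained natural-scene-statistics model that cannot be
shipped or downloaded here; the CLI prints `n/a` in its place.

## Synthetic phantoms

`generate_phantom` emulates a log-compressed B-scan: a smooth anatomy field
(sum of random ellipses and annuli, Gaussian-smoothed, σ = 4 px) times
unit-mean gamma speckle with shape `speckle_looks` (default 4, moderate
compounding; 1 would be fully developed speckle), log compression
(`log(1+60x)` rescaled), and a soft elliptical field-of-view mask that
leaves a dark border (default margin 36 px). The border is deliberate: it
makes circular convolution numerically identical to linear convolution for
the blur lengths of interest, so the moment and spectrum identities used by
the estimators and tests hold essentially exactly. Everything is
deterministic per seed.

What the phantom does **not** model: depth-dependent speckle correlation
and beam width, attenuation, shadowing, refraction artefacts, nonlinear
scan conversion, or probe-geometry-dependent (spatially varying) motion.
A green test on these phantoms establishes correctness of the mathematics
and robustness to multiplicative speckle at realistic contrast — not
clinical performance, where blur is rarely exactly linear or spatially
invariant.

## Known limitations

* All estimators assume a single, global, straight-line blur; curved or
  spatially varying motion is out of scope.
* The frequency route needs `L sinθ < N` and `L cosθ < M` (first-lobe
  branch); the blind route needs at least two resolvable zero lines and
  degrades near the bin-Nyquist line spacing (L approaching frame/2).
* Angle estimates carry a 180° ambiguity by nature (the kernel is
  symmetric) and the moment route additionally folds into [0°, 90°].
* Noise: the moment relations are derived for the noiseless model; under
  additive noise the blind angle estimate degrades gracefully but the
  length minima fill in first. No hard accuracy bounds are asserted under
  noise.
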