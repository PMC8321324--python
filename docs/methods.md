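# Methods

## Degradation model

The veiling-glare degradation is modelled as linear shift-invariant
convolution, `i' = K_α ⊗ i`, with a kernel built from the CIE general
disability-glare equation.  The curve (implemented in `deglare.gsf`)
is a sum of three Lorentzian-type lobes with angular half-widths 0.0046°,
0.045° and 0.1°, an age term growing as `(age/70)^4`, an ocular
pigmentation term `PF`, and small constant floors.  Defaults are age 70
years and PF 0.5 (a middle-of-range pigmentation); both are configurable
(`GSFCurveParams`).  The curve spans nine orders of magnitude: an extreme
forward peak well inside one pixel, plus a wide shallow veil.

Two numerical choices matter when the curve becomes a pixel kernel:

- **Pixel-footprint core.**  At fundus-camera sampling (45° field over
  400 px, 0.1125°/px — both configurable) the forward peak is ~25×
  narrower than one pixel.  Point-sampling the curve at θ = 0 would give
  the central pixel ~99% of the kernel mass and make the modelled
  degradation invisible.  The central pixel therefore receives the
  *analytic disc average* of the curve over its own half-width; all five
  CIE terms integrate in closed form against `2πθ dθ`
  (`gsf_disc_integral`).  Off-centre pixels use the point value at their
  centre angle, which is accurate because the curve is locally smooth
  there.
- **Glare angle as angular scale.**  The searched parameter α rescales
  the curve's angular axis: a pixel at radial angle θ receives
  `GSF(θ/α)`.  α = 0 degenerates to the identity (delta) kernel; larger α
  spreads the same curve over wider angles, moving kernel mass from the
  core into the veil (central weight 0.64 at 1°, 0.29 at 5°).  An
  alternative reading — α as a hard truncation half-angle of the fixed
  curve — was implemented and rejected: consecutive truncated kernels
  differ only by an outer annulus carrying < 1% of the mass, so the
  induced angle is not identifiable from the image (even an oracle that
  compares against the ground truth prefers α+1 at larger angles), and
  the simulated degradation is imperceptible (SSIM ≥ 0.998 at 5°).
  Under the scale reading, kernels of different α differ at all radii and
  degradation severity grows realistically (SSIM versus truth falls
  0.81 → 0.43 over 1..8°).

Kernel support is truncated where the rescaled curve is negligible
(default `support_factor = 3`, i.e. 3α, capped at the full grid radius of
twice the image size); weights are normalised to unit sum after
truncation.  The full 2×-radius grid can be materialised with
`build_kernel(..., crop=False)`; cropping the all-zero margin does not
change convolution results.

## Richardson-Lucy deconvolution

`deglare.richardson_lucy` implements the multiplicative update with the
both-axes-flipped kernel as adjoint.  Convolution runs in the frequency
domain (`scipy.signal.fftconvolve`) after padding the image by edge
replication out to the kernel support radius, which avoids wrap-around
ringing; a direct spatial path (`convolve_direct`) exists for
cross-checking and agrees to 1e-10 on small fixtures.  The ratio
denominator is guarded at 1e-12.  The initial estimate is the observed
image.  Iterates are kept unclipped internally (non-negativity is
automatic); clipping to [0, 1] happens only for scoring and export.

## Step 1: glare-angle search

For α = 0, 1·step, 2·step, … the search builds the kernel, runs a short
fixed-length RL probe (default 10 updates) against the observed image,
and measures the probe's sharpness (mean gradient magnitude) after
min-max remapping to display range.  The remap is the load-bearing
nonlinearity: a probe with an oversized kernel overcorrects, pushing
values outside the data's range; remapping divides the measured gradients
by that inflated range, so the display-range sharpness has an interior
maximum at the matched angle instead of growing monotonically with kernel
strength.  Greedy hill climbing stops at the first strict decrease and
returns the predecessor; ties continue; hitting `alpha_max` (default 15°)
returns the ceiling with a warning.  A single-update probe was tried
first and rejected: one multiplicative update corrects so little of the
veil that the sharpness trace is monotone in α under every variant
measured (raw, clipped, both kernel families), leaving no local maximum
for the hill climb to find.  Ten updates are enough for the probe to
approach its asymptote at the matched angle while staying cheap; the
value is configurable (`probe_iterations`).

On the canonical star the search recovers every induced angle in
0..8° exactly.  On low-contrast fundus-like charts, whose intensities do
not span the full display range, the overcorrection penalty is weaker and
the search can overshoot by a few degrees; the iteration optimiser then
compensates by stopping earlier, and restoration quality remains good.
This content dependence is a known limitation.

## Step 2: trained quality model and stopping rule

The no-reference model (`deglare.quality`) tiles an image into
non-overlapping `block_size` blocks (default 40 px, i.e. 100 blocks of a
400×400 image; incomplete edge blocks are discarded) and extracts per
block the mean luminance, the within-block intensity variance and the
mean gradient-magnitude sharpness.  Blocks below the 25th percentile of
per-image block sharpness are dropped (low-information background); the
threshold is configurable and the same selection applies during training
and scoring, so an image scored against a model trained only on itself
has distance exactly 0.  A Gaussian (mean, population covariance) is
fitted to the features pooled over all reference images; population form
makes the model invariant to duplicated references.  The score of a test
image is `−d` with

```
d = sqrt( (ν_r − ν_t)^T [ (Σ_r + Σ_t)/2 ]^{-1} (ν_r − ν_t) )
```

(the symmetric NIQE-style Gaussian distance); near-singular pooled
covariances are ridge-regularised on the diagonal (1e-8 × trace/dim) with
a logged warning.  Models persist as JSON with exact float round-trip.

The iteration optimiser scores each RL iterate (clipped to display
range) and stops once the score has failed to improve on the best seen
for `patience` consecutive iterations (default 3), returning the
best-scoring iterate.  A strict first-decrease rule was tried and
rejected: the hard selection threshold makes the score trace jitter by
~1e-2 between adjacent iterates, so a patience-free rule stops at noise
long before the score's actual maximum.  `max_iterations` (default 200)
caps the search with a warning.

The reference set defines what "restored" should look like, so it must be
domain-matched: the generator's fixture sets use full-contrast star
charts whose spoke counts span the family evenly around the canonical
32-spoke target, with seeded rotation phases.  Both of the mismatches
this avoids were observed directly: pooling charts of widely varying
contrast or skewed spoke counts places the reference Gaussian *between*
the degraded and restored statistics, so the score peaks mid-restoration
and the stop fires with the veil only partly removed.

## Synthetic data

`siemens_star` renders alternating angular sectors (levels
`(1±contrast)/2` inside a disc of radius 0.45·size) at 4× supersampling
followed by box-downsampling, to keep pixel-level aliasing from
dominating the sharpness metric.  `fundus_chart` renders a vignetted
background, a soft-edged bright disc and thin dark vessel arcs, emulating
the one property of retinal photographs this package's segmentation
demonstration needs: faint edges that a fixed Canny threshold loses under
veiling and regains after restoration.  `degrade` is exact kernel
convolution — the restoration's own forward model.  What passing tests on
these fixtures show is therefore self-consistency: parameter recovery and
restoration quality under the model's stated assumptions.  They do not
show robustness to ray-traced or real-eye degradations, sensor noise,
spatially varying glare, or kernel-model mismatch, none of which the
generator emulates.

## Segmentation

Grayscale conversion uses BT.601 luminance weights (0.299/0.587/0.114);
binarisation is Otsu's between-class-variance threshold (constant images
yield an all-false mask with a warning); edges come from Canny with
σ = 1.4 and hysteresis thresholds (sensitivity/2, sensitivity).  By
default Canny runs on the grayscale image with the binarised image kept
as an intermediate; a flag reproduces the literal
grayscale→binarise→Canny order.  `segment_pair` applies one sensitivity
to both images of a degraded/restored comparison by construction.

## Problem sizes and determinism

All experiments use the 400×400 chart at 0.1125°/px; the acceptance
script trains on 5 reference charts and completes in well under a minute
on one core.  The only randomness anywhere is the fixture generator's
seed (reference spoke phases); detection, deconvolution, scoring and
segmentation are fully deterministic, and identical inputs give
bit-identical restorations.

## Known limitations

- Glare-angle detection assumes the image's natural range spans most of
  display range; low-contrast content weakens the overshoot penalty and
  can bias detection upward.
- The quality model's 3-feature Gaussian is deliberately simple; it
  encodes "statistically similar to the reference corpus", not human
  opinion, and needs a domain-matched corpus to place its maximum at full
  restoration.
- The kernel is global: spatially varying or wavelength-dependent
  straylight is out of scope, as are regularised RL variants and
  noise-model extensions.
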