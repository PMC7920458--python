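# Methods

## Purpose and model

`tvphantom` benchmarks edge-preserving noise reduction for PET images whose
attenuation correction derives from MR pulse sequences, using a fully
synthetic stand-in for the scanner experiment: a digital Jaszczak phantom,
a parametric acquisition-degradation chain, and a four-arm denoising
comparison scored with contrast-to-noise ratio (CNR) and coefficient of
variation (COV).

The denoising model is the Rudin–Osher–Fatemi (ROF) objective on a 2-D
image `f` observed as `I`:

    phi[f | I] = sum_{m,n} sqrt((f[m,n]-f[m-1,n])^2 + (f[m,n]-f[m,n-1])^2)
                 + (lambda/2) * sum_{m,n} (I[m,n] - f[m,n])^2

The first term is the (isotropic) total-variation seminorm with backward
differences — the L1 norm of the per-pixel gradient magnitude — which
penalizes oscillation but charges a step edge only once, so edges survive
while noise does not. The second term anchors the estimate to the data;
`lambda` trades smoothing against fidelity (the study value is 0.1 on
intensities normalized to [0, 1]). Boundary differences use replicate
padding: an out-of-range neighbour equals the pixel itself, contributing
zero, so no artificial edge is created at the image border. The printed
form of the fidelity weight is ambiguous between `lambda*2` and `lambda/2`;
we use the standard ROF `(lambda/2)`, which only rescales the meaning of
`lambda` by a factor of 4.

## Solver

`denoise_tv` minimizes the epsilon-smoothed objective (epsilon = 1e-8 added
inside the square root to make it differentiable) by explicit gradient
descent from `f0 = I` with a monotone line search: each iteration minimizes
the objective along the negative gradient over step sizes in
`(0, step]` with a bounded scalar search, and falls back to step halving if
the search fails. Any step that would increase the objective is rejected,
so the recorded objective trace is non-increasing by construction.
Iteration stops when the relative objective decrease falls below `rel_tol`
(default 1e-5), when no descent step exists, or at `max_iters`
(default 200).

Two numerical points motivated the line search over naive halving-only
backtracking. First, the smoothed objective is stiff: its Hessian scales
like `1/sqrt(epsilon)` wherever the local gradient magnitude is below
`sqrt(epsilon)`, so stable steps are ~1e-4 even when `step` is 0.1, and a
power-of-two step ladder quantizes the total descent "time" accumulated in
a fixed iteration budget. Second, and consequently, with quantized steps
the 200-iteration endpoint is a discontinuous function of the input: two
images differing by a 2% smooth bias could land on different step ladders
and end with uniform-region residuals differing by tens of percent, which
is solver noise, not image content. The continuous line search makes the
iterate path vary smoothly with the data; with generous iteration budgets
the same solver reaches the objective value of a general-purpose
quasi-Newton minimizer to ~1e-11 relative on small test problems.

At the study defaults the solver is intentionally *not* run to full
convergence: the exact minimizer of the ROF objective at `lambda = 0.1` on
a [0, 1]-scaled image flattens the phantom globally (the interior mean
drops by half), which contradicts the method's purpose of removing noise
while preserving structure. Two hundred line-searched iterations sit in the
mild-smoothing regime: uniform-region noise drops by roughly an order of
magnitude while rods and the cylinder rim remain visible. The iteration cap
and tolerance are exposed in `TVParams` and recorded in `DenoiseResult`.

## Digital phantom

The Jaszczak quality-control phantom is modelled as a uniform activity disk
(radius 100 mm, activity 1.0) in a 256 x 256 grid of 2 mm pixels,
containing six 60-degree sectors of cold rods with the standard commercial
diameters {4.8, 6.4, 7.9, 9.5, 11.1, 12.7} mm on triangular lattices with
centre-to-centre pitch twice the diameter. Rods are kept only if the full
rod circle stays inside the cylinder wall, clear of both sector boundary
lines (reproducing the physical insert's uniform lanes), and outside a
rod-free central hub of 32 mm radius — the hub is sized to twice the
default reference-ROI radius so the reference region stays uniform under
blur and denoising spillover. Rasterization uses area-weighted
anti-aliasing (4 x 4 sub-pixel sampling), so the pixel-counted hot area
matches the analytic disk-minus-rods area to well under 1%.

## Degradation chain

Render -> blur -> bias -> noise, in that order:

1. **System blur.** Isotropic Gaussian PSF, default FWHM 4.0 mm (a typical
   whole-body PET resolution scale), replicate boundary handling. This is
   the source of the partial-volume effect: smaller rods lose more apparent
   cold contrast, monotonically in diameter.
2. **Acquisition non-uniformity.** A multiplicative field `1 + b` where `b`
   is white Gaussian noise smoothed to a 60 mm correlation length (FWHM of
   the smoothing kernel) and affinely mapped to `[-amplitude, 0]`: the
   field models regional signal loss from imperfect MR-based attenuation
   correction, normalized so the best-corrected region keeps full
   intensity. (A constant multiplicative offset would be indistinguishable
   from a change in injected activity, so the field is anchored at zero
   rather than made zero-mean; profiles then differ in uniformity, not in
   global calibration.) The two shipped profiles differ only in amplitude —
   `caipi_like` 0.02, `grappa_like` 0.08 — chosen to reproduce the
   *ordering* of the CAIPIRINHA- versus GRAPPA-derived PET images (the more
   uniform acquisition scores better on both metrics), never their
   percentages.
3. **Noise.** I.i.d. zero-mean Gaussian noise of variance 0.001 on the
   [0, 1] intensity scale (images exceeding 1 are first divided by their
   maximum and the scale recorded in the provenance). Values are not
   clipped: clipping would truncate the Gaussian and bias both ROI means
   and standard deviations.

Seeding: one base seed drives everything. Replicate `r` adds noise with
seed `base_seed + r` (auditable in the run log); the bias field uses seed
`base_seed + 1_000_003` so its white-noise stream never coincides with a
replicate noise stream.

## Metrics and study design

Circular ROIs use a deterministic membership rule (pixel centre within the
radius, inclusive). Statistics are the ROI mean `H` and *sample* (n-1)
standard deviation `sigma`; then

    CNR = (H_A - H_B) / sqrt(sigma_A^2 + sigma_B^2)      (sign preserved)
    COV = sigma_A / H_A

Defaults: ROI A radius 8 px at the phantom centre (inside the uniform hub),
ROI B radius 8 px outside the cylinder near a corner. Both are
config-exposed assumptions. A zero denominator raises a
`MetricUndefinedError` rather than returning infinity.

The replicated study runs 2 profiles x 4 arms (unfiltered noise, 3 x 3
local-adaptive Wiener, 3 x 3 median, TV) x 10 noise replicates; the same
replicate seeds are used for both profiles, so profile contrasts are paired
comparisons in which the noise realization cancels. Aggregates (replicate
mean and sd per profile/arm) are always recomputable from the tidy
per-replicate table. Failing cells are logged and recorded as NaN rather
than dropped.

The Wiener arm is the local-adaptive estimator
`mu + max(var - v, 0)/max(var, 1e-12) * (x - mu)` with windowed mean and
variance under replicate padding and the noise variance `v` estimated as
the mean local variance when not supplied; the median arm is a rank filter
(lower median for even windows, which are never the default). All three
arms share replicate padding so they differ only by algorithm.

## What the generator does and does not emulate

Emulated: the cold-rod geometry and partial-volume contrast loss, a
uniformity gap between two acquisition profiles, and reconstructed-image
Gaussian noise of the stated variance. Not emulated: Poisson counting
statistics and sinogram-domain reconstruction noise correlations, MR
k-space acceleration artefacts, attenuation-map segmentation errors with
anatomical structure, scatter and randoms, and scanner-specific resolution
anisotropy. Passing tests therefore demonstrate the *directional* behaviour
of the denoising arms under controlled Gaussian degradation — TV ahead of
Wiener/median ahead of no filtering, and the more uniform profile ahead of
the less uniform one — but say nothing quantitative about any physical
scanner; the original experiment's percentage differences depend on
undeposited scanner data and are out of reach by construction.

## Numerical choices and degenerate inputs

- TV seminorm at `epsilon = 0` is the exact objective; the solver requires
  `epsilon > 0`.
- Constant images are exact fixed points of all three filters and of the
  solver (both objective terms vanish at `f = I`).
- `lambda >= 1e4` pins the output to the input within 1e-2 in max norm.
- ROIs with fewer than two pixels, windows larger than the image, rod
  sectors whose geometry admits no rod, overlapping CNR ROIs and negative
  noise variances all raise `ConfigurationError` naming the offending
  element.
- End-to-end determinism: a saved resolved config plus seed reproduces the
  metrics CSV byte-for-byte.

## Problem sizes

The shipped study (2 profiles x 4 arms x 10 replicates at 256 x 256, TV at
200 iterations) completes in roughly two minutes on one CPU; unit tests use
a 64 x 64 phantom with three rod sectors and two replicates. The solver
oracle comparison runs on five 8 x 8 images where a quasi-Newton
minimizer over the 64 raw pixel values is cheap and independent.

## Known limitations

- The solver is first-order; run-to-convergence use cases (small `lambda`,
  large images) would want a dual/projection algorithm, which is out of
  scope here.
- The bias-field model is a single-scale Gaussian random field; real
  MR-AC non-uniformity has anatomy- and sequence-specific structure.
- CNR/COV are the only metrics; no hypothesis testing is performed between
  arms, matching the descriptive character of the comparisons it emulates.
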