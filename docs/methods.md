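# Methods

This note documents the models, numerical choices and limitations behind
`mitorestore`. It complements the README, which states the pipeline; here
we record *why* each piece is the way it is.

## Degradation model (HR → LR synthesis)

Training pairs are synthesized from high-resolution images. The forward
model is a Gaussian blur of sd `sigma_blur` (default 3.25 px),
approximating the microscope PSF, followed by mixed Poisson–Gaussian
noise: the blurred intensity is interpreted directly as the expected
photon count (gain 1), a Poisson variate is drawn per pixel, and
independent zero-mean Gaussian noise of sd `sigma_noise` (default 4.0
intensity units) is added, with no clipping. Under this model a flat
region of mean m has variance m + σ_noise², which is exactly the
assumption behind the Anscombe step of the sampler, so the two stages are
mutually consistent. Blur uses reflective boundaries to avoid dark halos
at frame edges inside training patches. When both parameters are zero the
operation is the identity (the Poisson draw is bypassed), giving a clean
degenerate case for tests.

Richardson–Lucy enhancement of the HR training targets uses a Gaussian
PSF of sd 1.5 px and 10 iterations by default. These values are exposed
in configuration: the enhancement is a contrast prior, not a calibrated
deconvolution, and the right setting depends on how oversampled the
acquisition is. The implementation delegates to the standard
multiplicative-update routine (scikit-image) with clipping disabled,
preserving non-negativity and total intensity up to boundary effects.

Inference-time width normalization resamples an image by
`target_width / measured_width` with cubic interpolation (nearest for
masks), where the target is the mean mitochondrial width of the training
distribution, 15.64 px (391 nm at 25 nm/px). The factor is returned so
restored images can be mapped back to the native grid.

## Phantom generator

The generator is the package's stand-in for real acquisitions: seeded,
exact, and statistically matched to the training-data geometry. Tube
centerlines are cubic splines through four uniformly drawn control points
(chord-length parametrized, control points drawn from a 15 % margin
beyond the frame so tubes enter and leave the field). Each tube gets a
width from N(15.64, 4.04²) truncated above the crista width, a crista
spacing from N(5, 1²) px, and a peak amplitude uniform in [56, 356]
intensity units over a background of 10. The tube is the set of pixels
within width/2 of the centerline (computed with a Euclidean distance
transform of the rasterized centerline at 2× supersampling); intensity is
a plateau at 45 % of the peak modulated by raised-cosine transverse
stripes of width 3.5 px keyed to the arclength of the nearest centerline
point. The cristae mask is the set of pixels whose ridge modulation is at
least half its maximum — a crisp, reproducible replacement for manual
annotation. Images are rendered at 2× and block-averaged; masks use a
majority vote, with containment (cristae ⊆ mitochondria) enforced after
downsampling.

What the phantom does **not** emulate: anisotropic/airy PSF structure,
depletion-beam physics, out-of-focus haze, intensity falloff along tubes,
branching networks, and motion. Passing tests on phantoms therefore
demonstrates the pipeline's internal consistency (the sampler finds the
structures, the loss prioritizes them, the network improves masked
fidelity on this degradation model), not performance on any particular
instrument's data.

The generator exposes per-tube ground truth (width, spacing, amplitude,
centerline with arclength), which the test suite uses for oracle
measurements: widths via the medial-axis distance transform of the
mitochondria mask at interior centerline points, spacings via
peak-to-peak intervals of noiseless centerline profiles (measured on
single-tube phantoms, since crossings contaminate longitudinal profiles).

## Sampler

The saliency chain runs on the **raw** LR frame, before percentile
normalization: the Anscombe transform's 3/8 offset presumes photon-count
statistics, and normalized intensities can fall below −3/8. Patches are
then cut from the normalized frames at the selected centers.

Numerical choices, each config-exposed:

- **Threshold floor.** The relaxation loop (start 30, step 5) stops at
  the last strictly positive threshold with a warning if the 10 % target
  is unattainable; this guarantees termination on pathological inputs.
- **Mask cleanup.** One pass of a 3×3 binary median — the smallest kernel
  that removes salt noise without eroding thin tubes. The 10 % criterion
  applies to the thresholded set the loop controls; the cleanup may trim
  isolated pixels afterwards.
- **Borders.** A patch center must be at least N/2 from every edge so the
  patch fits without padding.
- **Distance constraint.** Rejection sampling, uniform over the eligible
  mitochondria set, with a 1000-retry cap per center and a warning when
  the constraints admit fewer than N_I centers. Uniform sampling over
  mask pixels makes a region's selection probability proportional to its
  mitochondrial area.
- **Shrink augmentation.** Isotropic 0.75 downscale, reflect-padded back
  to size; applied (with both flips) to a seeded 25 % of the
  rotation-augmented set, identically to both members of a pair.
- **Split.** The 80/20 train/validation split is at patch level, seeded,
  with no patch in both sets. (An image-level split is the stricter
  alternative; at desk scale patch-level is what keeps the validation set
  non-trivial.)
- **Coordinates.** 0-based row/column indexing, pixel centers on integer
  coordinates, Euclidean center distance. Pseudo-residuals use forward
  differences, so the residual grid is (W−1)×(L−1).

## Loss and network

The SSIM map inside the loss uses an 11×11 Gaussian window (sd 1.5) with
the standard constants C1 = (0.01·R)², C2 = (0.03·R)² on the normalized
range R = 1. At patch borders the window is renormalized by its in-frame
mass (normalized convolution with zero padding). This choice is
deliberate: the windowing stays a linear operator with an exact adjoint,
so the loss gradient is analytic and verifiable against finite
differences (the suite demands ≤ 1e-4 relative agreement; measured
agreement is ~1e-9 in double precision). The γ map is precomputed from
the target-side mitochondria mask and never depends on predictions, so
loss weights are fixed during optimization.

The network and training loop are implemented directly in NumPy. The
residual U-Net (depth 3, two 3×3 convolutions + ReLU per block, 2×2
max-pool, nearest-neighbour 2×2 upsampling with skip concatenation, 1×1
head added to the input) evaluates convolutions channels-last as a sum
over kernel offsets of contiguous-slab matrix products; every layer
carries an explicit backward pass. The head is zero-initialized, so the
untrained model is the identity and training learns a correction field —
this also pins the "no-op" baseline for end-to-end tests. Optimization is
Adam with learning rate 1e-3 (default; the value is exposed and smaller
rates behave as expected, just more slowly at desk scale), batch 16,
early stopping on validation SCoP with patience 10, best-validation
weights returned. All randomness (init, shuffling) flows from explicit
seeds, making loss curves bit-reproducible.

At inference, frames of any size are percentile-normalized,
reflect-padded to a multiple of 2^depth, restored, and cropped; stacks
are processed plane by plane. A frame with degenerate percentiles (flat
frame) is passed through unrestored with a warning rather than aborting a
sequence.

## Metrics

Masked NRMSE divides the masked RMSE by the target's masked dynamic range
(mean normalization is available behind a flag, as both conventions are
in circulation). Masked PSNR uses the same masked range; a perfect match
returns an +inf sentinel that is excluded from aggregates with a warning.
Masked SSIM computes the local SSIM map over the full frame and then
averages inside the mask, so windows at mask borders keep their context;
with the all-ones mask all three metrics equal their unmasked versions
exactly. Aggregation is mean ± sd over images.

FWHM fitting is an unconstrained least-squares Gaussian
(amplitude·exp(−(x−c)²/2σ²) + baseline) on a profile sampled with
bilinear interpolation at 0.25 px steps; the result reports
2√(2 ln 2)·σ·pixel_size in nm. Flat profiles, non-positive fitted
amplitudes and non-convergence raise a typed error — unmeasurable
profiles are dropped, never reported. Note that bilinear sampling of a
pixel grid broadens a σ = 2 px peak by ~2 %; analytic profiles recover
the closed form to < 0.1 %. Peak detection for crista-to-crista intervals
uses a prominence of 10 % of the profile's dynamic range.

## Desk-scale study sizes

The end-to-end study used by the tests and the acceptance script runs on
24 phantom fields of 192×256 px (plus 6 held-out fields), degraded with
the default σ_blur/σ_noise, yielding ≈185 patches of 128×128 after
4× rotation augmentation and budget-limited ROI selection; the network is
depth 3 with 16 base filters, trained 10 epochs with batch 16. Target
enhancement is disabled in this study (the phantom ground truth carries
no instrument blur, so deconvolving it would push the regression target
away from the image restorations are scored against).

What the study shows, and what it cannot: validation SCoP decreases and
the restoration beats the degraded input on mitochondria-scope PSNR, so
the loop optimizes the intended objective and the restoration is real.
On the *cristae* scope, however, the SSIM objective and masked L2
genuinely diverge under these conditions, and restorations score below
the input on cristae PSNR no matter how long training runs. The mechanism
is worth recording. A Gaussian blur of sd 3.25 px attenuates the crista
ridge frequency (spacing ≈ 5 px) by exp(−2π²σ²f²) ≈ 2×10⁻⁴: ridge phase
is informationally destroyed in the input. Cristae-mask pixels are the
ridge tops — a narrow intensity band whose mean the blurred input already
matches — so the input is close to the L2-optimal predictor on that
scope. A structural-similarity loss, whose luminance term tolerates small
local-mean errors and whose structure term rewards variance-matched
texture, then has no incentive toward the L2 optimum: as it improves, it
synthesizes plausible but unverifiable texture and cristae-masked PSNR
drops. Real acquisitions differ in exactly the respect that matters:
cristae positions correlate with observable larger-scale structure, so a
full-scale model can place them informatively — the phantom's ridge phase
is arclength-periodic and independent of observable features by
construction (see the generator's limitations above). The test suite
keeps the cristae-scope assertion at its stated threshold, and it fails
on phantoms for this reason; the measured values are reported as-is by
the acceptance script.

## Known limitations

- The phantom's cristae-mask definition (ridge modulation ≥ 0.5 of max)
  is a modeling convention, not a reproduction of expert annotation.
- The Richardson–Lucy settings for target enhancement are priors, not
  calibrated values; they must be revisited per dataset.
- The NumPy network is CPU-bound and meant for desk-scale training and
  inference; large-scale training would port the identical architecture
  and loss to an accelerator framework.
- Metrics assume co-registered prediction/target pairs; no registration
  is performed.
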