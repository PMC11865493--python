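# mitorestore

Restoration of mitochondrial **cristae** — the 30–50 nm folds of the inner
mitochondrial membrane — from intermediate/low-resolution fluorescence
microscopy images. The package implements a complete, trainable
restoration pipeline for single-channel 2D images (or plane stacks):
paired-data synthesis, mitochondria-focused patch sampling, a residual
U-Net trained with a region-prioritizing structural-similarity loss, and
masked evaluation metrics with line-profile resolution measurements. A
seeded phantom generator makes every stage testable without any microscopy
data.

## The method

**Training pairs.** High-resolution (HR) images are degraded into
low-resolution (LR) network inputs with a Gaussian blur of sd
σ_blur = 3.25 px (a PSF surrogate) followed by mixed Poisson–Gaussian
noise (Poisson on the blurred intensity, plus additive Gaussian of sd
σ_noise = 4.0). HR training targets are sharpened with Richardson–Lucy
deconvolution. Both are harmonized with a percentile normalizer

    I_norm = (I − perc(I, 2)) / (perc(I, 99.8) − perc(I, 2)),

also applied at inference.

**Mitochondria-focused sampling.** Fluorescence fields are mostly dark
background, so 128×128 training patches are drawn around mitochondria:
the Anscombe transform `2·√(3/8 + I)` stabilizes the Poisson–Gaussian
noise to unit variance; robust noise statistics come from the median
(μ̂) and the MAD of pseudo-residuals
`r = (2I(i,j) − I(i+1,j) − I(i,j+1))/√6` (σ̂ = 1.4826·median|r|); the
Z-score map `(I_Ansc − μ̂)/σ̂` is thresholded starting at c = 30,
relaxing by 5 until the mask holds ≥ 10 % of pixels. Patch centers are
drawn from that mask, ≥ 60 px apart and clear of the borders, up to
N_I = ⌊W/128⌋·⌊L/128⌋ per frame; the set is augmented by 90°/180°/270°
rotations plus shrink/flip transforms on a random quarter.

**The SCoP loss.** Training minimizes the mean of per-pixel structural
dissimilarity raised to a region-dependent exponent:

    SCoP(y, ŷ) = (1/N²) Σ_ij ((1 − SSIM_map(i,j)) / 2)^γ_ij,

with γ = 1 on mitochondria pixels and γ = 4 on background. Since each
DSSIM term lies in [0, 1], the larger exponent strictly shrinks background
contributions, concentrating the optimization on mitochondria and their
cristae. The model is a depth-3 residual U-Net (two 3×3 conv + ReLU per
block, 2×2 max-pool, 2×2 upsampling with skip concatenation, final 1×1
conv added to the input).

**Evaluation.** NRMSE, PSNR and SSIM are reported over the full frame and
restricted to mitochondria / cristae masks (reference range taken over
masked target pixels). Cristae width is the FWHM (= 2√(2 ln 2)·σ) of a
Gaussian fitted to a transverse line profile, in nm; crista-to-crista
distances are consecutive peak-to-peak intervals along a longitudinal
profile. Images whose mitochondria differ in apparent width from the
training data (15.64 px ≈ 391 nm at 25 nm/px) are first rescaled
isotropically to that width.

## Worked example

```python
import numpy as np
from mitorestore import (
    PhantomConfig, generate_phantom, DegradationParams, degrade,
    LineProfile, fwhm_width, scop_from_ssim_map,
)

# a synthetic HR field of tubular mitochondria with cristae ridges
sample = generate_phantom(PhantomConfig(seed=7))
lr = degrade(sample.hr_image, DegradationParams(seed=7))  # blur + noise

# the loss worked example: SSIM map = 0 on 4 pixels, gamma = (1, 1, 4, 4)
print(scop_from_ssim_map(np.zeros((2, 2)), np.array([[1., 1.], [4., 4.]])))
# 0.28125    = (0.5 + 0.5 + 0.0625 + 0.0625) / 4

# FWHM of a sigma = 2 px Gaussian profile at 25 nm/px
x = np.arange(0, 40, 0.25)
v = 100 * np.exp(-((x - 20) ** 2) / 8) + 10
print(round(fwhm_width(LineProfile(x, v, pixel_size=25.0)).fwhm_nm, 2))
# 117.74     = 2 sqrt(2 ln 2) * 2 px * 25 nm/px
```

The end-to-end study (phantoms → degradation → sampling → training →
masked evaluation) is available as a single call:

```python
from mitorestore.pipeline import run_desk_study
result = run_desk_study(seed=1)          # ~7 min on one CPU
print(result.psnr_mito_gain_db)          # mitochondria-scope PSNR gain over the input, dB
```

## Command line

```bash
mitorestore phantom --n-images 6 --seed 1 --out-dir phantoms/
mitorestore degrade --sigma-blur 3.25 --sigma-noise 4.0 --seed 1 in.tif lr.tif
mitorestore rescale --factor 2.6 in.tif rescaled.tif
mitorestore run --config run.yaml --out-dir runs/demo     # composite pipeline
mitorestore predict --model runs/demo/model --in stack.tif --out restored.tif
mitorestore measure-width --image restored.tif --line 120,40,120,90 --pixel-size 25
```

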