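"""Synthesis of low-resolution inputs from high-resolution images.

Training pairs are built by degrading HR images with a Gaussian blur
(sigma_blur, approximating the microscope PSF) followed by mixed
Poisson-Gaussian noise (Poisson on the blurred intensity treated as expected
counts, gain 1, plus additive zero-mean Gaussian of sd sigma_noise).
Training targets are HR images sharpened with Richardson-Lucy deconvolution
to accentuate the cristae ridges.  At inference time, images whose
mitochondria differ in apparent width from the training data are first
resampled isotropically to the training width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import richardson_lucy as _sk_richardson_lucy

__all__ = [
    "DegradationParams",
    "TRAINING_MITO_WIDTH_PX",
    "gaussian_blur",
    "add_poisson_gaussian_noise",
    "degrade",
    "richardson_lucy_enhance",
    "rescale_to_width",
]

#: average mitochondrial width (px) in the training images; inference inputs
#: are rescaled so their mitochondria match this width.
TRAINING_MITO_WIDTH_PX = 15.64


@dataclass(frozen=True)
class DegradationParams:
    """HR -> LR synthesis parameters.

    sigma_blur is the sd (px) of the Gaussian PSF surrogate; sigma_noise the
    sd (intensity units) of the additive Gaussian component of the mixed
    Poisson-Gaussian noise.
    """

    sigma_blur: float = 3.25
    sigma_noise: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_blur < 0:
            raise ValueError("sigma_blur must be >= 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


def gaussian_blur(image: np.ndarray, sigma_blur: float) -> np.ndarray:
    """Convolve with a normalized isotropic Gaussian (reflective boundaries)."""
    if sigma_blur < 0:
        raise ValueError("sigma_blur must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma_blur == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma_blur, mode="reflect")


def add_poisson_gaussian_noise(
    image: np.ndarray, sigma_noise: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Per-pixel Poisson(mean = pixel) plus N(0, sigma_noise^2), unclipped."""
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ValueError("Poisson intensities must be non-negative")
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = rng.poisson(image).astype(np.float64)
    if sigma_noise > 0:
        noisy += rng.normal(0.0, sigma_noise, size=image.shape)
    return noisy


def degrade(image: np.ndarray, params: DegradationParams) -> np.ndarray:
    """Blur then corrupt with Poisson-Gaussian noise (this order is fixed)."""
    blurred = gaussian_blur(image, params.sigma_blur)
    if params.sigma_blur == 0 and params.sigma_noise == 0:
        # exact identity contract, bypassing the (deterministic but lossy
        # only in dtype) Poisson draw
        return blurred
    blurred = np.maximum(blurred, 0.0)  # guard tiny negative round-off
    return add_poisson_gaussian_noise(blurred, params.sigma_noise, params.seed)


def richardson_lucy_enhance(
    image: np.ndarray, psf_sigma: float = 1.5, n_iter: int = 10
) -> np.ndarray:
    """Richardson-Lucy deconvolution with a Gaussian PSF of sd ``psf_sigma``.

    Used to sharpen cristae ridges in HR training targets.  Multiplicative
    updates preserve non-negativity; ``psf_sigma = 0`` is the identity.
    """
    image = np.asarray(image, dtype=np.float64)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    total = image.sum()
    if total <= 0:
        raise ValueError("image must have positive total intensity")
    if psf_sigma == 0:
        return image.copy()
    radius = max(1, int(np.ceil(4 * psf_sigma)))
    x = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (x / psf_sigma) ** 2)
    psf = np.outer(g, g)
    psf /= psf.sum()
    # scale to [0,1]-ish range for the skimage implementation, then restore
    scale = image.max()
    out = _sk_richardson_lucy(image / scale, psf, num_iter=n_iter, clip=False)
    return np.maximum(out, 0.0) * scale


def rescale_to_width(
    image: np.ndarray,
    measured_width: float,
    target_width: float = TRAINING_MITO_WIDTH_PX,
    order: int = 3,
) -> tuple[np.ndarray, float]:
    """Resample so mitochondria of ``measured_width`` px reach ``target_width``.

    Returns the resampled image and the applied factor
    ``target_width / measured_width`` (kept for inverse mapping).  Use
    ``order=0`` for masks.
    """
    if measured_width <= 0 or target_width <= 0:
        raise ValueError("widths must be positive")
    factor = target_width / measured_width
    if factor == 1.0:
        return np.asarray(image, dtype=np.float64).copy(), 1.0
    out = ndimage.zoom(np.asarray(image, dtype=np.float64), factor, order=order, mode="reflect")
    return out, factor
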