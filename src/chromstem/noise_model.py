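"""Composite HAADF-STEM noise model for synthetic training images.

Noise-free images in [0, 1] are corrupted with the three dominant noise
sources of dark-field STEM acquisition, composed in this order:

1. signal-dependent shot noise — each pixel becomes
   ``Poisson(pixel * counts_scale) / counts_scale`` (electron counting);
2. additive Gaussian noise with mean equal to the image mean and
   sigma = 0.8 in detector-count units (thermal/electronic noise plus a
   signal-level-dependent background pedestal); on the normalized [0, 1]
   scale the layer therefore enters with weight 1 / counts_scale unless an
   explicit ``gaussian_amplitude`` overrides it;
3. scan-line shifts — each row is resampled at a random subpixel offset
   drawn from [-shift_max, shift_max) with linear interpolation
   (beam-positioning error perpendicular to the scan lines).

The composed result is clipped back to [0, 1].  All draws are functions of
the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NoiseConfig",
    "NoisyImagePair",
    "apply_poisson",
    "apply_gaussian",
    "apply_scan_shifts",
    "corrupt",
    "corrupt_sweep",
    "DEFAULT_COUNTS_RANGE",
]

#: count-scale sweep used when building training/benchmark datasets
DEFAULT_COUNTS_RANGE = (2.0, 20.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Parameters of the composite noise model.

    counts_scale
        Expected detector count at unit intensity; lower means stronger shot
        noise.  The benchmark sweep draws it log-uniformly from
        ``DEFAULT_COUNTS_RANGE``, spanning heavily corrupted (~15 dB PSNR)
        to mildly corrupted acquisitions.
    gaussian_sigma / gaussian_mu_mode / gaussian_amplitude
        Gaussian layer N(mu, sigma) with mu the image mean (or a fixed
        float) and sigma = 0.8 detector counts; ``gaussian_amplitude=None``
        (default) applies it in count units (weight 1 / counts_scale on the
        normalized scale), a float overrides that weight directly.
    shift_max
        Subpixel scan-shift bound (rows shifted by u ~ U[-shift_max, shift_max)).
    shift_mode
        "per_row" (independent shift per scan line, the standard scan-noise
        model) or "global" (one offset for the whole image).
    """

    counts_scale: float = 20.0
    gaussian_sigma: float = 0.8
    gaussian_mu_mode: str | float = "image_mean"
    gaussian_amplitude: float | None = None
    shift_max: float = 1.0
    shift_mode: str = "per_row"
    seed: int = 0

    @property
    def effective_gaussian_amplitude(self) -> float:
        """Weight of the Gaussian layer on the normalized-intensity scale.

        The layer's sigma = 0.8 is expressed in detector-count units; on an
        image normalized by ``counts_scale`` counts the field therefore
        enters with weight 1 / counts_scale unless an explicit amplitude
        overrides it.
        """
        if self.gaussian_amplitude is None:
            return 1.0 / self.counts_scale
        return self.gaussian_amplitude

    def __post_init__(self) -> None:
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be > 0")
        if self.gaussian_amplitude is not None and self.gaussian_amplitude < 0:
            raise ValueError("gaussian_amplitude must be >= 0")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")
        if self.shift_mode not in ("per_row", "global"):
            raise ValueError(f"unknown shift_mode {self.shift_mode!r}")


@dataclass
class NoisyImagePair:
    """A noise-free image and its corrupted counterpart, both in [0, 1]."""

    clean: np.ndarray
    noisy: np.ndarray

    def __post_init__(self) -> None:
        self.clean = np.asarray(self.clean, dtype=np.float64)
        self.noisy = np.asarray(self.noisy, dtype=np.float64)
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean/noisy shape mismatch")
        if not (np.all(np.isfinite(self.clean)) and np.all(np.isfinite(self.noisy))):
            raise ValueError("images must be finite")


def apply_poisson(image: np.ndarray, counts_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Shot noise: pixel -> Poisson(pixel * counts_scale) / counts_scale.

    Zero pixels stay exactly zero (Poisson(0) is 0 almost surely).
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be > 0")
    image = np.asarray(image, dtype=np.float64)
    return rng.poisson(image * counts_scale).astype(np.float64) / counts_scale


def apply_gaussian(image: np.ndarray, config: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian layer: image + amplitude * N(mu, sigma) per pixel.

    mu defaults to the image mean.  No clipping here; the composition step
    clips the final result.
    """
    image = np.asarray(image, dtype=np.float64)
    amp = config.effective_gaussian_amplitude
    if amp == 0:
        return image.copy()
    mu = float(image.mean()) if config.gaussian_mu_mode == "image_mean" else float(config.gaussian_mu_mode)
    noise = rng.normal(loc=mu, scale=config.gaussian_sigma, size=image.shape)
    return image + amp * noise


def apply_scan_shifts(
    image: np.ndarray,
    shift_max: float,
    rng: np.random.Generator,
    mode: str = "per_row",
) -> np.ndarray:
    """Resample each scan line at a random subpixel offset.

    Linear interpolation with clamp-to-edge boundary handling; output values
    on each row stay within that row's original [min, max].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("scan shifts operate on 2D images")
    n_rows, n_cols = image.shape
    if shift_max == 0:
        return image.copy()
    if mode == "per_row":
        u = rng.uniform(-shift_max, shift_max, size=n_rows)
    elif mode == "global":
        u = np.full(n_rows, rng.uniform(-shift_max, shift_max))
    else:
        raise ValueError(f"unknown shift mode {mode!r}")
    x = np.arange(n_cols, dtype=np.float64)
    out = np.empty_like(image)
    for r in range(n_rows):
        # sample the row at x + u[r]; np.interp clamps to the edge values
        out[r] = np.interp(x + u[r], x, image[r])
    return out


def corrupt(image: np.ndarray, config: NoiseConfig) -> NoisyImagePair:
    """Full composite corruption: Poisson -> Gaussian -> scan shifts -> clip."""
    image = np.asarray(image, dtype=np.float64)
    if image.size and (image.min() < 0 or image.max() > 1):
        raise ValueError("corrupt expects an image normalized to [0, 1]")
    rng = np.random.default_rng(config.seed)
    noisy = apply_poisson(image, config.counts_scale, rng)
    noisy = apply_gaussian(noisy, config, rng)
    noisy = apply_scan_shifts(noisy, config.shift_max, rng, mode=config.shift_mode)
    noisy = np.clip(noisy, 0.0, 1.0)
    return NoisyImagePair(clean=image.copy(), noisy=noisy)


def corrupt_sweep(
    images: list[np.ndarray],
    base: NoiseConfig | None = None,
    counts_range: tuple = DEFAULT_COUNTS_RANGE,
    seed: int = 0,
) -> list[NoisyImagePair]:
    """Corrupt a dataset with per-image count scales swept log-uniformly over
    ``counts_range``, emulating the acquisition-to-acquisition variability of
    shot-noise levels."""
    base = base or NoiseConfig()
    rng = np.random.default_rng(seed)
    lo, hi = np.log(counts_range[0]), np.log(counts_range[1])
    pairs = []
    for img in images:
        cs = float(np.exp(rng.uniform(lo, hi)))
        cfg = replace(base, counts_scale=cs, seed=int(rng.integers(2**31 - 1)))
        pairs.append(corrupt(img, cfg))
    return pairs
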