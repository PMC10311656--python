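"""Image-quality metrics (MSE, PSNR, SSIM), diagonal power-spectral-density
profiles, and the denoiser benchmark harness.

SSIM is computed from *global* image statistics (means, standard deviations
and cross-covariance over all pixels), the form used to score whole 28x28
patches; the conventional sliding-window variant is available through
``windowed=True``.

The PSD profile is the modulus of the 2D DFT sampled along the diagonal
k = l, ``P(k) = |F(k, k)|``, which equalizes row and column frequency
components for square images; high-k content measures fine-scale noise
energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "PSDProfile",
    "mse",
    "psnr",
    "ssim",
    "psd",
    "psd_stack",
    "benchmark",
    "nlm_denoiser",
    "bm3d_denoiser",
    "dae_denoiser",
]


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(image: np.ndarray, reference: np.ndarray) -> float:
    """Mean squared pixel difference."""
    a, b = _check_pair(image, reference)
    return float(np.mean((a - b) ** 2))


def psnr(image: np.ndarray, reference: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB.

    Identical images have zero MSE; the sentinel ``numpy.inf`` is returned.
    """
    if peak <= 0:
        raise ValueError("peak must be > 0")
    err = mse(image, reference)
    if err == 0.0:
        return float(np.inf)
    return float(10.0 * np.log10(peak**2 / err))


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    peak: float = 1.0,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    windowed: bool = False,
) -> float:
    """Structural similarity index in [-1, 1].

    Luminance, contrast, and structure terms are computed from whole-image
    statistics with stabilizers C1 = (k1*peak)^2, C2 = (k2*peak)^2,
    C3 = C2/2, and combined as l^alpha * c^beta * s^gamma.
    """
    x, y = _check_pair(x, y)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(x, y, data_range=peak, K1=k1, K2=k2))
    c1 = (k1 * peak) ** 2
    c2 = (k2 * peak) ** 2
    c3 = c2 / 2.0
    mu_x, mu_y = x.mean(), y.mean()
    sd_x, sd_y = x.std(), y.std()
    cov = np.mean((x - mu_x) * (y - mu_y))
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sd_x * sd_y + c2) / (sd_x**2 + sd_y**2 + c2)
    struct = (cov + c3) / (sd_x * sd_y + c3)
    if alpha == beta == gamma == 1.0:
        return float(lum * con * struct)
    # sign-preserving powers (the structure term can be negative)
    signed_pow = lambda v, e: float(np.sign(v) * np.abs(v) ** e)
    return signed_pow(lum, alpha) * signed_pow(con, beta) * signed_pow(struct, gamma)


@dataclass
class PSDProfile:
    """Diagonal power-spectral-density profile P(k) = |F(k, k)|."""

    wavenumbers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.wavenumbers) != len(self.values):
            raise ValueError("wavenumbers/values length mismatch")


def psd(image: np.ndarray) -> PSDProfile:
    """Diagonal PSD of a square image: modulus of the unnormalized 2D DFT
    evaluated at row frequency = column frequency."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("psd requires a square 2D image")
    f = np.fft.fft2(image)
    diag = np.abs(np.diagonal(f))
    return PSDProfile(wavenumbers=np.arange(image.shape[0]), values=diag)


def psd_stack(slices: list) -> PSDProfile:
    """Per-slice mean of the diagonal PSD over a stack of square images."""
    profiles = [psd(s) for s in slices]
    vals = np.mean([p.values for p in profiles], axis=0)
    return PSDProfile(wavenumbers=profiles[0].wavenumbers, values=vals)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-image metric table plus per-method mean/std aggregates."""

    per_image: pd.DataFrame  # columns: method, image, mse, ssim, psnr
    summary: pd.DataFrame  # index: method; columns: <metric>_mean, <metric>_std

    def method_means(self, method: str) -> dict:
        row = self.summary.loc[method]
        return {m: float(row[f"{m}_mean"]) for m in ("mse", "ssim", "psnr")}


def nlm_denoiser(**kwargs):
    """Non-local means baseline (scikit-image), noise sigma estimated per
    image, remaining parameters at library defaults."""
    from skimage.restoration import denoise_nl_means, estimate_sigma

    def run(noisy: np.ndarray) -> np.ndarray:
        sigma = float(estimate_sigma(noisy))
        return np.clip(denoise_nl_means(noisy, sigma=sigma, **kwargs), 0.0, 1.0)

    return run


def bm3d_denoiser(**kwargs):
    """Block-matching and 3D collaborative filtering baseline, noise sigma
    estimated per image."""
    from skimage.restoration import estimate_sigma

    from .bm3d import bm3d

    def run(noisy: np.ndarray) -> np.ndarray:
        sigma = max(float(estimate_sigma(noisy)), 1e-3)
        return bm3d(noisy, sigma, **kwargs)

    return run


def dae_denoiser(trained):
    """Wrap a trained autoencoder as a 2D-image denoiser callable."""
    from .dae_core import denoise_image

    def run(noisy: np.ndarray) -> np.ndarray:
        return denoise_image(trained, noisy)

    return run


def benchmark(pairs: list, denoisers: dict) -> MetricsReport:
    """Score each denoiser on (clean, noisy) pairs with MSE/SSIM/PSNR.

    ``denoisers`` maps method name to a callable taking the noisy 2D image
    and returning the denoised image.  A method whose callable raises is
    skipped with a warning, matching baseline-unavailable semantics.
    """
    rows = []
    for name, fn in denoisers.items():
        try:
            for i, pair in enumerate(pairs):
                out = fn(pair.noisy)
                rows.append(
                    {
                        "method": name,
                        "image": i,
                        "mse": mse(pair.clean, out),
                        "ssim": ssim(pair.clean, out),
                        "psnr": psnr(pair.clean, out),
                    }
                )
        except Exception as exc:  # pragma: no cover - defensive path
            warnings.warn(f"denoiser {name!r} failed and is skipped: {exc}")
            rows = [r for r in rows if r["method"] != name]
    per_image = pd.DataFrame(rows)
    agg = per_image.groupby("method")[["mse", "ssim", "psnr"]].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return MetricsReport(per_image=per_image, summary=agg)
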