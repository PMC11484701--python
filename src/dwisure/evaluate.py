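"""Self-supervised evaluation of denoising via the corrected residual.

If a denoiser removes exactly the noise, the residual (noisy input minus
denoised output), divided pixelwise by the noise map, is standard normal:
variance 1 and mean Gaussian log density of -(1 + log 2*pi)/2 ~ -1.4189.
Under-denoising drives the variance below 1 (too little removed);
removing image content makes the residual structured and non-Gaussian,
lowering the log-likelihood. These two statistics therefore grade a
denoiser without any clean reference.

Oracle metrics against the known clean image exist only for synthetic
phantoms and live in :func:`oracle_mse`; nothing else in this module may
touch ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ResidualReport", "corrected_residual", "residual_variance",
           "residual_gaussian_loglik", "oracle_mse", "evaluate_denoising"]

#: mean log density of a standard normal sample, -(1 + log(2 pi)) / 2
IDEAL_LOGLIK = -0.5 * (1.0 + np.log(2.0 * np.pi))


@dataclass
class ResidualReport:
    variance: float
    gaussian_loglik: float
    n_pixels: int
    mask_fraction: float

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def corrected_residual(noisy, denoised, noise_map,
                       mask_threshold: float = 0.05):
    """Noise-map-corrected residual ``(noisy - denoised) / sigma``.

    Pixels where ``sigma <= mask_threshold * max(sigma)`` are excluded
    (the division is ill-conditioned there). Returns ``(residual, mask)``
    with the residual zeroed outside the mask.
    """
    noisy = np.asarray(getattr(noisy, "values", noisy), dtype=np.float64)
    denoised = np.asarray(getattr(denoised, "values", denoised),
                          dtype=np.float64)
    sigma = np.asarray(getattr(noise_map, "sigma", noise_map),
                       dtype=np.float64)
    if not (noisy.shape == denoised.shape == sigma.shape):
        raise ValueError(
            f"shape mismatch: noisy {noisy.shape}, denoised {denoised.shape}, "
            f"sigma {sigma.shape}"
        )
    if not (0.0 <= mask_threshold < 1.0):
        raise ValueError("mask_threshold must lie in [0, 1)")
    mask = sigma > mask_threshold * sigma.max()
    if not mask.any():
        raise ValueError(
            "mask excludes every pixel; lower mask_threshold or check the "
            "noise map"
        )
    r = np.zeros_like(noisy)
    r[mask] = (noisy[mask] - denoised[mask]) / sigma[mask]
    return r, mask


def residual_variance(residual: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sample variance of the corrected residual over the mask (ideal: 1)."""
    r = residual[mask] if mask is not None else np.ravel(residual)
    if r.size < 2:
        raise ValueError("need at least 2 masked pixels")
    return float(np.var(r, ddof=1))


def residual_gaussian_loglik(residual: np.ndarray,
                             mask: np.ndarray | None = None) -> float:
    """Mean standard-normal log density of the corrected residual.

    ``mean(-r^2/2 - log(2 pi)/2)``; per-pixel so values are comparable
    across image sizes. Ideal value ~= -1.4189 for a standard-normal
    residual; 0-residual gives -log(2 pi)/2 ~= -0.9189.
    """
    r = residual[mask] if mask is not None else np.ravel(residual)
    if r.size < 1:
        raise ValueError("empty mask")
    return float(np.mean(-0.5 * r ** 2 - 0.5 * np.log(2.0 * np.pi)))


def oracle_mse(denoised, clean) -> float:
    """Per-pixel MSE against ground truth (synthetic phantoms only)."""
    denoised = np.asarray(getattr(denoised, "values", denoised),
                          dtype=np.float64)
    clean = np.asarray(clean, dtype=np.float64)
    if denoised.shape != clean.shape:
        raise ValueError(
            f"shape mismatch: {denoised.shape} vs {clean.shape}"
        )
    return float(np.mean((denoised - clean) ** 2))


def evaluate_denoising(noisy, denoised, noise_maps,
                       mask_threshold: float = 0.05) -> ResidualReport:
    """Pooled corrected-residual statistics over one or more images."""
    if isinstance(noisy, np.ndarray) and noisy.ndim == 2:
        noisy, denoised, noise_maps = [noisy], [denoised], [noise_maps]
    pooled = []
    n_total = 0
    n_masked = 0
    for yn, yd, sm in zip(noisy, denoised, noise_maps):
        r, mask = corrected_residual(yn, yd, sm, mask_threshold)
        pooled.append(r[mask])
        n_total += mask.size
        n_masked += int(mask.sum())
    r = np.concatenate(pooled)
    return ResidualReport(
        variance=float(np.var(r, ddof=1)) if r.size > 1 else 0.0,
        gaussian_loglik=float(np.mean(-0.5 * r ** 2 - 0.5 * np.log(2 * np.pi))),
        n_pixels=int(r.size),
        mask_fraction=n_masked / max(n_total, 1),
    )
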