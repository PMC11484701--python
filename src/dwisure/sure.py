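"""Stein's unbiased risk estimator (SURE) for spatially variant Gaussian noise.

For an observation ``y ~ N(x, Sigma)`` with unknown mean ``x`` (the clean
image) and diagonal covariance ``Sigma_dd = sigma_d^2`` given by a
per-pixel noise map, the expected mean squared error of a denoiser
``f(y)`` can be written without access to ``x``:

    E[ (1/D) ||f(y) - x||^2 ]
      = E[ (1/D) ( ||f(y) - y||^2 - sum_d sigma_d^2
                   + 2 div_y( sigma^2 ⊙ f(y) ) ) ]

where ``⊙`` is the element-wise product and the divergence term is
``sum_d sigma_d^2 * d f_d / d y_d``. The constant ``sum_d sigma_d^2`` does
not depend on the denoiser and can be dropped during optimization.

For a neural denoiser the divergence has no tractable closed form; it is
estimated with a Monte-Carlo probe ``b`` (zero-mean, unit-variance i.i.d.):

    div approx  b^T ( sigma^2 ⊙ (f(y + eps*b) - f(y)) / eps )

with a small step ``eps``, by default ``max(y) * 1e-3``. With a Rademacher
probe the estimate is exact for denoisers with diagonal Jacobians (e.g.
the identity), and unbiased in general.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SureConfig",
    "draw_probe",
    "epsilon_for",
    "mc_divergence",
    "analytic_divergence_linear",
    "sure_loss",
]


@dataclass
class SureConfig:
    #: "max_y_times_1e-3" or a fixed positive float
    epsilon_rule: str | float = "max_y_times_1e-3"
    #: "rademacher" or "gaussian"
    probe_distribution: str = "rademacher"
    #: include the additive sum(sigma^2) constant (for comparability with MSE)
    include_constant: bool = True
    probe_seed: int = 0
    #: probes averaged per divergence evaluation
    n_probes: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.epsilon_rule, (int, float)):
            if self.epsilon_rule <= 0:
                raise ValueError("fixed epsilon must be positive")
        elif self.epsilon_rule != "max_y_times_1e-3":
            raise ValueError(f"unknown epsilon rule: {self.epsilon_rule!r}")
        if self.probe_distribution not in ("rademacher", "gaussian"):
            raise ValueError(
                f"unknown probe distribution: {self.probe_distribution!r}"
            )
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")


def epsilon_for(y: np.ndarray, cfg: SureConfig) -> float:
    """Finite-difference step for the Monte-Carlo divergence."""
    if isinstance(cfg.epsilon_rule, (int, float)):
        return float(cfg.epsilon_rule)
    eps = float(np.max(y)) * 1e-3
    if eps <= 0:
        # degenerate non-positive input; fall back to an absolute step
        eps = 1e-6
    return eps


def draw_probe(shape, cfg: SureConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.probe_distribution == "rademacher":
        return rng.integers(0, 2, size=shape).astype(np.float64) * 2.0 - 1.0
    return rng.normal(0.0, 1.0, size=shape)


def mc_divergence(denoiser, y: np.ndarray, sigma2: np.ndarray,
                  cfg: SureConfig | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo estimate of ``div_y(sigma^2 ⊙ f(y))``.

    ``denoiser`` maps an image to an image of the same shape. A fresh
    probe is drawn per call (and per probe when ``cfg.n_probes > 1``) from
    ``rng``, or from a generator seeded with ``cfg.probe_seed``.
    """
    cfg = cfg or SureConfig()
    y = np.asarray(y, dtype=np.float64)
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if sigma2.shape != y.shape:
        raise ValueError(
            f"sigma2 shape {sigma2.shape} does not match y shape {y.shape}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.probe_seed)
    eps = epsilon_for(y, cfg)
    f0 = np.asarray(denoiser(y), dtype=np.float64)
    total = 0.0
    for _ in range(cfg.n_probes):
        b = draw_probe(y.shape, cfg, rng)
        f1 = np.asarray(denoiser(y + eps * b), dtype=np.float64)
        if not np.all(np.isfinite(f1)):
            raise FloatingPointError(
                "denoiser returned non-finite values on the perturbed input "
                f"(eps={eps:.3g}, sigma2 range=[{sigma2.min():.3g}, "
                f"{sigma2.max():.3g}])"
            )
        total += float(np.sum(b * sigma2 * (f1 - f0) / eps))
    return total / cfg.n_probes


def analytic_divergence_linear(A: np.ndarray, sigma2: np.ndarray) -> float:
    """Exact ``div_y(sigma^2 ⊙ A y) = sum_d sigma_d^2 A_dd`` (test oracle)."""
    A = np.asarray(A, dtype=np.float64)
    sigma2 = np.asarray(sigma2, dtype=np.float64).ravel()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"A must be square, got {A.shape}")
    if sigma2.size != A.shape[0]:
        raise ValueError("sigma2 length does not match A")
    return float(np.sum(sigma2 * np.diag(A)))


def sure_loss(denoiser, y, noise_map, cfg: SureConfig | None = None,
              rng: np.random.Generator | None = None) -> float:
    """Spatially-variant SURE estimate of the per-pixel MSE of ``denoiser``.

    ``y`` is one image or a sequence of images (e.g. the diffusion
    directions); the loss is averaged over them. ``noise_map`` supplies
    the per-pixel noise standard deviation (one map, or one per image).
    With ``cfg.include_constant`` the value estimates the true MSE; the
    constant can be dropped for optimization since it has no gradient.
    """
    cfg = cfg or SureConfig()
    images = [y] if isinstance(y, np.ndarray) else list(y)
    sigma = getattr(noise_map, "sigma", noise_map)
    maps = [sigma] * len(images) if isinstance(sigma, np.ndarray) else \
        [getattr(m, "sigma", m) for m in sigma]
    if rng is None:
        rng = np.random.default_rng(cfg.probe_seed)
    total = 0.0
    for img, sig in zip(images, maps):
        img = np.asarray(img, dtype=np.float64)
        sig = np.asarray(sig, dtype=np.float64)
        if sig.shape != img.shape:
            raise ValueError("noise map shape does not match image shape")
        d = img.size
        f = np.asarray(denoiser(img), dtype=np.float64)
        fidelity = float(np.sum((f - img) ** 2))
        div = mc_divergence(denoiser, img, sig ** 2, cfg, rng)
        value = fidelity + 2.0 * div
        if cfg.include_constant:
            value -= float(np.sum(sig ** 2))
        total += value / d
    return total / len(images)
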