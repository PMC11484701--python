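"""Phase correction, repetition averaging, noise-map estimation and trace images.

The preprocessing chain for repeated complex-valued DWI acquisitions:

1. estimate a low-frequency phase image per repetition with a uniform
   (boxcar) filter and remove it by complex rotation, so the signal of
   interest lies in the real channel and the imaginary channel is
   noise-only and can be discarded;
2. average the phase-corrected real repetitions arithmetically — unlike
   magnitude averaging this keeps the noise zero-mean Gaussian and avoids
   the Rician noise floor;
3. estimate a per-pixel noise map from the sample standard deviation
   across repetitions, scale it by 1/sqrt(N) to describe the averaged
   image, and smooth it with a Gaussian filter;
4. combine per-direction images into a trace image via the geometric mean.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NoiseMap",
    "DirectionImage",
    "InsufficientRepetitionsError",
    "lowfreq_phase",
    "phase_correct",
    "average_repetitions",
    "magnitude_average",
    "noise_map_from_repetitions",
    "accept_external_noise_map",
    "trace_image",
    "preprocess_stack",
    "PreprocessedBundle",
]

DEFAULT_PHASE_KERNEL = 15
DEFAULT_BLUR_SIGMA = 10.0


class InsufficientRepetitionsError(ValueError):
    """Too few repetitions to estimate a noise map.

    With a single repetition the per-pixel sample standard deviation is
    undefined; supply an externally derived noise map (e.g. propagated
    from a scanner noise calibration scan) via
    :func:`accept_external_noise_map` instead.
    """


@dataclass
class NoiseMap:
    """Per-pixel noise standard deviation, in the image's signal units."""

    sigma: np.ndarray
    provenance: str = "from_repetitions"

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if np.any(self.sigma < 0):
            raise ValueError("noise map contains negative values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.sigma.shape

    def scaled(self, factor: float) -> "NoiseMap":
        return NoiseMap(sigma=self.sigma * factor, provenance=self.provenance)


@dataclass
class DirectionImage:
    """Phase-corrected, averaged real image for one (b-value, direction)."""

    values: np.ndarray
    b_value: float
    direction_label: str = ""
    n_repetitions_used: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("direction image contains non-finite values")


def _check_kernel(kernel: int) -> None:
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")


def lowfreq_phase(image: np.ndarray, kernel: int = DEFAULT_PHASE_KERNEL) -> np.ndarray:
    """Low-frequency phase estimate of a complex image.

    Real and imaginary parts are each smoothed with a ``kernel x kernel``
    uniformly weighted (boxcar) filter with reflect boundary handling; the
    phase of the filtered complex image is returned. ``kernel=1`` returns
    the input's own phase.
    """
    _check_kernel(kernel)
    image = np.asarray(image)
    if kernel == 1:
        return np.angle(image)
    re = ndimage.uniform_filter(image.real.astype(np.float64), size=kernel,
                                mode="reflect")
    im = ndimage.uniform_filter(image.imag.astype(np.float64), size=kernel,
                                mode="reflect")
    return np.arctan2(im, re)


def phase_correct(image: np.ndarray,
                  kernel: int = DEFAULT_PHASE_KERNEL) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a complex image by its low-frequency phase estimate.

    Returns ``(real, imaginary)`` of ``image * exp(-i * phi_lowfreq)``.
    After correction the real channel carries the signal plus Gaussian
    noise with the original per-pixel standard deviation (rotation is
    unitary), while the imaginary channel is noise-only and is discarded
    by the rest of the pipeline.
    """
    phi = lowfreq_phase(image, kernel)
    rotated = np.asarray(image) * np.exp(-1j * phi)
    return rotated.real, rotated.imag


def average_repetitions(stack: np.ndarray, b_value: float = 0.0,
                        direction_label: str = "") -> DirectionImage:
    """Pixelwise arithmetic mean over an ``(N, H, W)`` stack of real images."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (N, H, W) stack")
    return DirectionImage(values=stack.mean(axis=0), b_value=b_value,
                          direction_label=direction_label,
                          n_repetitions_used=stack.shape[0])


def magnitude_average(stack: np.ndarray) -> np.ndarray:
    """Mean of per-repetition magnitudes.

    Carries the Rician noise floor: over pure-noise pixels the expected
    value is sigma * sqrt(pi/2) instead of zero, which is why the pipeline
    averages complex data after phase correction instead.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (N, H, W) stack")
    return np.abs(stack).mean(axis=0).astype(np.float64)


def noise_map_from_repetitions(stack: np.ndarray,
                               blur_sigma: float = DEFAULT_BLUR_SIGMA) -> NoiseMap:
    """Noise map of the repetition-averaged image, from the repetitions.

    The per-pixel sample standard deviation (ddof=1) across the N
    phase-corrected real repetitions estimates the single-repetition noise
    level; dividing by sqrt(N) converts it to the noise level of the
    N-average. A Gaussian blur (default sigma 10 pixels, reflect boundary)
    suppresses the large sampling variability of a std estimate from few
    repetitions, keeping only the smooth spatial noise profile.

    Set ``blur_sigma=0`` to skip the smoothing.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected an (N, H, W) stack")
    n = stack.shape[0]
    if n < 2:
        raise InsufficientRepetitionsError(
            f"need >= 2 repetitions to estimate a noise map (got {n}); "
            "supply an external noise map via accept_external_noise_map()"
        )
    sigma = stack.std(axis=0, ddof=1) / np.sqrt(n)
    if blur_sigma > 0:
        sigma = ndimage.gaussian_filter(sigma, sigma=blur_sigma, mode="reflect")
    return NoiseMap(sigma=np.maximum(sigma, 0.0), provenance="from_repetitions")


def accept_external_noise_map(source, scale: float = 1.0,
                              expected_shape: tuple[int, int] | None = None) -> NoiseMap:
    """Adopt an externally derived noise map (e.g. from a noise prescan).

    ``source`` is a NIfTI file path or an array. ``scale`` applies any
    factors needed to make the map describe the phase-corrected, averaged
    image this pipeline produces (for instance 1/sqrt(N) after averaging N
    repetitions).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if isinstance(source, (str, os.PathLike)):
        import nibabel as nib

        sigma = np.squeeze(np.asanyarray(nib.load(os.fspath(source)).dataobj))
    else:
        sigma = np.asarray(source)
    sigma = sigma.astype(np.float64) * scale
    if expected_shape is not None and sigma.shape != tuple(expected_shape):
        raise ValueError(
            f"noise map shape {sigma.shape} does not match image grid "
            f"{tuple(expected_shape)}"
        )
    if np.any(sigma < 0):
        raise ValueError("external noise map is negative after scaling")
    return NoiseMap(sigma=sigma, provenance="external")


def trace_image(direction_images) -> np.ndarray:
    """Geometric mean across diffusion directions.

    Accepts DirectionImages or arrays. Negative pixels (possible in
    phase-corrected averages at low SNR) are clipped to zero before the
    product so the root stays real.
    """
    arrays = [im.values if isinstance(im, DirectionImage) else np.asarray(im)
              for im in direction_images]
    if len(arrays) == 0:
        raise ValueError("need at least one direction image")
    stack = np.stack([np.maximum(a.astype(np.float64), 0.0) for a in arrays])
    return np.power(np.prod(stack, axis=0), 1.0 / len(arrays))


@dataclass
class PreprocessedBundle:
    """Per-direction averaged images and noise maps for one subject/slice."""

    images: dict[tuple[float, int], DirectionImage]
    noise_maps: dict[tuple[float, int], NoiseMap]
    b_values: tuple[float, ...]
    n_directions: int
    direction_labels: tuple[str, ...]

    def image(self, b: float, direction: int) -> DirectionImage:
        return self.images[(b, direction)]

    def noise_map(self, b: float, direction: int) -> NoiseMap:
        return self.noise_maps[(b, direction)]


def preprocess_stack(stack, kernel: int = DEFAULT_PHASE_KERNEL,
                     blur_sigma: float = DEFAULT_BLUR_SIGMA,
                     repetition_fraction: float = 1.0,
                     noise_map_b_values=None) -> PreprocessedBundle:
    """Run the full preprocessing chain on a RepetitionStack.

    For every (b-value, direction): phase-correct each repetition, average
    the first ``ceil(repetition_fraction * N)`` corrected real images, and
    (where at least two repetitions are used) derive the matching noise
    map. ``noise_map_b_values`` restricts noise-map computation (typically
    to the high b-value, whose many repetitions make the estimate
    reliable); ``None`` means every b-value with >= 2 repetitions used.
    """
    if not (0.0 < repetition_fraction <= 1.0):
        raise ValueError("repetition_fraction must lie in (0, 1]")
    images: dict[tuple[float, int], DirectionImage] = {}
    maps: dict[tuple[float, int], NoiseMap] = {}
    for b in stack.b_values:
        n_total = stack.n_repetitions(b)
        n_used = int(np.ceil(repetition_fraction * n_total))
        for d in range(stack.data[b].shape[0]):
            reps = stack.repetitions(b, d)[:n_used]
            corrected = np.stack([phase_correct(r, kernel)[0] for r in reps])
            images[(b, d)] = average_repetitions(
                corrected, b_value=b, direction_label=stack.direction_labels[d]
            )
            wanted = noise_map_b_values is None or b in noise_map_b_values
            if wanted and n_used >= 2:
                maps[(b, d)] = noise_map_from_repetitions(corrected, blur_sigma)
    return PreprocessedBundle(images=images, noise_maps=maps,
                              b_values=tuple(stack.b_values),
                              n_directions=stack.data[stack.b_values[0]].shape[0],
                              direction_labels=tuple(stack.direction_labels))
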