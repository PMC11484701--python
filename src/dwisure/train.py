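"""Self-supervised training strategies for DWI denoising.

Three ways to train a denoiser without clean targets, all operating on
phase-corrected, repetition-averaged direction images:

* **sure** — minimize the spatially-variant SURE loss using the
  repetition-derived noise map; needs no reference image at all.
* **noise2noise** — split the repetitions into two halves, average each,
  and regress one half-average onto the other with an MSE loss.
* **half2full** — regress the half-repetition average onto the
  full-repetition average with an MSE loss (at inference the full
  average is the input).

The public surface follows the statsmodels convention: build a
:class:`DenoisingModel` from data, call :meth:`~DenoisingModel.fit`, and
work with the returned :class:`DenoisingResults` (loss history, residual
diagnostics, ``summary()``, ``denoise()``). The module-level functions
``train_sure``/``train_noise2noise``/``train_half2full``/``denoise`` are
thin wrappers over the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import evaluate as _evaluate
from .models import DenoiserConfig, build_denoiser, count_parameters, make_optimizer
from .preprocess import (DEFAULT_BLUR_SIGMA, DEFAULT_PHASE_KERNEL, DirectionImage,
                         average_repetitions, noise_map_from_repetitions,
                         phase_correct, trace_image)
from .sure import SureConfig, draw_probe

__all__ = ["GuidedSample", "TrainConfig", "make_sure_dataset",
           "make_split_dataset", "DenoisingModel", "DenoisingResults",
           "train_sure", "train_noise2noise", "train_half2full", "denoise"]


@dataclass
class GuidedSample:
    """One training sample: high-b target, optional low-b guidance, noise map."""

    target: np.ndarray                    # (H, W), normalized
    guidance: np.ndarray | None           # (H, W) or None
    noise_map: np.ndarray | None          # (H, W) sigma, same normalization
    subject: int = 0
    direction: int = 0
    b_value: float = 0.0
    norm_scale: float = 1.0               # multiply model output by this
    reference: np.ndarray | None = None   # MSE reference (noise2noise/half2full)
    noise_map_provenance: str = "from_repetitions"

    def input_channels(self, use_guidance: bool = True) -> np.ndarray:
        chans = [self.target]
        if use_guidance and self.guidance is not None:
            chans.append(self.guidance)
        return np.stack(chans).astype(np.float32)


@dataclass
class TrainConfig:
    strategy: str = "sure"                # sure | noise2noise | half2full
    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10                    # early-stop patience (epochs)
    seed: int = 0
    repetition_fraction: float = 1.0
    guidance: str = "matched"             # matched | none
    val_fraction: float = 0.25
    sure: SureConfig = field(default_factory=SureConfig)

    def __post_init__(self) -> None:
        if self.strategy not in ("sure", "noise2noise", "half2full"):
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.repetition_fraction <= 1.0):
            raise ValueError("repetition_fraction must lie in (0, 1]")


def _normalize(target, guidance, sigma, reference=None):
    """Joint robust scaling of image and noise map.

    Dividing the image and its sigma-map by the same scalar leaves the
    SURE objective's meaning intact (both transform linearly). The scale
    is the 99th percentile of the guidance channel (higher SNR), falling
    back to the target.
    """
    basis = guidance if guidance is not None else target
    scale = float(np.percentile(np.abs(basis), 99.0))
    if scale <= 0:
        scale = 1.0
    div = lambda a: None if a is None else (a / scale)
    return div(target), div(guidance), div(sigma), div(reference), scale


def _matched_pairs(stack, target_b=None, guidance_b=None):
    bvals = sorted(stack.b_values)
    if target_b is None:
        target_b = bvals[-1]
    if guidance_b is None:
        guidance_b = bvals[0] if len(bvals) > 1 else None
    if guidance_b == target_b:
        guidance_b = None
    return target_b, guidance_b


def _corrected_reps(stack, b, direction, kernel):
    reps = stack.repetitions(b, direction)
    return np.stack([phase_correct(r, kernel)[0] for r in reps])


def make_sure_dataset(stacks, cfg: TrainConfig,
                      kernel: int = DEFAULT_PHASE_KERNEL,
                      blur_sigma: float = DEFAULT_BLUR_SIGMA,
                      target_b: float | None = None,
                      guidance_b: float | None = None) -> list[GuidedSample]:
    """Build SURE training samples from repetition stacks.

    One sample per (subject/slice, direction): the target is the high-b
    direction image averaged from ``ceil(repetition_fraction * N)``
    phase-corrected repetitions, the guidance the matched-direction low-b
    average (all repetitions), and the noise map is derived from the used
    repetitions — so it is automatically scaled for the actual count
    averaged (the sigma/sqrt(N) law).
    """
    samples: list[GuidedSample] = []
    for subject, stack in enumerate(stacks):
        tb, gb = _matched_pairs(stack, target_b, guidance_b)
        n_dir = stack.data[tb].shape[0]
        if gb is not None and stack.data[gb].shape[0] != n_dir:
            raise ValueError(
                f"subject {subject}: direction counts differ between "
                f"b={tb} and b={gb}"
            )
        for d in range(n_dir):
            reps = _corrected_reps(stack, tb, d, kernel)
            n_used = int(np.ceil(cfg.repetition_fraction * reps.shape[0]))
            if n_used < 2:
                raise ValueError(
                    "repetition_fraction leaves fewer than 2 repetitions; "
                    "a repetition-derived noise map needs at least 2"
                )
            used = reps[:n_used]
            target = used.mean(axis=0)
            nmap = noise_map_from_repetitions(used, blur_sigma)
            guidance = None
            if gb is not None and cfg.guidance == "matched":
                guidance = _corrected_reps(stack, gb, d, kernel).mean(axis=0)
            t, g, s, _, scale = _normalize(target, guidance, nmap.sigma)
            samples.append(GuidedSample(
                target=t, guidance=g, noise_map=s, subject=subject,
                direction=d, b_value=tb, norm_scale=scale,
                noise_map_provenance=nmap.provenance))
    return samples


def make_split_dataset(stacks, cfg: TrainConfig, mode: str,
                       kernel: int = DEFAULT_PHASE_KERNEL,
                       blur_sigma: float = DEFAULT_BLUR_SIGMA,
                       target_b: float | None = None,
                       guidance_b: float | None = None) -> list[GuidedSample]:
    """Samples for the reference-based strategies.

    ``mode="noise2noise"``: input = average of the even-index repetitions,
    reference = average of the odd-index repetitions. ``mode="half2full"``:
    input = average of the first half, reference = average of all
    repetitions. A noise map for the *input* average is attached for
    later residual evaluation (it plays no role in the MSE objective).
    """
    if mode not in ("noise2noise", "half2full"):
        raise ValueError(f"unknown split mode: {mode!r}")
    samples: list[GuidedSample] = []
    for subject, stack in enumerate(stacks):
        tb, gb = _matched_pairs(stack, target_b, guidance_b)
        n_dir = stack.data[tb].shape[0]
        for d in range(n_dir):
            reps = _corrected_reps(stack, tb, d, kernel)
            n = reps.shape[0]
            if n < 2:
                raise ValueError("cannot split a single repetition")
            if mode == "noise2noise":
                inp = reps[0::2].mean(axis=0)
                ref = reps[1::2].mean(axis=0)
            else:
                inp = reps[:n // 2].mean(axis=0)
                ref = reps.mean(axis=0)
            nmap = noise_map_from_repetitions(reps, blur_sigma)
            # describe the input average: rescale from 1/sqrt(n) to its count
            n_in = reps[0::2].shape[0] if mode == "noise2noise" else n // 2
            sigma_in = nmap.sigma * np.sqrt(n / n_in)
            guidance = None
            if gb is not None and cfg.guidance == "matched":
                guidance = _corrected_reps(stack, gb, d, kernel).mean(axis=0)
            t, g, s, r, scale = _normalize(inp, guidance, sigma_in, ref)
            samples.append(GuidedSample(
                target=t, guidance=g, noise_map=s, subject=subject,
                direction=d, b_value=tb, norm_scale=scale, reference=r))
    return samples


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack_batch(samples: Sequence[GuidedSample], idx, use_guidance: bool):
    X = np.stack([samples[i].input_channels(use_guidance) for i in idx])
    y = X[:, 0:1].copy()
    sig = [samples[i].noise_map for i in idx]
    sigma2 = None
    if all(s is not None for s in sig):
        sigma2 = np.stack(sig)[:, None].astype(np.float32) ** 2
    ref = None
    if all(samples[i].reference is not None for i in idx):
        ref = np.stack([samples[i].reference for i in idx])[:, None]
        ref = ref.astype(np.float32)
    return X.astype(np.float32), y, sigma2, ref


class DenoisingModel:
    """A denoiser to be fitted to guided samples with a chosen strategy.

    Parameters
    ----------
    samples
        ``GuidedSample`` list from :func:`make_sure_dataset` or
        :func:`make_split_dataset`.
    config
        Optimization settings; ``config.strategy`` picks the objective.
    denoiser_config
        Architecture; ``in_channels`` is inferred from the samples when
        left at odds with them.
    """

    def __init__(self, samples: Sequence[GuidedSample],
                 config: TrainConfig | None = None,
                 denoiser_config: DenoiserConfig | None = None):
        if len(samples) == 0:
            raise ValueError("no training samples")
        self.samples = list(samples)
        self.config = config or TrainConfig()
        use_guidance = self.config.guidance != "none"
        n_chan = self.samples[0].input_channels(use_guidance).shape[0]
        dcfg = denoiser_config or DenoiserConfig(depth=6, width=32)
        if dcfg.in_channels != n_chan:
            dcfg = replace(dcfg, in_channels=n_chan)
        self.denoiser_config = dcfg
        if self.config.strategy == "sure":
            missing = [i for i, s in enumerate(self.samples)
                       if s.noise_map is None]
            if missing:
                raise ValueError(
                    f"samples {missing[:5]} lack noise maps; the SURE "
                    "strategy requires one per sample"
                )

    @classmethod
    def from_stacks(cls, stacks, config: TrainConfig | None = None,
                    denoiser_config: DenoiserConfig | None = None,
                    **dataset_kwargs) -> "DenoisingModel":
        config = config or TrainConfig()
        if config.strategy == "sure":
            samples = make_sure_dataset(stacks, config, **dataset_kwargs)
        else:
            samples = make_split_dataset(stacks, config, config.strategy,
                                         **dataset_kwargs)
        return cls(samples, config, denoiser_config)

    # -- fitting ---------------------------------------------------------

    def fit(self, verbose: bool = False) -> "DenoisingResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_split, s_batch, s_probe, s_val = ss.spawn(5)
        net = build_denoiser(replace(
            self.denoiser_config,
            seed=int(s_init.generate_state(1)[0] % (2 ** 31))))
        opt = make_optimizer(net, cfg.learning_rate)
        rng_split = np.random.default_rng(s_split)
        rng_batch = np.random.default_rng(s_batch)
        rng_probe = np.random.default_rng(s_probe)
        val_seed = int(s_val.generate_state(1)[0] % (2 ** 31))

        n = len(self.samples)
        n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
        perm = rng_split.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = perm, perm

        use_guidance = cfg.guidance != "none"
        history = {"train": [], "val": []}
        best_val = np.inf
        best_params = None
        best_epoch = -1
        stale = 0
        for epoch in range(cfg.max_epochs):
            losses = []
            for bidx in _batches(len(train_idx), cfg.batch_size, rng_batch):
                idx = train_idx[bidx]
                X, y, sigma2, ref = _stack_batch(self.samples, idx, use_guidance)
                if cfg.strategy == "sure":
                    loss = self._sure_step(net, opt, X, y, sigma2, rng_probe)
                else:
                    loss = self._mse_step(net, opt, X, ref)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} "
                        f"(lr={cfg.learning_rate}, strategy={cfg.strategy})"
                    )
                losses.append(loss)
            val = self._validation_loss(net, val_idx, use_guidance, val_seed)
            history["train"].append(float(np.mean(losses)))
            history["val"].append(val)
            if verbose:
                print(f"epoch {epoch:3d}  train {history['train'][-1]:.5e}  "
                      f"val {val:.5e}")
            if val < best_val - 1e-12:
                best_val = val
                best_epoch = epoch
                best_params = [p.copy() for lay in net.layers()
                               for p, _ in lay.params()]
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
        if best_params is not None:
            i = 0
            for lay in net.layers():
                for p, _ in lay.params():
                    p[...] = best_params[i]
                    i += 1
        return DenoisingResults(
            network=net, model=self, history=history, best_epoch=best_epoch,
            train_indices=train_idx, val_indices=val_idx)

    def _sure_step(self, net, opt, X, y, sigma2, rng) -> float:
        cfg = self.config.sure
        B = X.shape[0]
        D = y[0, 0].size
        eps = float(np.max(y)) * 1e-3 if not isinstance(cfg.epsilon_rule, (int, float)) \
            else float(cfg.epsilon_rule)
        if eps <= 0:
            eps = 1e-6
        f1, c1 = net.forward(X)
        b = draw_probe(y.shape, cfg, rng).astype(np.float32)
        Xp = X.copy()
        Xp[:, 0:1] += eps * b
        f2, c2 = net.forward(Xp)
        scale = 1.0 / (B * D)
        div = float(np.sum(b * sigma2 * (f2 - f1), dtype=np.float64)) / eps
        fid = float(np.sum((f1 - y) ** 2, dtype=np.float64))
        loss = (fid + 2.0 * div) * scale
        g1 = (2.0 * (f1 - y) - 2.0 * sigma2 * b / eps) * scale
        g2 = (2.0 * sigma2 * b / eps) * scale
        opt.zero_grad()
        net.backward(g1.astype(np.float32), c1)
        net.backward(g2.astype(np.float32), c2)
        opt.step()
        return loss

    def _mse_step(self, net, opt, X, ref) -> float:
        if ref is None:
            raise ValueError("reference-based strategy without references")
        B = X.shape[0]
        D = ref[0, 0].size
        f, cache = net.forward(X)
        scale = 1.0 / (B * D)
        loss = float(np.sum((f - ref) ** 2, dtype=np.float64)) * scale
        g = 2.0 * (f - ref) * scale
        opt.zero_grad()
        net.backward(g.astype(np.float32), cache)
        opt.step()
        return loss

    def _validation_loss(self, net, val_idx, use_guidance, val_seed) -> float:
        """Validation objective (fixed probe seed so epochs are comparable).

        For SURE the constant term is included, making the value an
        estimate of the actual per-pixel MSE.
        """
        cfg = self.config
        rng = np.random.default_rng(val_seed)
        total = 0.0
        for i in range(0, len(val_idx), cfg.batch_size):
            idx = val_idx[i:i + cfg.batch_size]
            X, y, sigma2, ref = _stack_batch(self.samples, idx, use_guidance)
            B = X.shape[0]
            D = y[0, 0].size
            f1, _ = net.forward(X)
            if cfg.strategy == "sure":
                eps = max(float(np.max(y)) * 1e-3, 1e-6)
                b = draw_probe(y.shape, cfg.sure, rng).astype(np.float32)
                Xp = X.copy()
                Xp[:, 0:1] += eps * b
                f2, _ = net.forward(Xp)
                div = float(np.sum(b * sigma2 * (f2 - f1), dtype=np.float64)) / eps
                fid = float(np.sum((f1 - y) ** 2, dtype=np.float64))
                const = float(np.sum(sigma2, dtype=np.float64))
                total += (fid - const + 2.0 * div) / D
            else:
                total += float(np.sum((f1 - ref) ** 2, dtype=np.float64)) / D
        # each batch contributed the sum of per-image (1/D)-normalized losses
        return total / max(len(val_idx), 1)


@dataclass
class DenoisingResults:
    """Fitted denoiser with its training history and diagnostics."""

    network: object
    model: DenoisingModel
    history: dict
    best_epoch: int
    train_indices: np.ndarray
    val_indices: np.ndarray

    @property
    def n_epochs(self) -> int:
        return len(self.history["train"])

    def denoise(self, samples: Sequence[GuidedSample] | None = None
                ) -> list[DirectionImage]:
        """Denoised direction images (denormalized to input units)."""
        samples = self.model.samples if samples is None else list(samples)
        use_guidance = self.model.config.guidance != "none"
        out = []
        for s in samples:
            x = s.input_channels(use_guidance)
            den = self.network(x) * s.norm_scale
            out.append(DirectionImage(values=den, b_value=s.b_value,
                                      direction_label=str(s.direction),
                                      n_repetitions_used=1))
        return out

    def trace(self, samples: Sequence[GuidedSample] | None = None) -> dict:
        """Per-subject trace image of the denoised directions."""
        samples = self.model.samples if samples is None else list(samples)
        denoised = self.denoise(samples)
        by_subject: dict[int, list] = {}
        for s, d in zip(samples, denoised):
            by_subject.setdefault(s.subject, []).append(d)
        return {subj: trace_image(images) for subj, images in by_subject.items()}

    def residual_report(self, samples: Sequence[GuidedSample] | None = None):
        """Self-supervised evaluation of the fit on its own samples."""
        samples = self.model.samples if samples is None else list(samples)
        usable = [s for s in samples if s.noise_map is not None]
        if not usable:
            raise ValueError("no samples carry noise maps")
        denoised = self.denoise(usable)
        noisy = [s.target * s.norm_scale for s in usable]
        sigma = [s.noise_map * s.norm_scale for s in usable]
        return _evaluate.evaluate_denoising(noisy, [d.values for d in denoised],
                                            sigma)

    def summary(self) -> str:
        cfg = self.model.config
        dcfg = self.model.denoiser_config
        lines = [
            "          DWI Denoising Results",
            "=" * 46,
            f"strategy:            {cfg.strategy}",
            f"architecture:        {dcfg.family} "
            f"(depth={dcfg.depth}, width={dcfg.width}, "
            f"in_channels={dcfg.in_channels})",
            f"parameters:          {count_parameters(self.network)}",
            f"samples (train/val): {len(self.train_indices)}/"
            f"{len(self.val_indices)}",
            f"epochs run:          {self.n_epochs} (best: {self.best_epoch})",
            f"final train loss:    {self.history['train'][-1]:.5e}",
            f"best val loss:       {min(self.history['val']):.5e}",
        ]
        try:
            rep = self.residual_report()
            lines += [
                f"residual variance:   {rep.variance:.4f}  (ideal 1.0)",
                f"residual loglik:     {rep.gaussian_loglik:.4f}  "
                "(ideal -1.4189)",
            ]
        except ValueError:
            pass
        return "\n".join(lines)


# -- functional wrappers --------------------------------------------------

def train_sure(samples, denoiser_config: DenoiserConfig | None = None,
               config: TrainConfig | None = None, **fit_kwargs):
    cfg = replace(config or TrainConfig(), strategy="sure")
    return DenoisingModel(samples, cfg, denoiser_config).fit(**fit_kwargs)


def train_noise2noise(stacks, denoiser_config: DenoiserConfig | None = None,
                      config: TrainConfig | None = None, **dataset_kwargs):
    cfg = replace(config or TrainConfig(), strategy="noise2noise")
    return DenoisingModel.from_stacks(stacks, cfg, denoiser_config,
                                      **dataset_kwargs).fit()


def train_half2full(stacks, denoiser_config: DenoiserConfig | None = None,
                    config: TrainConfig | None = None, **dataset_kwargs):
    cfg = replace(config or TrainConfig(), strategy="half2full")
    return DenoisingModel.from_stacks(stacks, cfg, denoiser_config,
                                      **dataset_kwargs).fit()


def denoise(results_or_net, samples: Sequence[GuidedSample],
            use_guidance: bool = True):
    """Apply a fitted denoiser to samples; returns per-direction images
    and the per-subject trace images."""
    if isinstance(results_or_net, DenoisingResults):
        images = results_or_net.denoise(samples)
    else:
        net = results_or_net
        images = []
        for s in samples:
            den = net(s.input_channels(use_guidance)) * s.norm_scale
            images.append(DirectionImage(values=den, b_value=s.b_value,
                                         direction_label=str(s.direction),
                                         n_repetitions_used=1))
    by_subject: dict[int, list] = {}
    for s, d in zip(samples, images):
        by_subject.setdefault(s.subject, []).append(d)
    traces = {subj: trace_image(imgs) for subj, imgs in by_subject.items()}
    return images, traces
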