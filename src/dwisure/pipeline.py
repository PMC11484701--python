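"""End-to-end orchestration: simulate -> preprocess -> train -> denoise -> evaluate.

Configuration is a YAML file with nested sections mirroring the library
modules (``phantom``, ``preprocess``, ``sure``, ``model``, ``train``,
``evaluate``) plus a global ``seed`` and ``outdir``. Unknown keys are
rejected so typos fail loudly. Every stage draws its randomness from a
named substream of the global seed, every intermediate artifact is
persisted, and the resolved configuration is written next to the outputs,
so a rerun with the same seed reproduces the same report.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, replace

import numpy as np
import yaml

from . import io as dio
from .evaluate import evaluate_denoising, oracle_mse
from .models import DenoiserConfig, save_checkpoint
from .phantom import PhantomConfig, SigmaProfile, generate_phantom
from .preprocess import DEFAULT_BLUR_SIGMA, DEFAULT_PHASE_KERNEL
from .sure import SureConfig
from .train import DenoisingModel, TrainConfig, make_split_dataset, make_sure_dataset

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_SECTIONS = {
    "phantom": {"n_subjects", "grid_size", "b_values", "n_directions",
                "n_repetitions", "rep_phase_scale", "phase_order",
                "sigma_min", "sigma_max", "sigma_kind", "adc_range"},
    "preprocess": {"kernel", "blur_sigma"},
    "sure": {"epsilon_rule", "probe", "include_constant", "probe_seed"},
    "model": {"family", "depth", "width", "residual", "levels"},
    "train": {"strategy", "learning_rate", "batch_size", "max_epochs",
              "patience", "repetition_fraction", "guidance", "val_fraction"},
    "evaluate": {"mask_threshold"},
}

DEFAULTS = {
    "seed": 0,
    "outdir": "dwisure_run",
    "phantom": {"n_subjects": 6, "grid_size": [64, 64],
                "b_values": [50.0, 1000.0], "n_directions": 3,
                "n_repetitions": {50.0: 4, 1000.0: 12},
                "rep_phase_scale": 0.3, "phase_order": 2,
                "sigma_min": 0.02, "sigma_max": 0.06, "sigma_kind": "radial",
                "adc_range": [0.3e-3, 3.0e-3]},
    "preprocess": {"kernel": DEFAULT_PHASE_KERNEL,
                   "blur_sigma": DEFAULT_BLUR_SIGMA},
    "sure": {"epsilon_rule": "max_y_times_1e-3", "probe": "rademacher",
             "include_constant": False, "probe_seed": 0},
    "model": {"family": "dncnn", "depth": 6, "width": 32, "residual": True,
              "levels": 2},
    "train": {"strategy": "sure", "learning_rate": 3e-3, "batch_size": 4,
              "max_epochs": 40, "patience": 10, "repetition_fraction": 1.0,
              "guidance": "matched", "val_fraction": 0.25},
    "evaluate": {"mask_threshold": 0.05},
}


class RunConfig(dict):
    """Validated pipeline configuration (a nested dict with defaults)."""


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {path}{key}")
        if isinstance(defaults[key], dict) and key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"section {key} must be a mapping")
            unknown = set(value) - _SECTIONS[key]
            if unknown:
                raise ValueError(
                    f"unknown keys in section {key}: {sorted(unknown)}"
                )
            merged = dict(defaults[key])
            merged.update(value)
            out[key] = merged
        else:
            out[key] = value
    return out


def load_config(source=None) -> RunConfig:
    """Load and validate a YAML config file (or dict); None gives defaults."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    return RunConfig(_merge(DEFAULTS, user))


def _phantom_config(cfg: RunConfig, seed: int) -> PhantomConfig:
    p = cfg["phantom"]
    reps = p["n_repetitions"]
    if isinstance(reps, dict):
        reps = {float(k): int(v) for k, v in reps.items()}
    return PhantomConfig(
        grid_size=tuple(p["grid_size"]),
        b_values=tuple(float(b) for b in p["b_values"]),
        n_directions=int(p["n_directions"]),
        n_repetitions=reps,
        adc_range=tuple(p["adc_range"]),
        phase_order=int(p["phase_order"]),
        rep_phase_scale=float(p["rep_phase_scale"]),
        sigma_profile=SigmaProfile(kind=p["sigma_kind"],
                                   sigma_min=float(p["sigma_min"]),
                                   sigma_max=float(p["sigma_max"])),
        seed=seed,
    )


def _train_config(cfg: RunConfig, seed: int) -> TrainConfig:
    t = cfg["train"]
    s = cfg["sure"]
    return TrainConfig(
        strategy=t["strategy"], learning_rate=float(t["learning_rate"]),
        batch_size=int(t["batch_size"]), max_epochs=int(t["max_epochs"]),
        patience=int(t["patience"]),
        repetition_fraction=float(t["repetition_fraction"]),
        guidance=t["guidance"], val_fraction=float(t["val_fraction"]),
        seed=seed,
        sure=SureConfig(epsilon_rule=s["epsilon_rule"],
                        probe_distribution=s["probe"],
                        include_constant=bool(s["include_constant"]),
                        probe_seed=int(s["probe_seed"])),
    )


class _StageLog:
    def __init__(self, path):
        self.path = path

    def __call__(self, stage: str, seconds: float, **info) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage,
                                 "seconds": round(seconds, 3), **info}) + "\n")


def run_pipeline(config=None, outdir: str | None = None,
                 seed: int | None = None) -> str:
    """Run the full pipeline; returns the artifact directory.

    Stages: simulate (synthetic phantoms per subject), preprocess + dataset
    construction, training, denoising, and residual evaluation. The
    resolved config, every intermediate, a JSON-lines stage log and the
    final ``report.json`` are written under ``outdir``.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    if outdir is not None:
        cfg["outdir"] = outdir
    if seed is not None:
        cfg["seed"] = int(seed)
    out = cfg["outdir"]
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
    log = _StageLog(os.path.join(out, "pipeline_log.jsonl"))

    ss = np.random.SeedSequence(cfg["seed"])
    s_phantom, s_train = ss.spawn(2)
    subject_seeds = [int(s % (2 ** 31))
                     for s in s_phantom.generate_state(cfg["phantom"]["n_subjects"])]

    # -- simulate --------------------------------------------------------
    t0 = time.perf_counter()
    truths, stacks = [], []
    for i, sseed in enumerate(subject_seeds):
        try:
            truth, stack = generate_phantom(_phantom_config(cfg, sseed))
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed for subject {i}") from exc
        truths.append(truth)
        stacks.append(stack)
        dio.write_stack(os.path.join(out, f"phantom_subj{i:02d}.h5"),
                        stack, truth)
    log("simulate", time.perf_counter() - t0, subjects=len(stacks))

    # -- preprocess / dataset -------------------------------------------
    t0 = time.perf_counter()
    tcfg = _train_config(cfg, seed=int(s_train.generate_state(1)[0] % (2 ** 31)))
    pp = cfg["preprocess"]
    try:
        if tcfg.strategy == "sure":
            samples = make_sure_dataset(stacks, tcfg, kernel=int(pp["kernel"]),
                                        blur_sigma=float(pp["blur_sigma"]))
        else:
            samples = make_split_dataset(stacks, tcfg, tcfg.strategy,
                                         kernel=int(pp["kernel"]),
                                         blur_sigma=float(pp["blur_sigma"]))
    except Exception as exc:
        raise RuntimeError("stage 'preprocess' failed") from exc
    log("preprocess", time.perf_counter() - t0, samples=len(samples))

    # -- train -----------------------------------------------------------
    t0 = time.perf_counter()
    m = cfg["model"]
    dcfg = DenoiserConfig(family=m["family"], depth=int(m["depth"]),
                          width=int(m["width"]), residual=bool(m["residual"]),
                          levels=int(m["levels"]))
    model = DenoisingModel(samples, tcfg, dcfg)
    try:
        results = model.fit()
    except Exception as exc:
        raise RuntimeError("stage 'train' failed") from exc
    save_checkpoint(results.network, os.path.join(out, "denoiser"),
                    extra={"seed": cfg["seed"],
                           "strategy": tcfg.strategy})
    with open(os.path.join(out, "loss_history.jsonl"), "w") as fh:
        for ep, (tr, va) in enumerate(zip(results.history["train"],
                                          results.history["val"])):
            fh.write(json.dumps({"epoch": ep, "train": tr, "val": va}) + "\n")
    log("train", time.perf_counter() - t0, epochs=results.n_epochs)

    # -- denoise ---------------------------------------------------------
    t0 = time.perf_counter()
    denoised = results.denoise(samples)
    traces = results.trace(samples)
    for s, img in zip(samples, denoised):
        dio.write_map(os.path.join(
            out, f"denoised_subj{s.subject:02d}_dir{s.direction}.nii.gz"), img)
    for subj, tr in traces.items():
        dio.write_map(os.path.join(out, f"trace_subj{subj:02d}.nii.gz"), tr)
    log("denoise", time.perf_counter() - t0, images=len(denoised))

    # -- evaluate --------------------------------------------------------
    t0 = time.perf_counter()
    noisy = [s.target * s.norm_scale for s in samples]
    sigma = [s.noise_map * s.norm_scale for s in samples]
    report = evaluate_denoising(noisy, [d.values for d in denoised], sigma,
                                mask_threshold=float(
                                    cfg["evaluate"]["mask_threshold"]))
    tb = sorted(stacks[0].b_values)[-1]
    mse_noisy = float(np.mean([
        oracle_mse(s.target * s.norm_scale,
                   truths[s.subject].clean[tb][s.direction])
        for s in samples]))
    mse_denoised = float(np.mean([
        oracle_mse(img.values, truths[s.subject].clean[tb][s.direction])
        for s, img in zip(samples, denoised)]))
    payload = {
        "residual_variance": report.variance,
        "residual_gaussian_loglik": report.gaussian_loglik,
        "n_pixels": report.n_pixels,
        "mask_fraction": report.mask_fraction,
        "oracle_mse_noisy": mse_noisy,
        "oracle_mse_denoised": mse_denoised,
        "strategy": tcfg.strategy,
        "seed": cfg["seed"],
        "epochs": results.n_epochs,
    }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    log("evaluate", time.perf_counter() - t0, n_pixels=report.n_pixels)
    return out
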