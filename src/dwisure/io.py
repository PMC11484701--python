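"""HDF5 / NIfTI readers and writers for the pipeline's artifacts.

Multi-repetition complex stacks live in one HDF5 file::

    /dwi/b{val}/dir{k}/rep{j}   complex64 (H, W)
    /sigma_map                  float64  (H, W)       [optional ground truth]
    /truth/s0, /truth/adc, /truth/phase_bg, /truth/clean/b{val}

with file attributes ``b_values``, ``direction_labels`` and ``seed``.
(HDF5 stores complex64 as a compound real/imaginary pair, so the on-disk
representation is paired float32 components and round-trips exactly.)
Real-valued end products (direction images, noise maps, denoised images)
are written as single-slice float32 NIfTI volumes.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .phantom import PhantomTruth, RepetitionStack
from .preprocess import NoiseMap

__all__ = ["write_stack", "read_stack", "write_map", "read_map",
           "read_sigma_map", "FormatError"]


class FormatError(ValueError):
    """A file does not follow the expected layout."""


def _b_key(b: float) -> str:
    return f"b{int(b) if float(b).is_integer() else b}"


def write_stack(path, stack: RepetitionStack,
                truth: PhantomTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["b_values"] = np.asarray(stack.b_values, dtype=np.float64)
        f.attrs["direction_labels"] = list(stack.direction_labels)
        if stack.seed is not None:
            f.attrs["seed"] = int(stack.seed)
        for b in stack.b_values:
            arr = stack.data[b]
            for d in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    f.create_dataset(f"/dwi/{_b_key(b)}/dir{d}/rep{j}",
                                     data=arr[d, j].astype(np.complex64))
        if truth is not None:
            f.create_dataset("/sigma_map", data=truth.sigma_map)
            f.create_dataset("/truth/s0", data=truth.s0)
            f.create_dataset("/truth/adc", data=truth.adc)
            f.create_dataset("/truth/phase_bg", data=truth.phase_bg)
            for b in stack.b_values:
                f.create_dataset(f"/truth/clean/{_b_key(b)}",
                                 data=truth.clean[b])


def read_stack(path) -> tuple[RepetitionStack, PhantomTruth | None]:
    with h5py.File(path, "r") as f:
        if "dwi" not in f:
            raise FormatError(f"{path}: missing '/dwi' group")
        b_values = tuple(float(b) for b in f.attrs["b_values"])
        labels = tuple(str(x) for x in f.attrs["direction_labels"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        data: dict[float, np.ndarray] = {}
        for b in b_values:
            grp = f[f"dwi/{_b_key(b)}"]
            dirs = sorted(grp.keys(), key=lambda s: int(s[3:]))
            per_dir = []
            for dname in dirs:
                dgrp = grp[dname]
                reps = sorted(dgrp.keys(), key=lambda s: int(s[3:]))
                per_dir.append(np.stack([dgrp[r][()] for r in reps]))
            data[b] = np.stack(per_dir).astype(np.complex64)
        stack = RepetitionStack(data=data, b_values=b_values,
                                direction_labels=labels, seed=seed)
        truth = None
        if "truth" in f:
            truth = PhantomTruth(
                s0=f["truth/s0"][()],
                adc=f["truth/adc"][()],
                phase_bg=f["truth/phase_bg"][()],
                phase_rep={},
                sigma_map=f["sigma_map"][()] if "sigma_map" in f else None,
                clean={b: f[f"truth/clean/{_b_key(b)}"][()] for b in b_values},
            )
        return stack, truth


def read_sigma_map(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if "sigma_map" not in f:
            raise FormatError(f"{path}: missing '/sigma_map' dataset")
        return f["sigma_map"][()]


def write_map(path, image, affine: np.ndarray | None = None) -> None:
    """Write a 2-D real image as a single-slice float32 NIfTI volume."""
    import nibabel as nib

    arr = np.asarray(getattr(image, "values", getattr(image, "sigma", image)),
                     dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    vol = arr[:, :, None]
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)),
             os.fspath(path))


def read_map(path) -> np.ndarray:
    import nibabel as nib

    arr = np.squeeze(np.asanyarray(nib.load(os.fspath(path)).dataobj))
    return arr.astype(np.float32)
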