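"""Checkpoint persistence: weights as HDF5 plus a JSON hyperparameter manifest."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .networks import LSTMWeights, SkipGramWeights, SRNWeights

_ARCH_CLASSES = {"srn": SRNWeights, "lstm": LSTMWeights, "skipgram": SkipGramWeights}


def _arch_of(weights) -> str:
    for name, cls in _ARCH_CLASSES.items():
        if isinstance(weights, cls):
            return name
    raise TypeError(f"unknown weight container {type(weights)!r}")


def save_checkpoint(
    path: str | Path, weights, manifest: dict | None = None
) -> None:
    """Write weight arrays to ``path`` (.h5) and hyperparameters to a
    sibling ``.json`` manifest."""
    path = Path(path)
    arch = _arch_of(weights)
    with h5py.File(path, "w") as f:
        f.attrs["arch"] = arch
        for name, arr in weights.params().items():
            f.create_dataset(name, data=arr)
        if isinstance(weights, SkipGramWeights):
            f.attrs["window_size"] = weights.window_size
            f.attrs["n_epochs"] = weights.n_epochs
    manifest = dict(manifest or {})
    manifest.setdefault("arch", arch)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1, default=str))


def load_checkpoint(path: str | Path):
    """Read back (weights, manifest) written by `save_checkpoint`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        arch = f.attrs["arch"]
        arrays = {name: np.asarray(f[name]) for name in f}
        extra = {}
        if arch == "skipgram":
            extra = {
                "window_size": int(f.attrs["window_size"]),
                "n_epochs": int(f.attrs["n_epochs"]),
            }
    weights = _ARCH_CLASSES[arch](**arrays, **extra)
    manifest_path = path.with_suffix(".json")
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    return weights, manifest
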