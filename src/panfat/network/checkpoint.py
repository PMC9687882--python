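"""Model checkpointing: weights as .npz with a JSON config sidecar."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .unet import NetworkConfig, UNet, build_network


def save_model(model: UNet, path) -> Path:
    """Write weights (npz) plus ``<path>.json`` carrying the NetworkConfig."""
    path = Path(path)
    arrays = {}
    for i, conv in enumerate(model._conv_layers()):
        arrays[f"w{i}"] = conv.w
        arrays[f"b{i}"] = conv.b
    np.savez(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.config),
                                  indent=2, sort_keys=True))
    return path


def load_model(path) -> UNet:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    config = NetworkConfig(**json.loads(sidecar.read_text()))
    model = build_network(config)
    with np.load(path) as data:
        for i, conv in enumerate(model._conv_layers()):
            conv.w[...] = data[f"w{i}"]
            conv.b[...] = data[f"b{i}"]
    return model
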