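"""Sequential network container with save/load and shape probing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Layer

__all__ = ["Network"]


class Network:
    """An ordered stack of layers trained end to end.

    The container exposes flat ``params``/``grads`` lists for the optimiser,
    a ``layer_shapes`` probe used to assert architecture conformance, and
    ``save``/``load`` in ``.npz`` form with a JSON-compatible metadata dict.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple, meta: dict | None = None):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.meta = dict(meta or {})

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def layer_shapes(self) -> list[tuple]:
        """Per-layer output shapes for a single input of ``input_shape``."""
        shapes = []
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
            shapes.append(shape)
        return shapes

    # -- persistence ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_param{j}"] = p
            for name in ("running_mean", "running_var"):
                if hasattr(layer, name):
                    arrays[f"layer{i}_{name}"] = getattr(layer, name)
        return arrays

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = self.state_arrays()
        arrays["_meta"] = np.frombuffer(
            json.dumps(self.meta, sort_keys=True).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def load(self, path: str | Path) -> "Network":
        """Load parameters saved by :meth:`save` into this architecture."""
        with np.load(Path(path)) as data:
            for i, layer in enumerate(self.layers):
                for j, p in enumerate(layer.params):
                    p[...] = data[f"layer{i}_param{j}"]
                for name in ("running_mean", "running_var"):
                    if hasattr(layer, name):
                        getattr(layer, name)[...] = data[f"layer{i}_{name}"]
            if "_meta" in data:
                self.meta = json.loads(bytes(data["_meta"]).decode())
        return self
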