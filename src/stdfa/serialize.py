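"""Checkpoint and spike-table persistence.

A checkpoint is a single ``.npz`` container holding layer sizes, weight
matrices, neuron parameters, and the fixed feedback matrices (with their
power-of-2 decomposition when applicable), sufficient to reconstruct the
network bit-for-bit. Spike rasters round-trip through the sparse
``(neuron, time)`` table form of :mod:`stdfa.neuron`.
"""

from __future__ import annotations

import json

import numpy as np

from .learning import FeedbackMatrix
from .neuron import Network, NeuronParams

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, net: Network, extra: dict | None = None) -> None:
    """Write a network (weights, params, feedback) to one ``.npz`` file."""
    if not isinstance(net.params, NeuronParams):
        raise NotImplementedError("per-layer parameter checkpoints not supported")
    arrays: dict[str, np.ndarray] = {
        "layer_sizes": np.asarray(net.layer_sizes, dtype=np.int64),
    }
    for k, w in enumerate(net.weights):
        arrays[f"weights_{k}"] = w
    meta = {
        "params": {
            "tau_m": net.params.tau_m,
            "tau_s": net.params.tau_s,
            "threshold": net.params.threshold,
            "reset": net.params.reset,
        },
        "feedback_variants": [],
        "extra": extra or {},
    }
    for k, fb in enumerate(net.feedback or []):
        arrays[f"feedback_{k}_b"] = fb.b
        if fb.variant == "power-of-2-set":
            arrays[f"feedback_{k}_m"] = fb.shift_exponents
            arrays[f"feedback_{k}_signs"] = fb.signs
        meta["feedback_variants"].append(fb.variant)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Network, dict]:
    """Reconstruct a network from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        layer_sizes = tuple(int(s) for s in data["layer_sizes"])
        weights = [data[f"weights_{k}"] for k in range(len(layer_sizes) - 1)]
        feedback = []
        for k, variant in enumerate(meta["feedback_variants"]):
            b = data[f"feedback_{k}_b"]
            if variant == "power-of-2-set":
                feedback.append(
                    FeedbackMatrix(
                        b=b, variant=variant,
                        shift_exponents=data[f"feedback_{k}_m"],
                        signs=data[f"feedback_{k}_signs"],
                    )
                )
            else:
                feedback.append(FeedbackMatrix(b=b, variant=variant))
    params = NeuronParams(**meta["params"])
    net = Network(
        layer_sizes=layer_sizes, weights=weights, params=params, feedback=feedback
    )
    return net, meta.get("extra", {})
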