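"""File formats: JSON structure descriptors, NPZ weight archives,
pre-charge profiles, scale sets, and tidy metric tables.

A network on disk is a pair of files: a JSON *descriptor* listing the
layers (kind, shapes, stride, padding, bias flag) and an NPZ archive
with keys ``w{l}`` / ``b{l}`` for the l-th layer (1-based; weightless
layers have no keys).  Convolution arrays are channels-first,
row-major, 0-based, as stated in the descriptor.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conversion import ScaleSet
from .network_model import LayerSpec, NetworkSpec
from .spiking_sim import PCMPProfile, SimTrace

__all__ = [
    "save_network",
    "load_network",
    "save_inputs",
    "load_inputs",
    "save_pcmp",
    "load_pcmp",
    "save_scales",
    "load_scales",
    "save_trace_csv",
    "save_metrics_csv",
]

DESCRIPTOR_FORMAT = "snnlat-network"
FLOAT_FMT = "%.9g"


def save_network(net: NetworkSpec, descriptor_path, weights_path) -> None:
    doc = {
        "format": DESCRIPTOR_FORMAT,
        "version": 1,
        "layout": "channels-first, row-major, 0-based",
        "layers": [
            {
                "kind": layer.kind,
                "input_shape": list(layer.input_shape),
                "output_shape": list(layer.output_shape),
                "stride": layer.stride,
                "padding": layer.padding,
                "has_bias": layer.has_bias,
            }
            for layer in net.layers
        ],
    }
    Path(descriptor_path).write_text(json.dumps(doc, indent=2) + "\n")
    arrays: dict[str, np.ndarray] = {}
    for j, layer in enumerate(net.layers, start=1):
        if net.weights[j - 1] is not None:
            arrays[f"w{j}"] = net.weights[j - 1]
        if net.biases[j - 1] is not None:
            arrays[f"b{j}"] = net.biases[j - 1]
    np.savez(weights_path, **arrays)


def load_network(descriptor_path, weights_path) -> NetworkSpec:
    doc = json.loads(Path(descriptor_path).read_text())
    if doc.get("format") != DESCRIPTOR_FORMAT:
        raise ValueError(f"not a {DESCRIPTOR_FORMAT} descriptor: {descriptor_path}")
    layers = [
        LayerSpec(
            kind=entry["kind"],
            input_shape=tuple(entry["input_shape"]),
            output_shape=tuple(entry["output_shape"]),
            stride=entry.get("stride", 1),
            padding=entry.get("padding", 0),
            has_bias=entry.get("has_bias", True),
        )
        for entry in doc["layers"]
    ]
    with np.load(weights_path) as archive:
        weights = [archive[f"w{j}"] if f"w{j}" in archive else None for j in range(1, len(layers) + 1)]
        biases = [archive[f"b{j}"] if f"b{j}" in archive else None for j in range(1, len(layers) + 1)]
    return NetworkSpec(layers, weights, biases)


def save_inputs(inputs: np.ndarray, path) -> None:
    np.savez(path, inputs=np.asarray(inputs))


def load_inputs(path) -> np.ndarray:
    with np.load(path) as archive:
        return archive["inputs"]


def save_pcmp(profile: PCMPProfile, path) -> None:
    Path(path).write_text(json.dumps([float(v) for v in profile.values]) + "\n")


def load_pcmp(path) -> PCMPProfile:
    return PCMPProfile(np.asarray(json.loads(Path(path).read_text()), dtype=float))


def save_scales(scales: ScaleSet, path) -> None:
    Path(path).write_text(json.dumps([float(v) for v in scales.scales]) + "\n")


def load_scales(path) -> ScaleSet:
    return ScaleSet(np.asarray(json.loads(Path(path).read_text()), dtype=float))


def save_trace_csv(trace: SimTrace, path) -> None:
    """Spike raster as (stage, neuron, timestep) triples, one per spike."""
    rows = []
    for s in range(trace.n_stages):
        raster = trace.spikes[s].reshape(trace.timesteps, -1)
        ts, neurons = np.nonzero(raster)
        for t, i in zip(ts, neurons):
            rows.append((s, int(i), int(t) + 1))
    pd.DataFrame(rows, columns=["stage", "neuron", "timestep"]).to_csv(path, index=False)


def save_metrics_csv(records: list[dict], path) -> None:
    """Tidy metric table: (metric, layer, timestep, vpc, delay, value)."""
    df = pd.DataFrame(records, columns=["metric", "layer", "timestep", "vpc", "delay", "value"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
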