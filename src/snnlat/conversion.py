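"""Data-based weight normalization for ANN-to-SNN conversion.

Rate coding caps a neuron's firing rate at one spike per timestep, so a
converted network can only represent activations in [0, 1].  The
data-based rule rescales each layer by the maximum activation observed
on a calibration set: with per-stage scales lambda^l,

    w'^l = w^l * lambda^(l-1) / lambda^l,      b'^l = b^l / lambda^l,

which maps every activation to a'^l = a^l / lambda^l, i.e. at most 1 on
the calibration inputs while preserving the network function up to the
per-layer rescaling.  The input stage keeps lambda^0 = 1 because inputs
are already encoded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network_model import NetworkSpec, relu_forward

__all__ = ["ScaleSet", "compute_layer_scales", "normalize_weights"]


@dataclass
class ScaleSet:
    """One positive scale per spiking stage (stage 0 = input, scale 1)."""

    scales: np.ndarray

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("all scales must be positive")

    def __getitem__(self, stage: int) -> float:
        return float(self.scales[stage])

    def __len__(self) -> int:
        return len(self.scales)


def compute_layer_scales(
    net: NetworkSpec,
    normalization_inputs,
    percentile: float = 100.0,
    floor: float = 1.0,
) -> ScaleSet:
    """Maximum (or percentile) activation per stage over a calibration set.

    Parameters
    ----------
    percentile
        100 (default) takes the strict maximum; smaller values trade
        outlier robustness against occasional saturation.
    floor
        Scale assigned to a dead stage (all activations zero); a dead
        layer transmits nothing either way, so 1.0 leaves it untouched.

    Weightless stages (gap) inherit the scale of the preceding stage:
    they cannot absorb a rescaling of their own, and pooling already
    never increases the maximum.
    """
    inputs = list(normalization_inputs)
    if not inputs:
        raise ValueError("normalization input set is empty")
    per_stage = [[] for _ in range(net.n_stages)]
    for x in inputs:
        rec = relu_forward(net, x)
        for s in range(net.n_stages):
            per_stage[s].append(rec[s].reshape(-1))
    scales = np.ones(net.n_stages)
    for s in range(1, net.n_stages):
        if net.layers[s - 1].kind == "gap":
            scales[s] = scales[s - 1]
            continue
        pooled = np.concatenate(per_stage[s])
        lam = float(np.max(pooled)) if percentile >= 100.0 else float(np.percentile(pooled, percentile))
        if lam <= 0.0:
            warnings.warn(f"stage {s} has no positive activation; scale floored to {floor}")
            lam = floor
        scales[s] = lam
    return ScaleSet(scales)


def normalize_weights(net: NetworkSpec, scales: ScaleSet) -> NetworkSpec:
    """Rescale weights/biases so calibration activations fit in [0, 1]."""
    if len(scales) != net.n_stages:
        raise ValueError(f"need {net.n_stages} scales, got {len(scales)}")
    new_w: list[np.ndarray | None] = []
    new_b: list[np.ndarray | None] = []
    for j, layer in enumerate(net.layers):
        lam_in, lam_out = scales[j], scales[j + 1]
        if net.weights[j] is None:
            new_w.append(None)
            new_b.append(None)
            continue
        new_w.append(net.weights[j] * (lam_in / lam_out))
        b = net.biases[j]
        new_b.append(None if b is None else b / lam_out)
    return NetworkSpec(list(net.layers), new_w, new_b)
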