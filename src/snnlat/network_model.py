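"""ReLU feedforward network container and evaluation.

The analog (conventional) network is both the conversion source for the
spiking simulator and the ground-truth reference for every error metric:
under rate coding the firing rate of an integrate-and-fire neuron
approximates the ReLU activation of its analog counterpart, so all
latency and error diagnostics compare spike rates against the
activations computed here.

A network is an ordered list of layers, each a linear map with optional
bias: a dense (fully connected) layer, a strided 2-D convolution, or a
global average pool (which carries no weights).  Convolution arrays are
channels-first, row-major, 0-based; padding is "valid" (none) unless a
symmetric zero padding is declared on the layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ActivationRecord",
    "NetworkError",
    "linear_map_apply",
    "relu_forward",
    "validate_network",
]

LAYER_KINDS = ("dense", "conv2d", "gap")


class NetworkError(ValueError):
    """Structural or numerical problem in a network, naming the layer."""

    def __init__(self, layer: int | None, message: str):
        self.layer = layer
        prefix = f"layer {layer}: " if layer is not None else ""
        super().__init__(prefix + message)


def _as_shape(shape) -> tuple[int, ...]:
    t = tuple(int(s) for s in np.atleast_1d(np.asarray(shape, dtype=int)))
    if any(s < 1 for s in t):
        raise ValueError(f"shape entries must be >= 1, got {t}")
    return t


@dataclass(frozen=True)
class LayerSpec:
    """Descriptor of one layer: its kind, shapes, stride and padding.

    ``input_shape``/``output_shape`` are the shapes of the activation
    arrays flowing in and out.  Dense layers flatten their input; conv2d
    shapes are ``(channels, height, width)``; gap maps ``(C, H, W)`` to
    ``(C,)``.
    """

    kind: str
    input_shape: tuple[int, ...]
    output_shape: tuple[int, ...]
    stride: int = 1
    padding: int = 0
    has_bias: bool = True

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        object.__setattr__(self, "input_shape", _as_shape(self.input_shape))
        object.__setattr__(self, "output_shape", _as_shape(self.output_shape))
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")

    @property
    def n_in(self) -> int:
        return int(np.prod(self.input_shape))

    @property
    def n_out(self) -> int:
        return int(np.prod(self.output_shape))


@dataclass
class NetworkSpec:
    """Ordered layers plus their weight/bias arrays.

    ``weights[j]`` / ``biases[j]`` belong to ``layers[j]``; both are
    ``None`` for weightless layers (gap).  Layer ``j`` consumes the
    output of layer ``j - 1``; the input of layer 0 is the network
    input.  In spiking terms the network has ``n_layers + 1`` spiking
    *stages*: stage 0 is the input layer (driven by constant current),
    stage ``j + 1`` is fed through layer ``j``.
    """

    layers: list[LayerSpec]
    weights: list[np.ndarray | None]
    biases: list[np.ndarray | None]

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ValueError("a network needs at least one layer")
        if not (len(self.layers) == len(self.weights) == len(self.biases)):
            raise ValueError("layers, weights and biases must have equal length")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_stages(self) -> int:
        """Number of spiking stages (input stage + one per layer)."""
        return len(self.layers) + 1

    def stage_shape(self, stage: int) -> tuple[int, ...]:
        if stage == 0:
            return self.layers[0].input_shape
        return self.layers[stage - 1].output_shape

    def stage_size(self, stage: int) -> int:
        return int(np.prod(self.stage_shape(stage)))


@dataclass
class ActivationRecord:
    """Per-layer ReLU activations for one input; index 0 is the input."""

    activations: list[np.ndarray]

    def __getitem__(self, stage: int) -> np.ndarray:
        return self.activations[stage]

    def __len__(self) -> int:
        return len(self.activations)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.activations)


def _conv2d(weight: np.ndarray, v: np.ndarray, stride: int, padding: int) -> np.ndarray:
    out_c, in_c, kh, kw = weight.shape
    if padding:
        v = np.pad(v, ((0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(v, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (in_c, H', W', kh, kw)
    return np.einsum("oikl,ihwkl->ohw", weight, win)


def linear_map_apply(
    layer: LayerSpec,
    weight: np.ndarray | None,
    bias: np.ndarray | None,
    v: np.ndarray,
    include_bias: bool = True,
    bias_scale: float = 1.0,
) -> np.ndarray:
    """Apply the layer's affine map ``W v (+ bias_scale * b)`` without ReLU.

    Shared by the analog forward pass and the spiking simulator (where
    ``v`` is a spike indicator vector and the bias contributes a
    constant current every timestep).
    """
    v = np.asarray(v, dtype=float)
    if v.shape != layer.input_shape and (v.size,) != (layer.n_in,):
        raise NetworkError(None, f"input shape {v.shape} does not match layer input {layer.input_shape}")
    if layer.kind == "dense":
        out = weight @ v.reshape(-1)
    elif layer.kind == "conv2d":
        out = _conv2d(weight, v.reshape(layer.input_shape), layer.stride, layer.padding)
    elif layer.kind == "gap":
        out = v.reshape(layer.input_shape).mean(axis=(1, 2))
    else:  # pragma: no cover - guarded by LayerSpec
        raise NetworkError(None, f"unknown kind {layer.kind}")
    if include_bias and layer.has_bias and bias is not None:
        if layer.kind == "conv2d":
            out = out + bias_scale * bias.reshape(-1, 1, 1)
        else:
            out = out + bias_scale * bias
    return out


def relu_forward(net: NetworkSpec, x: np.ndarray) -> ActivationRecord:
    """Evaluate the ReLU network; the record includes the input as stage 0."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NetworkError(0, "input contains non-finite values")
    shape0 = net.layers[0].input_shape
    if x.shape != shape0 and (x.size,) != (int(np.prod(shape0)),):
        raise NetworkError(0, f"input shape {x.shape} does not match {shape0}")
    acts = [x.reshape(shape0).astype(float)]
    for j, layer in enumerate(net.layers):
        pre = linear_map_apply(layer, net.weights[j], net.biases[j], acts[-1])
        if layer.kind == "gap":
            acts.append(pre)  # inputs are nonnegative; pooling preserves that
        else:
            acts.append(np.maximum(pre, 0.0))
    return ActivationRecord(acts)


def _expected_conv_out(layer: LayerSpec, weight: np.ndarray) -> tuple[int, ...]:
    out_c, in_c, kh, kw = weight.shape
    _, h, w = layer.input_shape
    oh = (h + 2 * layer.padding - kh) // layer.stride + 1
    ow = (w + 2 * layer.padding - kw) // layer.stride + 1
    return (out_c, oh, ow)


def validate_network(net: NetworkSpec) -> list[str]:
    """Return one finding per violated invariant; empty list if valid."""
    findings: list[str] = []
    for j, layer in enumerate(net.layers):
        w, b = net.weights[j], net.biases[j]
        if j > 0:
            prev = net.layers[j - 1].output_shape
            if layer.kind == "dense":
                if int(np.prod(prev)) != layer.n_in:
                    findings.append(f"layer {j}: input size {layer.n_in} != previous output {prev}")
            elif prev != layer.input_shape:
                findings.append(f"layer {j}: input shape {layer.input_shape} != previous output {prev}")
        if layer.kind == "gap":
            if w is not None or b is not None:
                findings.append(f"layer {j}: gap layer must carry no weights or bias")
            if len(layer.input_shape) != 3:
                findings.append(f"layer {j}: gap expects (C, H, W) input, got {layer.input_shape}")
            elif layer.output_shape != (layer.input_shape[0],):
                findings.append(f"layer {j}: gap output {layer.output_shape} != ({layer.input_shape[0]},)")
            continue
        if w is None:
            findings.append(f"layer {j}: missing weight array")
            continue
        if layer.kind == "dense":
            if w.shape != (layer.n_out, layer.n_in):
                findings.append(
                    f"layer {j}: dense weight shape {w.shape} != declared ({layer.n_out}, {layer.n_in})"
                )
        elif layer.kind == "conv2d":
            if w.ndim != 4 or len(layer.input_shape) != 3:
                findings.append(f"layer {j}: conv2d needs 4-D weights and (C, H, W) shapes")
            elif w.shape[1] != layer.input_shape[0]:
                findings.append(f"layer {j}: kernel in-channels {w.shape[1]} != input channels {layer.input_shape[0]}")
            else:
                expect = _expected_conv_out(layer, w)
                if expect != layer.output_shape:
                    findings.append(f"layer {j}: conv2d output {layer.output_shape} != computed {expect}")
        if not np.all(np.isfinite(w)):
            findings.append(f"layer {j}: weight contains non-finite values")
        if layer.has_bias:
            if b is None:
                findings.append(f"layer {j}: has_bias set but bias missing")
            else:
                nb = w.shape[0] if layer.kind in ("dense", "conv2d") else layer.n_out
                if b.size != nb:
                    findings.append(f"layer {j}: bias size {b.size} != {nb}")
                if not np.all(np.isfinite(b)):
                    findings.append(f"layer {j}: bias contains non-finite values")
        elif b is not None:
            findings.append(f"layer {j}: bias supplied but has_bias is False")
    return findings
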