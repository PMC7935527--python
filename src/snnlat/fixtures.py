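"""Synthetic networks, inputs, and independent dynamics oracles.

Everything here exists so that every property of the simulator and the
latency methods is testable without external data: small random dense
networks with controllable sign structure, plus two oracles written
independently of the production simulator — a closed-form spike-count
formula for a single neuron under constant drive, and a deliberately
naive scalar-loop re-implementation of the full network dynamics.

Two reproducibility aids matter for exact comparisons.  Inputs are
quantized to a dyadic grid (multiples of 1/256, emulating 8-bit input
precision), and a *dyadic* fixture mode additionally quantizes weights
to multiples of 1/64 and skips normalization: with every quantity an
exact binary fraction, floating-point accumulation in any summation
order is exact, so the production simulator, the naive reference, and
the closed form can be required to agree bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import floor

import numpy as np

from .conversion import compute_layer_scales, normalize_weights
from .network_model import LayerSpec, NetworkSpec, relu_forward
from .spiking_sim import SimConfig, SimTrace, resolve_pcmp

__all__ = [
    "FixtureSpec",
    "OracleResult",
    "make_fixture",
    "if_oracle",
    "brute_force_reference",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible random dense network plus input set.

    ``drive="positive"`` guarantees strictly positive pre-activations
    everywhere (nonnegative weights, positive inputs, nonnegative
    biases) — the regime in which the error decomposition is exact.
    ``dyadic=True`` quantizes weights to 1/64 and disables
    normalization for bit-exact oracle comparisons.  ``output_margin``
    keeps only inputs whose top two analog outputs are separated by at
    least that much (decisive classification samples).
    """

    layer_sizes: tuple[int, ...]
    n_inputs: int = 8
    weight_mode: str = "positive"  # "positive" | "mixed"
    bias_mode: str = "zero"  # "zero" | "positive"
    drive: str = "positive"  # "positive" | "any"
    input_range: tuple[float, float] = (0.1, 0.9)
    quantize_inputs: int = 256  # dyadic denominator; 0 disables
    output_margin: float = 0.0
    normalize: bool = True
    dyadic: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be >= 1")
        if self.weight_mode not in ("positive", "mixed"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.bias_mode not in ("zero", "positive"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        if self.drive == "positive" and self.weight_mode == "mixed":
            raise ValueError("positive drive cannot be guaranteed with mixed-sign weights")
        lo, hi = self.input_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("input_range must satisfy 0 <= lo < hi <= 1")
        if self.drive == "positive" and lo <= 0:
            raise ValueError("positive drive needs strictly positive inputs")


def _draw_inputs(rng: np.random.Generator, spec: FixtureSpec, n: int) -> np.ndarray:
    lo, hi = spec.input_range
    x = rng.uniform(lo, hi, size=(n, spec.layer_sizes[0]))
    if spec.quantize_inputs:
        q = spec.quantize_inputs
        x = np.round(x * q) / q
        x = np.clip(x, 1.0 / q if spec.drive == "positive" else 0.0, 1.0)
    return x


def make_fixture(spec: FixtureSpec) -> tuple[NetworkSpec, np.ndarray]:
    """Build the network and input set described by ``spec``.

    The network is emitted already normalized (unless disabled), so
    its activations on the returned inputs are at most 1 in every
    layer; positive-drive mode is re-verified on the result.
    """
    rng = np.random.default_rng(spec.seed)
    layers: list[LayerSpec] = []
    weights: list[np.ndarray | None] = []
    biases: list[np.ndarray | None] = []
    sizes = spec.layer_sizes
    for j in range(len(sizes) - 1):
        n_in, n_out = sizes[j], sizes[j + 1]
        if spec.weight_mode == "positive":
            w = rng.uniform(0.05, 1.0, size=(n_out, n_in)) / n_in
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_out, n_in))
        if spec.dyadic:
            w = np.round(w * 64) / 64
        has_bias = spec.bias_mode == "positive"
        b = rng.uniform(0.0, 0.1, size=n_out) if has_bias else None
        if spec.dyadic and b is not None:
            b = np.round(b * 64) / 64
        layers.append(LayerSpec("dense", (n_in,), (n_out,), has_bias=has_bias))
        weights.append(w)
        biases.append(b)
    net = NetworkSpec(layers, weights, biases)

    pool_factor = 8 if spec.output_margin > 0 else 1
    pool = _draw_inputs(rng, spec, spec.n_inputs * pool_factor)
    calibration = pool[: spec.n_inputs]
    if spec.normalize and not spec.dyadic:
        scales = compute_layer_scales(net, calibration)
        net = normalize_weights(net, scales)
    if spec.output_margin > 0:
        keep = []
        for x in pool:
            out = np.sort(relu_forward(net, x)[net.n_stages - 1])[::-1]
            gap = out[0] - out[1] if out.size > 1 else out[0]
            if gap >= spec.output_margin:
                keep.append(x)
            if len(keep) == spec.n_inputs:
                break
        if len(keep) < spec.n_inputs:
            raise ValueError(
                f"only {len(keep)} of {pool.shape[0]} candidate inputs reach "
                f"output margin {spec.output_margin}"
            )
        inputs = np.asarray(keep)
    else:
        inputs = calibration
    if spec.drive == "positive":
        for x in inputs:
            rec = relu_forward(net, x)
            for s in range(1, net.n_stages):
                if np.min(rec[s]) <= 0:
                    raise AssertionError(f"positive-drive fixture violated at stage {s}")
    return net, inputs


@dataclass
class OracleResult:
    """Closed-form single-neuron trajectory under constant drive."""

    counts: np.ndarray  # N(t) for t = 1..T
    spike_times: list[int]  # 1-based timesteps with a spike
    first_spike: int | None


def if_oracle(a: float, v0: float = 0.0, v_th: float = 1.0, T: int = 255) -> OracleResult:
    """Exact spike counts of one integrate-and-fire neuron.

    Under constant current ``a`` with reset by subtraction and initial
    potential ``v0``, charge conservation gives the closed form

        N(t) = floor((a * t + v0) / v_th),

    with the first spike at ``ceil((v_th - v0) / a)``.  Evaluated in
    exact rational arithmetic on the binary values of the float
    arguments, so it is immune to accumulation rounding and serves as
    an independent ground truth for the simulator.
    """
    if not 0 <= v0 < v_th:
        raise ValueError("need 0 <= v0 < v_th")
    if T < 1:
        raise ValueError("T must be >= 1")
    if a <= 0:
        return OracleResult(np.zeros(T, dtype=np.int64), [], None)
    fa, fv0, fvth = Fraction(a), Fraction(v0), Fraction(v_th)
    counts = np.empty(T, dtype=np.int64)
    spike_times: list[int] = []
    prev = 0
    for t in range(1, T + 1):
        n = floor((fa * t + fv0) / fvth)
        counts[t - 1] = n
        if n > prev:
            spike_times.append(t)
        prev = n
    first = spike_times[0] if spike_times else None
    return OracleResult(counts, spike_times, first)


_MAX_BRUTE_NEURONS = 100


def brute_force_reference(
    net: NetworkSpec,
    x: np.ndarray,
    config: SimConfig | None = None,
    pcmp=0.0,
) -> SimTrace:
    """Naive scalar-loop re-implementation of the network dynamics.

    Written independently of the production simulator (plain Python
    loops, no shared linear-algebra path) and restricted to tiny dense
    networks; used only as a test oracle.
    """
    config = config or SimConfig()
    total = sum(net.stage_size(s) for s in range(net.n_stages))
    if total > _MAX_BRUTE_NEURONS:
        raise ValueError(f"brute-force reference limited to {_MAX_BRUTE_NEURONS} neurons, got {total}")
    for layer in net.layers:
        if layer.kind != "dense":
            raise ValueError("brute-force reference supports dense layers only")
    T = config.timesteps
    if T < 1:
        raise ValueError("timesteps must be >= 1")
    vth = config.v_th
    vals = resolve_pcmp(pcmp, net.n_stages, vth)
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != net.stage_size(0):
        raise ValueError("input size mismatch")
    if any(xi < 0 or xi > 1 for xi in x):
        raise ValueError("encoded inputs must lie in [0, 1]")
    sizes = [net.stage_size(s) for s in range(net.n_stages)]
    V = [[float(vals[s])] * sizes[s] for s in range(net.n_stages)]
    C = [[0.0] * sizes[s] for s in range(net.n_stages)]  # Kahan residuals
    rasters = [np.zeros((T, sizes[s]), dtype=bool) for s in range(net.n_stages)]
    pots = [np.zeros((T + 1, sizes[s])) for s in range(net.n_stages)]
    curs = [np.zeros((T, sizes[s])) for s in range(net.n_stages)]
    for s in range(net.n_stages):
        pots[s][0] = V[s]

    def add(s: int, i: int, term: float) -> None:
        # same compensated update as the production integrator
        y = term - C[s][i]
        t_new = V[s][i] + y
        C[s][i] = (t_new - V[s][i]) - y
        V[s][i] = t_new

    for t in range(T):
        prev_spikes: list[float] = []
        for s in range(net.n_stages):
            spikes_here: list[float] = []
            for i in range(sizes[s]):
                if s == 0:
                    current = float(x[i])
                else:
                    w = net.weights[s - 1]
                    current = 0.0
                    for j in range(sizes[s - 1]):
                        current += float(w[i, j]) * prev_spikes[j]
                    b = net.biases[s - 1]
                    if b is not None:
                        current += config.r_max * float(b[i])
                add(s, i, current)
                if V[s][i] >= vth:
                    fired = 1.0
                    add(s, i, -vth)
                else:
                    fired = 0.0
                    add(s, i, 0.0)
                if config.clamp_negative and V[s][i] < 0.0:
                    V[s][i] = 0.0
                    C[s][i] = 0.0
                rasters[s][t, i] = fired > 0
                pots[s][t + 1, i] = V[s][i]
                curs[s][t, i] = current
                spikes_here.append(fired)
            prev_spikes = spikes_here
    pcmp_vals = resolve_pcmp(pcmp, net.n_stages, vth)
    return SimTrace(rasters, pots, curs, config, pcmp_vals)
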