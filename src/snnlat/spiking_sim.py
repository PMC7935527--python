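"""Clock-driven integrate-and-fire simulation of a converted network.

Every spiking *stage* (the input layer plus one stage per network
layer) holds a vector of membrane potentials.  Each timestep, stages
update in order: the input stage receives a constant current equal to
the encoded input value; stage ``l`` receives the layer's affine map
applied to the spike indicator vector that stage ``l - 1`` emitted in
the same timestep (synchronous, layer-ordered update), with the bias
contributing ``b * r_max`` every timestep.  A neuron whose potential
reaches the threshold emits one spike and is reset by subtraction: the
threshold is removed, residual charge carries over, so the firing rate
converges to the analog activation.  At most one spike per neuron per
timestep (the rate-coding cap); there is no leak and no refractory
period.

Pre-charged membrane potentials set ``V(0) = V_pc`` per stage, which
moves the first spike earlier without changing the steady-state rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network_model import NetworkSpec, linear_map_apply

__all__ = [
    "SimConfig",
    "PCMPProfile",
    "SimState",
    "SimTrace",
    "SOPCount",
    "init_state",
    "encode_input",
    "step",
    "run",
    "stage_fanouts",
    "count_sops",
]


@dataclass
class SimConfig:
    """Simulation parameters.

    ``v_th`` is 1 by convention (activations are normalized to [0, 1]);
    ``r_max`` is 1 spike/timestep by the timestep convention, and scales
    the constant bias current.  ``epoch_length`` of 255 matches 8-bit
    input precision: after 255 timesteps the input image has been
    presented in full.  ``clamp_negative`` optionally floors potentials
    at zero (off by default: negative charge is allowed to accumulate).
    """

    timesteps: int = 255
    v_th: float = 1.0
    r_max: float = 1.0
    epoch_length: int = 255
    reset: str = "subtract"
    record_potentials: bool = False
    clamp_negative: bool = False
    divergence_bound: float = 1e9
    seed: int = 0

    def __post_init__(self):
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.epoch_length < 1:
            raise ValueError("epoch_length must be >= 1")
        if self.reset != "subtract":
            raise ValueError("only reset-by-subtraction is supported")


@dataclass
class PCMPProfile:
    """Initial membrane potential per spiking stage, each in [0, v_th)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))

    @classmethod
    def globally(cls, v: float, n_stages: int) -> "PCMPProfile":
        return cls(np.full(n_stages, float(v)))

    def validate(self, v_th: float = 1.0) -> None:
        if np.any(self.values < 0) or np.any(self.values >= v_th):
            raise ValueError(f"pre-charge values must lie in [0, {v_th}), got {self.values}")

    def __getitem__(self, stage: int) -> float:
        return float(self.values[stage])

    def __len__(self) -> int:
        return len(self.values)


def resolve_pcmp(pcmp, n_stages: int, v_th: float = 1.0) -> np.ndarray:
    """Broadcast a scalar / sequence / profile to one value per stage."""
    if isinstance(pcmp, PCMPProfile):
        vals = pcmp.values
    else:
        vals = np.atleast_1d(np.asarray(pcmp, dtype=float))
    if vals.size == 1:
        vals = np.full(n_stages, float(vals[0]))
    if vals.size < n_stages:
        raise ValueError(f"pre-charge profile covers {vals.size} stages, need {n_stages}")
    vals = vals[:n_stages].astype(float)
    PCMPProfile(vals).validate(v_th)
    return vals


@dataclass
class SimState:
    """Mutable per-stage potentials and spike counts at time t.

    ``compensation`` carries the Kahan residuals of the potential
    accumulation: integrating hundreds of identical currents naively
    drifts by several ulps, enough to miss a spike whose threshold
    crossing lands exactly on V_th; compensated summation keeps the
    integration faithful to the exact sum of the injected currents.
    """

    potentials: list[np.ndarray]
    compensation: list[np.ndarray]
    counts: list[np.ndarray]
    t: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.potentials)


@dataclass
class SOPCount:
    """Synaptic operations: one per outgoing synapse per spike."""

    per_stage: np.ndarray  # int64, one entry per spiking stage
    total: int


@dataclass
class SimTrace:
    """Spike rasters (and optionally potentials/currents) of one run.

    ``spikes[l]`` is a boolean ``(T, *stage_shape)`` raster.  When
    potentials are recorded, ``potentials[l]`` has shape
    ``(T + 1, *stage_shape)`` with index 0 holding V(0), and
    ``currents[l]`` holds the injected current per timestep, from which
    drive positivity is judged for the partial-error rule.
    """

    spikes: list[np.ndarray]
    potentials: list[np.ndarray] | None
    currents: list[np.ndarray] | None
    config: SimConfig
    pcmp: np.ndarray

    @property
    def n_stages(self) -> int:
        return len(self.spikes)

    @property
    def timesteps(self) -> int:
        return self.spikes[0].shape[0]

    def counts(self, stage: int, t: int | None = None) -> np.ndarray:
        """Cumulative spike counts N(t); t defaults to the full run."""
        t = self.timesteps if t is None else t
        if not 0 <= t <= self.timesteps:
            raise ValueError(f"t={t} outside [0, {self.timesteps}]")
        return self.spikes[stage][:t].sum(axis=0, dtype=np.int64)

    def count_series(self, stage: int) -> np.ndarray:
        """N(t) for t = 1..T as an ``(T, *shape)`` integer array."""
        return np.cumsum(self.spikes[stage], axis=0, dtype=np.int64)


def kahan_add(value: np.ndarray, residual: np.ndarray, term) -> None:
    """In-place compensated addition: (value + residual) += term.

    Elementwise and branch-free, so the vectorized simulator, the
    grid-sweep integrator and the scalar reference produce bit-equal
    states from the same sequence of terms.
    """
    y = term - residual
    t = value + y
    residual[...] = (t - value) - y
    value[...] = t


def encode_input(x: np.ndarray) -> np.ndarray:
    """Constant-current encoding: pixel/feature value = current/timestep.

    8-bit images should be divided by 255 beforehand so entries lie in
    [0, 1]; values outside that range are rejected (normalize first).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("encoded inputs must lie in [0, 1]; normalize first")
    return x.copy()


def init_state(
    net: NetworkSpec,
    pcmp,
    config: SimConfig | None = None,
    n_stages: int | None = None,
) -> SimState:
    """Fresh state: potentials pre-charged to V_pc, zero spike counts."""
    config = config or SimConfig()
    n_stages = net.n_stages if n_stages is None else n_stages
    vals = resolve_pcmp(pcmp, n_stages, config.v_th)
    potentials = [np.full(net.stage_shape(s), vals[s], dtype=float) for s in range(n_stages)]
    compensation = [np.zeros(net.stage_shape(s), dtype=float) for s in range(n_stages)]
    counts = [np.zeros(net.stage_shape(s), dtype=np.int64) for s in range(n_stages)]
    return SimState(potentials, compensation, counts)


def step(
    state: SimState,
    net: NetworkSpec,
    config: SimConfig,
    input_current: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Advance one timestep; returns (spike vectors, injected currents)."""
    spikes: list[np.ndarray] = []
    currents: list[np.ndarray] = []
    prev_spk: np.ndarray | None = None
    for s in range(state.n_stages):
        if s == 0:
            cur = input_current
        else:
            layer = net.layers[s - 1]
            cur = linear_map_apply(
                layer,
                net.weights[s - 1],
                net.biases[s - 1],
                prev_spk,
                include_bias=True,
                bias_scale=config.r_max,
            )
        V = state.potentials[s]
        c = state.compensation[s]
        kahan_add(V, c, cur)
        spk = V >= config.v_th
        kahan_add(V, c, np.where(spk, -config.v_th, 0.0))
        if config.clamp_negative:
            below = V < 0.0
            V[below] = 0.0
            c[below] = 0.0
        if np.any(np.abs(V) > config.divergence_bound):
            raise FloatingPointError(
                f"stage {s}: membrane potential exceeded {config.divergence_bound} at t={state.t + 1}"
            )
        state.counts[s] += spk
        spikes.append(spk)
        currents.append(np.asarray(cur, dtype=float))
        prev_spk = spk.astype(float)
    state.t += 1
    return spikes, currents


def run(
    net: NetworkSpec,
    x: np.ndarray,
    config: SimConfig | None = None,
    pcmp=0.0,
    n_stages: int | None = None,
) -> SimTrace:
    """Simulate T timesteps; deterministic given (net, x, config, pcmp).

    ``n_stages`` restricts the simulation to the first stages (1 =
    input stage only), which the layer-wise pre-charge optimizer uses.
    """
    config = config or SimConfig()
    if config.timesteps < 1:
        raise ValueError("timesteps must be >= 1")
    n_stages = net.n_stages if n_stages is None else n_stages
    if not 1 <= n_stages <= net.n_stages:
        raise ValueError(f"n_stages must be in [1, {net.n_stages}]")
    cur0 = encode_input(x).reshape(net.stage_shape(0))
    state = init_state(net, pcmp, config, n_stages)
    T = config.timesteps
    rasters = [np.zeros((T,) + net.stage_shape(s), dtype=bool) for s in range(n_stages)]
    record = config.record_potentials
    pots = curs = None
    if record:
        pots = [np.zeros((T + 1,) + net.stage_shape(s)) for s in range(n_stages)]
        curs = [np.zeros((T,) + net.stage_shape(s)) for s in range(n_stages)]
        for s in range(n_stages):
            pots[s][0] = state.potentials[s]
    for t in range(T):
        spk, cur = step(state, net, config, cur0)
        for s in range(n_stages):
            rasters[s][t] = spk[s]
            if record:
                pots[s][t + 1] = state.potentials[s]
                curs[s][t] = cur[s]
    pcmp_vals = resolve_pcmp(pcmp, n_stages, config.v_th)
    return SimTrace(rasters, pots, curs, config, pcmp_vals)


def stage_fanouts(net: NetworkSpec, n_stages: int | None = None) -> list[np.ndarray]:
    """Outgoing-synapse count per neuron of each stage.

    A spike in stage ``l`` triggers one synaptic operation per synapse
    into stage ``l + 1``; the output stage has fan-out zero.  Dense
    layers connect every input to every output; for a convolution the
    fan-out of an input position is the number of kernel placements
    covering it times the number of output channels; global average
    pooling connects each input element to exactly one output.
    """
    n_stages = net.n_stages if n_stages is None else n_stages
    fanouts: list[np.ndarray] = []
    for s in range(n_stages):
        shape = net.stage_shape(s)
        if s == n_stages - 1:
            fanouts.append(np.zeros(shape, dtype=np.int64))
            continue
        layer = net.layers[s]
        if layer.kind == "dense":
            fanouts.append(np.full(shape, layer.n_out, dtype=np.int64))
        elif layer.kind == "gap":
            fanouts.append(np.ones(shape, dtype=np.int64))
        else:  # conv2d
            out_c, in_c, kh, kw = net.weights[s].shape
            _, h, w = layer.input_shape
            cover = np.zeros((h, w), dtype=np.int64)
            _, oh, ow = layer.output_shape
            for oy in range(oh):
                for ox in range(ow):
                    y0 = oy * layer.stride - layer.padding
                    x0 = ox * layer.stride - layer.padding
                    ys = slice(max(y0, 0), min(y0 + kh, h))
                    xs = slice(max(x0, 0), min(x0 + kw, w))
                    cover[ys, xs] += 1
            fan = np.broadcast_to(cover * out_c, (in_c, h, w)).astype(np.int64)
            fanouts.append(fan)
    return fanouts


def count_sops(
    net: NetworkSpec,
    trace: SimTrace,
    up_to_t: int | None = None,
    method: str = "per_timestep",
) -> SOPCount:
    """Synaptic operations in the first ``up_to_t`` timesteps.

    ``method="per_timestep"`` multiplies cumulative spike counts by
    fan-outs; ``method="per_spike"`` walks the raster spike by spike.
    Both are exact integer tallies and must agree.
    """
    t = trace.timesteps if up_to_t is None else up_to_t
    if not 0 <= t <= trace.timesteps:
        raise ValueError(f"up_to_t={t} outside [0, {trace.timesteps}]")
    fanouts = stage_fanouts(net, trace.n_stages)
    for s in range(trace.n_stages):
        if trace.spikes[s].shape[1:] != fanouts[s].shape:
            raise ValueError(f"trace stage {s} shape does not match network")
    per_stage = np.zeros(trace.n_stages, dtype=np.int64)
    if method == "per_timestep":
        for s in range(trace.n_stages):
            counts = trace.counts(s, t)
            per_stage[s] = int((counts * fanouts[s]).sum())
    elif method == "per_spike":
        for s in range(trace.n_stages):
            fan = fanouts[s]
            acc = 0
            for ti in range(t):
                acc += int(fan[trace.spikes[s][ti]].sum())
            per_stage[s] = acc
    else:
        raise ValueError(f"unknown method {method!r}")
    return SOPCount(per_stage, int(per_stage.sum()))
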