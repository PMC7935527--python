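"""Latency-reduction methods: pre-charged potentials and delayed evaluation.

Two inference-time techniques shorten the transient before a rate-coded
spiking network reaches its steady-state performance:

* **Pre-charged membrane potential (PCMP).**  Starting integration from
  ``V_pc`` in (0, v_th) instead of 0 makes the first spike fire after
  ``ceil((v_th - V_pc) / a)`` timesteps instead of ``ceil(v_th / a)``,
  without altering the steady-state rate (the reset-by-subtraction
  dynamics forget the initial condition at rate 1/t).  The pre-charge
  can be global (one value for the whole network) or optimized layer by
  layer: sweep a grid of candidate values for one stage at a time, in
  input-to-output order, keeping the already-chosen values applied to
  the earlier stages, and pick the value minimizing the time-summed
  mean-squared deviation of firing rates from the analog activations
  over one epoch.

* **Delayed evaluation (DE).**  Output-layer spikes emitted in the
  first ``D`` timesteps carry the transient's error; discarding them
  and evaluating only spikes in ``(D, T]`` removes those error spikes
  at the cost of a shorter averaging window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_model import NetworkSpec, linear_map_apply, relu_forward
from .spiking_sim import (
    PCMPProfile,
    SimConfig,
    SimTrace,
    encode_input,
    kahan_add,
    resolve_pcmp,
    run,
)

__all__ = [
    "OptimizationConfig",
    "DelayConfig",
    "global_pcmp",
    "layer_error_objective",
    "optimize_pcmp_layerwise",
    "delayed_counts",
]


def _default_grid() -> np.ndarray:
    return np.round(np.arange(51) * 0.01, 2)


@dataclass
class OptimizationConfig:
    """Grid and horizon of the layer-wise pre-charge search.

    Defaults: candidate values 0.00 to 0.50 in steps of 0.01, objective
    summed over one epoch of 255 timesteps (8-bit input precision).
    """

    grid: np.ndarray = field(default_factory=_default_grid)
    horizon: int = 255

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size == 0:
            raise ValueError("grid must be nonempty")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class DelayConfig:
    """Intentional output-evaluation delay, in timesteps."""

    delay: int = 0

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


def global_pcmp(v: float, n_stages: int, v_th: float = 1.0) -> PCMPProfile:
    """Uniform pre-charge: the same V_pc for every stage of the network."""
    profile = PCMPProfile.globally(v, n_stages)
    profile.validate(v_th)
    return profile


def layer_error_objective(
    net: NetworkSpec,
    inputs,
    pcmp_prefix,
    stage: int,
    v_stage: float,
    horizon: int = 255,
    config: SimConfig | None = None,
) -> float:
    """Time-summed mean-squared rate error of one stage.

    Simulates stages 0..``stage`` with the fixed pre-charge prefix on
    the earlier stages and the candidate ``v_stage`` on this one, and
    returns  sum_{t=1..horizon} mean_i (N_i(t)/t - a_i)^2,  averaged
    over the input sample; ``a_i`` are the analog activations of the
    (normalized) network.
    """
    if not 0 <= stage < net.n_stages:
        raise ValueError(f"stage {stage} out of range")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    base = config or SimConfig()
    cfg = SimConfig(
        timesteps=horizon,
        v_th=base.v_th,
        r_max=base.r_max,
        epoch_length=base.epoch_length,
        clamp_negative=base.clamp_negative,
    )
    prefix = np.atleast_1d(np.asarray(pcmp_prefix, dtype=float))
    vals = np.zeros(stage + 1)
    vals[:stage] = prefix[:stage]
    vals[stage] = v_stage
    inputs = list(inputs)
    if not inputs:
        raise ValueError("input set is empty")
    t_axis = np.arange(1, horizon + 1, dtype=float)[:, None]
    total = 0.0
    for x in inputs:
        a = relu_forward(net, x)[stage].reshape(-1)
        trace = run(net, x, cfg, pcmp=vals, n_stages=stage + 1)
        cum = trace.count_series(stage).reshape(horizon, -1)
        err = cum / t_axis - a[None, :]
        total += float((err**2).mean(axis=1).sum())
    return total / len(inputs)


def _stage_current_series(
    net: NetworkSpec,
    x: np.ndarray,
    stage: int,
    prefix_vals: np.ndarray,
    cfg: SimConfig,
) -> np.ndarray:
    """Injected current into ``stage`` per timestep, shape (T, n)."""
    T = cfg.timesteps
    if stage == 0:
        cur = encode_input(x).reshape(1, -1)
        return np.broadcast_to(cur, (T, cur.size)).copy()
    trace = run(net, x, cfg, pcmp=prefix_vals, n_stages=stage)
    layer = net.layers[stage - 1]
    w, b = net.weights[stage - 1], net.biases[stage - 1]
    out = np.empty((T, net.stage_size(stage)))
    for t in range(T):
        out[t] = linear_map_apply(
            layer, w, b, trace.spikes[stage - 1][t].astype(float),
            include_bias=True, bias_scale=cfg.r_max,
        ).reshape(-1)
    return out


def _sweep_stage(
    currents: np.ndarray,
    a: np.ndarray,
    grid: np.ndarray,
    v_th: float,
    clamp_negative: bool,
) -> np.ndarray:
    """Objective value per grid point for one stage, one input.

    Integrates the stage's dynamics for all candidate pre-charges at
    once; the update order (add current, then threshold and subtract)
    matches the stage update of the full simulator exactly.
    """
    T, n = currents.shape
    G = grid.size
    V = np.tile(grid[:, None], (1, n))
    c = np.zeros((G, n))
    counts = np.zeros((G, n), dtype=np.int64)
    obj = np.zeros(G)
    for t in range(T):
        kahan_add(V, c, currents[t][None, :])
        spk = V >= v_th
        kahan_add(V, c, np.where(spk, -v_th, 0.0))
        if clamp_negative:
            below = V < 0.0
            V[below] = 0.0
            c[below] = 0.0
        counts += spk
        err = counts / float(t + 1) - a[None, :]
        obj += (err**2).mean(axis=1)
    return obj


def optimize_pcmp_layerwise(
    net: NetworkSpec,
    inputs,
    opt: OptimizationConfig | None = None,
    config: SimConfig | None = None,
) -> tuple[PCMPProfile, list[np.ndarray]]:
    """Sequential layer-wise pre-charge optimization.

    For each stage from input to output, evaluates the time-summed
    mean-squared rate error over the candidate grid with all previously
    chosen pre-charges applied to the earlier stages (stages not yet
    optimized do not influence the objective of the current stage in a
    feedforward network), and fixes the minimizer; ties break toward
    the smaller grid value.  Returns the profile and the per-stage
    objective curves over the grid.
    """
    opt = opt or OptimizationConfig()
    base = config or SimConfig()
    if np.any(opt.grid < 0) or np.any(opt.grid >= base.v_th):
        raise ValueError("grid values must lie in [0, v_th)")
    cfg = SimConfig(
        timesteps=opt.horizon,
        v_th=base.v_th,
        r_max=base.r_max,
        epoch_length=base.epoch_length,
        clamp_negative=base.clamp_negative,
    )
    inputs = list(inputs)
    if not inputs:
        raise ValueError("input set is empty")
    acts = [relu_forward(net, x) for x in inputs]
    chosen = np.zeros(net.n_stages)
    curves: list[np.ndarray] = []
    for stage in range(net.n_stages):
        curve = np.zeros(opt.grid.size)
        dead = True
        for x, rec in zip(inputs, acts):
            a = rec[stage].reshape(-1)
            if np.any(a > 0):
                dead = False
            cur = _stage_current_series(net, x, stage, chosen, cfg)
            curve += _sweep_stage(cur, a, opt.grid, cfg.v_th, cfg.clamp_negative)
        curve /= len(inputs)
        curves.append(curve)
        if dead:
            warnings.warn(f"stage {stage} is dead on the input sample; pre-charge set to 0")
            chosen[stage] = 0.0
            continue
        chosen[stage] = opt.grid[int(np.argmin(curve))]  # first minimum = smaller value
    profile = PCMPProfile(chosen)
    profile.validate(cfg.v_th)
    return profile, curves


def delayed_counts(trace: SimTrace, delay: DelayConfig | int) -> np.ndarray:
    """Output-stage spike counts restricted to timesteps in (D, T].

    The rate denominator for reconstruction tasks is ``T - D``; for
    classification, the most-firing output neuron over the window is
    the predicted class.
    """
    d = delay.delay if isinstance(delay, DelayConfig) else int(delay)
    T = trace.timesteps
    if not 0 <= d < T:
        raise ValueError(f"delay must satisfy 0 <= D < T={T}, got {d}")
    return trace.spikes[trace.n_stages - 1][d:].sum(axis=0, dtype=np.int64)
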