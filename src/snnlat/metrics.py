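"""Diagnostics: firing rates, error decomposition, latency measures.

The central identity of rate-coded conversion follows from charge
conservation in a reset-by-subtraction neuron: over ``t`` timesteps the
injected charge splits into emitted spikes and residual potential, so

    N(t)/t  =  (total current)/t  -  (V(t) - V(0)) / t.

For an input-stage neuron the current is the constant encoded input
``a``, giving  ``r(t) = a - (V(t) - V(0))/t``  exactly.  The deviation
``-(V(t) - V(0))/t`` of a positively driven neuron is its *partial
error*; a neuron receiving no positive drive never spikes and its
partial error is zero.  The deviation of a stage's firing rate from
the analog activation (the *network error* E = r - a) is the stage's
own partial error plus the partial errors of all earlier stages
propagated through the intervening weights — an exact decomposition
whenever drive stays positive so that the ReLU never clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .network_model import ActivationRecord, NetworkSpec, linear_map_apply
from .spiking_sim import SimTrace

__all__ = [
    "MetricSeries",
    "ErrorDecomposition",
    "Classification",
    "firing_rate",
    "partial_error",
    "error_decomposition",
    "normalized_mean_rate",
    "correlation_points",
    "classify",
    "output_mse",
    "latency_to_fraction",
    "accuracy_series",
    "mse_series",
]


@dataclass
class MetricSeries:
    """A metric sampled over timesteps, with identifying metadata."""

    timesteps: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timesteps = np.asarray(self.timesteps, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.timesteps.size != self.values.size:
            raise ValueError("timesteps and values must have equal length")
        if self.timesteps.size and np.any(np.diff(self.timesteps) <= 0):
            raise ValueError("timesteps must be strictly increasing")


class Classification(NamedTuple):
    label: int
    no_spike: bool


@dataclass
class ErrorDecomposition:
    """Direct and recursively reconstructed network errors at one time.

    ``exact`` is True when every neuron satisfied the positive-drive
    condition and no analog pre-activation was clipped by the ReLU, in
    which case ``direct`` and ``recursive`` agree to floating
    tolerance; otherwise the reconstruction is only approximate.
    """

    partial: list[np.ndarray]
    direct: list[np.ndarray]
    recursive: list[np.ndarray]
    exact: bool


def _require_potentials(trace: SimTrace) -> None:
    if trace.potentials is None or trace.currents is None:
        raise ValueError("trace was recorded without potentials; rerun with record_potentials=True")


def firing_rate(trace: SimTrace, stage: int, t: int) -> np.ndarray:
    """Elementwise spike rate N(t)/t, in [0, 1]."""
    if not 1 <= t <= trace.timesteps:
        raise ValueError(f"t must be in [1, {trace.timesteps}], got {t}")
    return trace.counts(stage, t) / float(t)


def partial_error(trace: SimTrace, stage: int, t: int) -> np.ndarray:
    """-(V(t) - V(0))/t where cumulative drive is positive, else 0."""
    _require_potentials(trace)
    if not 1 <= t <= trace.timesteps:
        raise ValueError(f"t must be in [1, {trace.timesteps}], got {t}")
    V = trace.potentials[stage]
    driven = trace.currents[stage][:t].sum(axis=0) > 0
    eps = -(V[t] - V[0]) / float(t)
    return np.where(driven, eps, 0.0)


def error_decomposition(
    trace: SimTrace,
    activations: ActivationRecord,
    net: NetworkSpec,
    t: int,
) -> ErrorDecomposition:
    """Network error per stage, directly and via the weighted recursion.

    Direct: E^l = r^l - a^l.  Recursive: E^0 = eps^0 and
    E^l = eps^l + W^l E^(l-1) (linear map without bias), which matches
    the direct error exactly on positive-drive runs.
    """
    _require_potentials(trace)
    n_stages = trace.n_stages
    partial = [partial_error(trace, s, t) for s in range(n_stages)]
    direct = [firing_rate(trace, s, t) - activations[s] for s in range(n_stages)]
    recursive = [partial[0]]
    exact = True
    for s in range(1, n_stages):
        layer = net.layers[s - 1]
        propagated = linear_map_apply(
            layer, net.weights[s - 1], None, recursive[s - 1], include_bias=False
        )
        recursive.append(partial[s] + propagated)
        pre = linear_map_apply(layer, net.weights[s - 1], net.biases[s - 1], activations[s - 1])
        if np.any(pre < 0):
            exact = False
    for s in range(n_stages):
        undriven = ~(trace.currents[s][:t].sum(axis=0) > 0)
        dv = trace.potentials[s][t] - trace.potentials[s][0]
        if np.any(undriven & (dv != 0)):
            exact = False
    return ErrorDecomposition(partial, direct, recursive, exact)


def normalized_mean_rate(
    traces: Sequence[SimTrace],
    activations: Sequence[ActivationRecord],
    stage: int,
    t: int,
) -> float:
    """<f_SNN>_norm: summed rates over summed activations, over samples.

    The ratio of sums runs over all neurons with positive analog
    activation across the sample (a mean of per-neuron ratios would
    blow up as a -> 0).  Converges to 1 at steady state on a
    normalized network.
    """
    num = 0.0
    den = 0.0
    for trace, rec in zip(traces, activations):
        a = np.asarray(rec[stage], dtype=float).reshape(-1)
        r = firing_rate(trace, stage, t).reshape(-1)
        mask = a > 0
        num += float(r[mask].sum())
        den += float(a[mask].sum())
    if den == 0.0:
        raise ValueError("all activations are zero; normalized rate undefined")
    return num / den


def correlation_points(
    trace: SimTrace,
    activations: ActivationRecord,
    stage: int,
    t: int,
) -> tuple[np.ndarray, float]:
    """(activation, rate) pair per neuron plus through-origin LS slope.

    Perfect rate/activation correspondence puts every point on y = x
    (slope 1); during the transient the rates lag and the slope is
    below 1.
    """
    a = np.asarray(activations[stage], dtype=float).reshape(-1)
    r = firing_rate(trace, stage, t).reshape(-1)
    points = np.column_stack([a, r])
    denom = float((a**2).sum())
    slope = float((a * r).sum() / denom) if denom > 0 else float("nan")
    return points, slope


def classify(output_counts: np.ndarray) -> Classification:
    """Most-firing output neuron; ties and all-silent resolve to the
    smallest index, with ``no_spike`` flagging the silent case."""
    counts = np.asarray(output_counts)
    if counts.size == 0:
        raise ValueError("empty output counts")
    return Classification(int(np.argmax(counts)), bool(counts.max() == 0))


def output_mse(
    trace: SimTrace,
    activations: ActivationRecord,
    t: int,
    delay: int = 0,
) -> float:
    """Mean squared output error: rate over (D, t] versus activation."""
    if not 0 <= delay < t:
        raise ValueError(f"need 0 <= delay < t, got delay={delay}, t={t}")
    if t > trace.timesteps:
        raise ValueError(f"t={t} exceeds trace length {trace.timesteps}")
    L = trace.n_stages - 1
    counts = trace.spikes[L][delay:t].sum(axis=0, dtype=np.int64)
    rate = counts / float(t - delay)
    a = np.asarray(activations[L], dtype=float)
    return float(((rate - a.reshape(rate.shape)) ** 2).mean())


def latency_to_fraction(
    series: MetricSeries,
    reference: float,
    fraction: float,
) -> int | None:
    """Smallest recorded timestep with a sustained crossing.

    Returns the first t whose value — and every later recorded value —
    reaches ``fraction * reference``; ``None`` if the level is never
    sustained.  The sustained rule guards against transient touches on
    noisy small-sample curves.
    """
    if series.timesteps.size == 0:
        raise ValueError("empty metric series")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if reference <= 0:
        raise ValueError("reference must be positive")
    ok = series.values >= fraction * reference
    sustained = np.logical_and.accumulate(ok[::-1])[::-1]
    if not sustained.any():
        return None
    return int(series.timesteps[int(np.argmax(sustained))])


def accuracy_series(
    traces: Sequence[SimTrace],
    labels: Sequence[int],
    delay: int = 0,
) -> MetricSeries:
    """Classification accuracy at every evaluable timestep.

    At time t the predicted class of each sample is the most-firing
    output neuron over the window (D, t]; evaluation starts at
    t = D + 1.
    """
    T = traces[0].timesteps
    if not 0 <= delay < T:
        raise ValueError(f"delay must satisfy 0 <= D < T={T}")
    labels = np.asarray(labels, dtype=int)
    ts = np.arange(delay + 1, T + 1)
    correct = np.zeros(ts.size)
    for trace, label in zip(traces, labels):
        L = trace.n_stages - 1
        cum = trace.count_series(L).reshape(T, -1)
        window = cum[delay:] - (cum[delay - 1] if delay > 0 else 0)
        pred = np.argmax(window, axis=1)
        correct += pred == label
    return MetricSeries(ts, correct / len(traces), {"delay": delay})


def mse_series(
    traces: Sequence[SimTrace],
    activations: Sequence[ActivationRecord],
    delay: int = 0,
) -> MetricSeries:
    """Mean output MSE over samples at every evaluable timestep."""
    T = traces[0].timesteps
    if not 0 <= delay < T:
        raise ValueError(f"delay must satisfy 0 <= D < T={T}")
    ts = np.arange(delay + 1, T + 1)
    acc = np.zeros(ts.size)
    for trace, rec in zip(traces, activations):
        L = trace.n_stages - 1
        a = np.asarray(rec[L], dtype=float).reshape(-1)
        cum = trace.count_series(L).reshape(T, -1)
        window = cum[delay:] - (cum[delay - 1] if delay > 0 else 0)
        rates = window / (ts - delay).astype(float)[:, None]
        acc += ((rates - a[None, :]) ** 2).mean(axis=1)
    return MetricSeries(ts, acc / len(traces), {"delay": delay})
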