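# snnlat

Low-latency inference for rate-coded spiking neural networks.

## The problem

Converting a trained ReLU feedforward network into a spiking network of
integrate-and-fire (IF) neurons is one of the most reliable routes to
high-accuracy, event-driven inference: each analog neuron is mapped
one-to-one onto a spiking neuron whose firing rate approximates the
ReLU activation. The price is *latency*. Information is carried by
spike counts per unit time, so the network needs many timesteps before
its rates — and therefore its accuracy, or its reconstruction error —
reach the analog network's level, and the transient worsens with depth.

`snnlat` implements the conversion and two inference-time remedies:

* **Pre-charged membrane potential (PCMP).** Initialize every membrane
  potential to some `V_pc ∈ (0, V_th)` instead of 0. A neuron under
  constant drive `a` then fires its first spike after
  `ceil((V_th − V_pc)/a)` timesteps instead of `ceil(V_th/a)`, while
  the steady-state rate is untouched (with reset by subtraction the
  initial condition decays like `1/t`). The pre-charge can be one
  global value, or optimized layer by layer: sweep a grid of
  candidates for one layer at a time from input to output, keeping the
  already-chosen values applied upstream, and minimize the time sum of
  the mean-squared rate error `⟨[E^l(t, V^l)]²⟩` over one epoch.
* **Delayed evaluation (DE).** Output spikes emitted during the first
  `D` timesteps carry the transient's error; evaluating only spikes in
  `(D, T]` removes them at the cost of a shorter averaging window.

## The model

Neurons are pure integrate-and-fire (no leak, no refractory period)
with reset by subtraction, updated layer-synchronously each timestep.
The input layer receives a constant current equal to the encoded input
(8-bit images divided by 255); at most one spike per neuron per
timestep (`r_max = 1`), bias currents inject `b·r_max` every step.
Charge conservation gives the firing rate

    r_i^l(t) = N_i^l(t)/t
             = (1/V_th) [ Σ_j w_ij^l r_j^(l−1)(t) + r_max b_i^l
                          − (V_i^l(t) − V_i^l(0))/t ],

so the deviation from the analog activation decomposes into *partial
errors* `ε_i^l = −(V_i^l(t) − V_i^l(0))/t` propagated through the
weights — the quantity the layer-wise optimizer minimizes, and which
`snnlat.metrics` reconstructs and verifies. Before conversion, weights
are rescaled by data-based normalization (`w·λ^(l−1)/λ^l`, `b/λ^l`
with `λ^l` the maximum activation observed on a calibration set) so
every activation is representable as a rate in [0, 1].

## Worked example

```python
import numpy as np
import snnlat as sl

# a small synthetic ReLU classifier, already normalized for conversion
spec = sl.FixtureSpec(
    layer_sizes=(12, 16, 16, 10), n_inputs=32,
    weight_mode="mixed", drive="any",
    input_range=(0.05, 0.9), output_margin=0.05, seed=19,
)
net, inputs = sl.make_fixture(spec)
acts = [sl.relu_forward(net, x) for x in inputs]
labels = [int(np.argmax(a[net.n_stages - 1])) for a in acts]

cfg = sl.SimConfig(timesteps=255)

# baseline: no pre-charge
base = [sl.run(net, x, cfg, pcmp=0.0) for x in inputs]
t99_base = sl.latency_to_fraction(sl.accuracy_series(base, labels), 1.0, 0.99)

# layer-wise optimized pre-charge
profile, _ = sl.optimize_pcmp_layerwise(net, inputs)
opt = [sl.run(net, x, cfg, pcmp=profile) for x in inputs]
t99_opt = sl.latency_to_fraction(sl.accuracy_series(opt, labels), 1.0, 0.99)

sops_base = sum(sl.count_sops(net, t, up_to_t=t99_base).total for t in base)
sops_opt = sum(sl.count_sops(net, t, up_to_t=t99_opt).total for t in opt)

print("optimized pre-charge per stage:", np.round(profile.values, 2))
print(f"t_99% latency: {t99_base} -> {t99_opt} timesteps")
print(f"synaptic ops to t_99%: {sops_base} -> {sops_opt} "
      f"({100 * (sops_base - sops_opt) / sops_base:.0f}% saved)")
```

prints

```
optimized pre-charge per stage: [0.5  0.39 0.19 0.5 ]
t_99% latency: 13 -> 9 timesteps
synaptic ops to t_99%: 49950 -> 39180 (22% saved)
```

`t_99%` is the first timestep from which the spiking classifier
sustains at least 99 % of the analog network's accuracy (here the
analog argmax labels themselves, so reference accuracy is 1). The
optimized pre-charge fires first spikes earlier in every layer, so the
accuracy curve shifts left and the event count needed to reach the
criterion drops accordingly.

## Layout

| module | contents |
| --- | --- |
| `snnlat.network_model` | ReLU network container, forward pass, validation |
| `snnlat.conversion` | data-based weight normalization |
| `snnlat.spiking_sim` | clock-driven IF simulation, traces, synaptic-operation counts |
| `snnlat.latency_methods` | global/optimized pre-charge, delayed evaluation |
| `snnlat.metrics` | rates, error decomposition, correlation, latency-to-criterion |
| `snnlat.fixtures` | synthetic networks and independent dynamics oracles |
| `snnlat.io`, `snnlat.cli` | file formats and the `snnlat` command line |
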