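# Methods

## Model

`snnlat` simulates feedforward spiking networks obtained by one-to-one
conversion of ReLU networks to integrate-and-fire (IF) neurons under
rate coding. The neuron model is deliberately minimal: no leak, no
refractory period, reset by subtraction. Each timestep every stage
updates in network order — the input stage first, then one stage per
layer — and a stage's synaptic current is the layer's affine map
applied to the spike indicator vector its predecessor emitted *in the
same global timestep*. This layer-synchronous scheme is the standard
clock-driven convention of the conversion literature and makes the
input-stage rate identity exact:

    N(t)/t = a − (V(t) − V(0))/t,

a direct consequence of charge conservation (injected charge = emitted
spikes × V_th + residual potential). A neuron spikes when `V ≥ V_th`
(closed bound, so a steady current of exactly `V_th` fires every
step), emits at most one spike per timestep regardless of how far `V`
exceeds threshold (excess charge carries over; the rate code caps at
`r_max = 1` spike/timestep), and biases inject `b · r_max` every
timestep. Negative potentials are allowed to accumulate by default —
the ReLU correspondence is already enforced by spiking only at
threshold — and a `clamp_negative` switch floors them at zero for
users who want the alternative convention; nothing in the test suite
depends on the clamp.

### Parameters that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| `v_th` | 1.0 | potential | activations are normalized to [0, 1]; threshold 1 makes rate = activation at steady state |
| `r_max` | 1.0 | spikes/timestep | timestep convention: the fastest neuron fires every step; also scales the bias current |
| `timesteps` (T) | 255 | timesteps | default horizon; one epoch |
| `epoch_length` | 255 | timesteps | 8-bit inputs are fully presented after 255 steps; the optimizer's default horizon |
| `V_pc` | 0.0 | potential | pre-charge, per stage, in [0, V_th); 0 reproduces the conventional cold start |
| `delay` (D) | 0 | timesteps | output spikes at t ≤ D are discarded; rates over (D, T] use denominator T − D |

Lowering `V_th` would also shorten latency but changes the
steady-state rate and so propagates a systematic error downstream;
pre-charging does not, because the initial condition enters the rate
only through `(V(t) − V(0))/t`, which decays as `1/t`. This is the
entire case for PCMP and the package treats it as the invariant to
test, not to tune.

## Conversion

Data-based normalization computes per-stage scales `λ^l` (maximum
observed activation over a calibration set, `λ^0 = 1` for inputs
already in [0, 1]) and rescales `w → w·λ^(l−1)/λ^l`, `b → b/λ^l`.
This preserves the network function up to per-layer rescaling
(`a'^l = a^l/λ^l`, asserted exactly in tests) and makes every
calibration activation representable as a rate ≤ 1. Two judgment
calls:

* a *dead* stage (no positive activation anywhere) gets scale 1.0
  with a warning — any positive floor works, since a dead layer
  transmits nothing, and 1.0 leaves its weights untouched;
* weightless stages (global average pooling) inherit the previous
  stage's scale: they have no weights to absorb a rescaling, and a
  spatial mean never exceeds its inputs' maximum, so continuity of the
  `λ` ratios is preserved. A percentile option (e.g. 99.9) is exposed
  for outlier-robust scaling but the default is the strict maximum.

## Layer-wise pre-charge optimization

Joint optimization over all layers is exponential in depth, so the
optimizer is sequential: for stages `l = 0 … L`, evaluate the
objective

    Σ_{t=1..horizon} ⟨[E^l(t, V^l)]²⟩,
    ⟨[E^l]²⟩ = Σ_i (N_i^l(t)/t − a_i^l)² / M^l,

averaged over the input sample, for each candidate `V^l` on the grid
(default 0.00–0.50 in 0.01 steps), with all previously chosen
pre-charges applied upstream, then fix the minimizer and move on. In
a feedforward network the not-yet-optimized downstream stages cannot
influence the objective of the current stage, so the sweep simulates
only stages `0..l`; the implementation additionally caches the
upstream spike trains per input and integrates just the swept stage
for all grid values at once, which is exact (same update order,
elementwise identical arithmetic) and roughly grid-size times faster
than re-simulating the prefix. Design choices the problem leaves
open: the time sum starts at `t = 1` (`N/t` is undefined at 0); the
per-input mean-squared errors are averaged over the sample before the
time sum (the symmetric aggregation); ties break toward the smaller
pre-charge, the conservative side with respect to early over-firing;
a dead stage gets `V_pc = 0` with a warning.

On a single neuron under constant drive the objective is a step
function of `V^l`: it falls as the pre-charge centers the floor
quantization (minimum near `V_th/2`) and rises beyond it from early
over-firing, so the curve has an interior global minimum on a grid
that spans `[0, V_th)`; on the default 0.00–0.50 grid the minimum may
sit at the upper edge. Multi-neuron layers average many such steps
into the smooth dip-then-rise curve the optimizer exploits.

## Delayed evaluation

Evaluation (classification argmax, or rate reconstruction) uses only
output spikes with `t > D`. Classification ties break to the smallest
index and an all-silent window is flagged. Three regimes emerge and
are asserted on fixtures: while `D` is shorter than the output layer's
no-spike period the result cannot change (latency plateau); moderate
delays discard transient error spikes (latency/MSE improve); large
delays shrink the averaging window until quantization noise and the
delay itself dominate (latency and MSE rise).

## Error decomposition

With potentials recorded, the partial error of a positively driven
neuron is `ε = −(V(t) − V(0))/t` (zero for an undriven neuron, which
never spikes). The stage error `E^l = r^l − a^l` is reconstructed
recursively as `E^0 = ε^0`, `E^l = ε^l + W^l E^(l−1)` and compared
against the directly measured error. The reconstruction is exact
(within accumulated float rounding, < 1e−9 in practice) whenever all
drives are positive and no analog pre-activation is clipped by the
ReLU; the result carries an `exact` flag and mixed-sign runs are
marked approximate rather than asserted.

## Numerical choices

* **Compensated integration.** Membrane potentials accumulate via
  Kahan summation, in the vectorized simulator, the grid-sweep
  integrator and the scalar reference alike (the identical elementwise
  update, so all three produce bit-equal states from equal inputs).
  Naive accumulation of hundreds of identical currents drifts by
  several ulps, enough to miss spikes whose threshold crossing lands
  exactly on `V_th` (e.g. drive 0.9 at `t = 10`); with compensation
  the simulator reproduces the exact-rational closed form on such
  boundary cases.
* **Closed-form oracle in exact arithmetic.** The single-neuron law
  `N(t) = floor((a·t + V0)/V_th)` is evaluated with `fractions.Fraction`
  on the binary values of the float arguments, immune to rounding.
* **Dyadic fixtures.** Fixture inputs are quantized to multiples of
  1/256 (mirroring 8-bit input precision); a `dyadic` mode also
  quantizes weights to 1/64 and skips normalization. On dyadic data
  every float operation is exact, so oracle-equivalence tests can
  demand bit-for-bit agreement instead of tolerances.
* **Degenerate inputs.** `T = 0` is rejected; `V_pc` outside
  `[0, V_th)` is rejected; a diverging potential (beyond a
  configurable bound) aborts with a diagnostic; latency-to-criterion
  uses a *sustained* crossing rule (first timestep from which the
  criterion holds for every later recorded value), which is stable on
  small-sample accuracy curves where a first-touch rule would be
  noise-sensitive, and returns a "not reached" sentinel (`None`)
  otherwise.

## What the synthetic fixtures do and do not show

The fixture generator emits small dense ReLU networks (optionally
positive-drive, optionally with decisive output margins for
classification) with quantized inputs, already normalized. They
emulate the *structure* of converted networks — activations in [0, 1],
one-to-one rate correspondence, realistic transients — but not the
statistics of trained vision models: no convolutional feature
hierarchies, no near-tie class scores, layer counts of 3 rather than
9+, and tens of neurons rather than tens of thousands. Consequently
the measured latencies are a dozen timesteps rather than hundreds, and
the pre-charge/delay savings (typically 5–60 % on latency, 15–25 % on
synaptic operations to criterion, reported by
`scripts/acceptance.py`) demonstrate the mechanisms and the exact
invariants, not the magnitudes attainable on deep trained networks.
Problem sizes throughout (3-layer fixtures, ≤ 50 neurons, horizons of
255–1024 timesteps, 32-sample input sets) were chosen as the smallest
at which every qualitative regime — transient, steady state, no-spike
plateau, error-removal window, excessive delay — is clearly separated.

## Known limitations

* Transposed convolutions and residual paths are not implemented; the
  layer abstraction (any linear map plus bias) admits them as
  extensions.
* Only rate coding is supported — no temporal, phase, burst or
  weighted-spike codes — and only synchronous clock-driven simulation,
  not event-driven execution or hardware mapping.
* Training is out of scope: networks arrive as weight archives.
* The layer-wise optimizer assumes all neurons of a stage share one
  pre-charge; per-neuron pre-charges would enlarge the search space
  beyond what the sequential sweep justifies.
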