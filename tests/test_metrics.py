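import numpy as np
import pytest

from snnlat import (
    MetricSeries,
    SimConfig,
    accuracy_series,
    classify,
    correlation_points,
    error_decomposition,
    firing_rate,
    latency_to_fraction,
    mse_series,
    normalized_mean_rate,
    output_mse,
    partial_error,
    relu_forward,
    run,
)


class TestFiringRate:
    def test_count_over_time(self, identity_neuron):
        trace = run(identity_neuron, np.array([0.4]), SimConfig(timesteps=10))
        assert firing_rate(trace, 0, 10)[0] == pytest.approx(0.4)  # N=4, t=10

    def test_input_layer_charge_identity(self, identity_neuron):
        """r^0(t) = a^0 - (V(t) - V(0))/t, from the recorded potentials."""
        a = np.array([0.4])
        cfg = SimConfig(timesteps=7, record_potentials=True)
        trace = run(identity_neuron, a, cfg)
        v7 = trace.potentials[0][7, 0]
        assert v7 == pytest.approx(0.8)
        assert firing_rate(trace, 0, 7)[0] == pytest.approx(0.4 - 0.8 / 7)
        assert firing_rate(trace, 0, 7)[0] == pytest.approx(2 / 7)

    def test_silent_layer_rate_zero(self, identity_neuron):
        trace = run(identity_neuron, np.array([0.0]), SimConfig(timesteps=10))
        assert firing_rate(trace, 1, 10)[0] == 0.0
        with pytest.raises(ValueError):
            firing_rate(trace, 0, 0)


class TestPartialError:
    def test_precharge_cancels_residual(self, identity_neuron):
        # a=0.4, V0=0.5: at t=10 the potential is back at 0.5, so eps = 0
        cfg = SimConfig(timesteps=10, record_potentials=True)
        trace = run(identity_neuron, np.array([0.4]), cfg, pcmp=[0.5, 0.0])
        assert trace.potentials[0][10, 0] == pytest.approx(0.5)
        assert partial_error(trace, 0, 10)[0] == pytest.approx(0.0)

    def test_zero_start_residual(self, identity_neuron):
        cfg = SimConfig(timesteps=7, record_potentials=True)
        trace = run(identity_neuron, np.array([0.4]), cfg)
        assert partial_error(trace, 0, 7)[0] == pytest.approx(-0.8 / 7)

    def test_undriven_neuron_zero_by_rule(self, identity_neuron):
        cfg = SimConfig(timesteps=10, record_potentials=True)
        trace = run(identity_neuron, np.array([0.0]), cfg, pcmp=[0.3, 0.0])
        assert partial_error(trace, 0, 10)[0] == 0.0

    def test_requires_recorded_potentials(self, identity_neuron):
        trace = run(identity_neuron, np.array([0.4]), SimConfig(timesteps=10))
        with pytest.raises(ValueError):
            partial_error(trace, 0, 5)


class TestErrorDecomposition:
    def test_chain_recursion_matches_direct(self, identity_chain):
        """E^1 = eps^1 + w * eps^0 equals r^1 - a^1 on a two-stage chain."""
        cfg = SimConfig(timesteps=10, record_potentials=True)
        trace = run(identity_chain, np.array([0.4]), cfg)
        acts = relu_forward(identity_chain, np.array([0.4]))
        dec = error_decomposition(trace, acts, identity_chain, 10)
        assert dec.exact
        for s in range(3):
            np.testing.assert_allclose(dec.recursive[s], dec.direct[s], atol=1e-12)

    def test_base_case_input_stage(self, identity_neuron):
        cfg = SimConfig(timesteps=8, record_potentials=True)
        trace = run(identity_neuron, np.array([0.7]), cfg)
        acts = relu_forward(identity_neuron, np.array([0.7]))
        dec = error_decomposition(trace, acts, identity_neuron, 8)
        np.testing.assert_allclose(dec.recursive[0], dec.partial[0])
        np.testing.assert_allclose(dec.direct[0], dec.partial[0], atol=1e-12)

    def test_both_sides_vanish_at_long_times(self, positive_fixture):
        net, inputs = positive_fixture
        cfg = SimConfig(timesteps=1024, record_potentials=True)
        trace = run(net, inputs[0], cfg)
        acts = relu_forward(net, inputs[0])
        dec = error_decomposition(trace, acts, net, 1024)
        for s in range(net.n_stages):
            assert np.abs(dec.direct[s]).max() < 0.02
            assert np.abs(dec.recursive[s]).max() < 0.02

    def test_exact_on_positive_drive_at_all_times(self, positive_fixture):
        net, inputs = positive_fixture
        cfg = SimConfig(timesteps=128, record_potentials=True)
        trace = run(net, inputs[1], cfg, pcmp=0.2)
        acts = relu_forward(net, inputs[1])
        worst = 0.0
        for t in range(1, 129):
            dec = error_decomposition(trace, acts, net, t)
            assert dec.exact
            for s in range(net.n_stages):
                worst = max(worst, float(np.abs(dec.recursive[s] - dec.direct[s]).max()))
        assert worst < 1e-9

    def test_mixed_sign_flagged_approximate(self, mixed_fixture):
        net, inputs = mixed_fixture
        cfg = SimConfig(timesteps=64, record_potentials=True)
        trace = run(net, inputs[0], cfg)
        acts = relu_forward(net, inputs[0])
        dec = error_decomposition(trace, acts, net, 64)
        assert not dec.exact


class TestAggregateMetrics:
    def test_normalized_mean_rate_is_ratio_of_sums(self):
        # input-stage rates {0.2, 0.4} against activations {0.4, 0.4} -> 0.75
        from snnlat import LayerSpec, NetworkSpec

        net = NetworkSpec(
            [LayerSpec("dense", (2,), (2,), has_bias=False)], [np.eye(2)], [None]
        )
        trace = run(net, np.array([0.2, 0.4]), SimConfig(timesteps=10))
        acts = relu_forward(net, np.array([0.4, 0.4]))
        assert normalized_mean_rate([trace], [acts], 0, 10) == pytest.approx(0.75)

    def test_normalized_mean_rate_converges_to_one(self, positive_fixture):
        net, inputs = positive_fixture
        traces = [run(net, x, SimConfig(timesteps=1024)) for x in inputs]
        acts = [relu_forward(net, x) for x in inputs]
        L = net.n_stages - 1
        v = normalized_mean_rate(traces, acts, L, 1024)
        assert v == pytest.approx(1.0, abs=2 * L / 1024)

    def test_all_silent_trace_gives_zero(self, identity_neuron):
        trace = run(identity_neuron, np.array([0.0]), SimConfig(timesteps=16))
        acts = relu_forward(identity_neuron, np.array([0.5]))  # pretend positive target
        assert normalized_mean_rate([trace], [acts], 0, 16) == 0.0

    def test_all_zero_activations_rejected(self, identity_neuron):
        trace = run(identity_neuron, np.array([0.0]), SimConfig(timesteps=16))
        acts = relu_forward(identity_neuron, np.array([0.0]))
        with pytest.raises(ValueError):
            normalized_mean_rate([trace], [acts], 0, 16)

    def test_correlation_slope(self, positive_fixture):
        net, inputs = positive_fixture
        acts = relu_forward(net, inputs[0])
        t1 = run(net, inputs[0], SimConfig(timesteps=64))
        t2 = run(net, inputs[0], SimConfig(timesteps=512))
        L = net.n_stages - 1
        points64, slope64 = correlation_points(t1, acts, L, 64)
        points512, slope512 = correlation_points(t2, acts, L, 512)
        assert points64.shape == (net.stage_size(L), 2)
        assert slope64 <= slope512 + 1e-9  # lag shrinks with time
        assert slope512 == pytest.approx(1.0, abs=0.05)


class TestClassify:
    @pytest.mark.parametrize(
        "counts, label, no_spike",
        [([3, 5, 2], 1, False), ([4, 4], 0, False), ([0, 0, 0], 0, True)],
    )
    def test_argmax_with_tie_break(self, counts, label, no_spike):
        got = classify(np.array(counts))
        assert got.label == label and got.no_spike == no_spike

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([]))


class TestOutputMse:
    def test_perfect_rates_zero_mse(self, identity_chain):
        trace = run(identity_chain, np.array([1.0]), SimConfig(timesteps=16))
        acts = relu_forward(identity_chain, np.array([1.0]))
        assert output_mse(trace, acts, 16) == pytest.approx(0.0)

    def test_silent_output_mse(self, identity_chain):
        trace = run(identity_chain, np.array([0.0]), SimConfig(timesteps=16))
        acts = relu_forward(identity_chain, np.array([0.5]))
        assert output_mse(trace, acts, 16) == pytest.approx(0.25)

    def test_transient_decays_between_horizons(self, positive_fixture):
        net, inputs = positive_fixture
        trace = run(net, inputs[0], SimConfig(timesteps=512))
        acts = relu_forward(net, inputs[0])
        assert output_mse(trace, acts, 512) <= output_mse(trace, acts, 128) + 1e-12

    def test_delay_validation(self, identity_chain):
        trace = run(identity_chain, np.array([0.5]), SimConfig(timesteps=16))
        acts = relu_forward(identity_chain, np.array([0.5]))
        with pytest.raises(ValueError):
            output_mse(trace, acts, 16, delay=16)


class TestLatencyToFraction:
    def test_first_sustained_crossing(self):
        series = MetricSeries(np.arange(1, 6), [0.5, 0.8, 0.99, 0.995, 0.999])
        assert latency_to_fraction(series, 1.0, 0.99) == 3

    def test_never_reached(self):
        series = MetricSeries(np.arange(1, 4), [0.1, 0.2, 0.3])
        assert latency_to_fraction(series, 1.0, 0.99) is None

    def test_dip_defers_crossing(self):
        values = [0.99, 0.5, 0.6, 0.7, 0.8, 0.9, 0.995, 0.999]
        series = MetricSeries(np.arange(1, 9), values)
        assert latency_to_fraction(series, 1.0, 0.99) == 7

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            latency_to_fraction(MetricSeries(np.array([]), np.array([])), 1.0, 0.99)


class TestSeries:
    def test_accuracy_series_reaches_one(self, positive_fixture):
        net, inputs = positive_fixture
        traces = [run(net, x, SimConfig(timesteps=255)) for x in inputs]
        labels = [int(np.argmax(relu_forward(net, x)[net.n_stages - 1])) for x in inputs]
        series = accuracy_series(traces, labels)
        assert series.timesteps[0] == 1 and series.timesteps[-1] == 255
        assert series.values[-1] == pytest.approx(1.0)

    def test_mse_series_matches_pointwise_metric(self, positive_fixture):
        net, inputs = positive_fixture
        traces = [run(net, x, SimConfig(timesteps=64)) for x in inputs]
        acts = [relu_forward(net, x) for x in inputs]
        series = mse_series(traces, acts, delay=8)
        t = 40
        expected = np.mean([output_mse(tr, a, t, delay=8) for tr, a in zip(traces, acts)])
        idx = int(np.where(series.timesteps == t)[0][0])
        assert series.values[idx] == pytest.approx(expected, rel=1e-12)
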