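"""Spike detection and adaptation statistics on constructed fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tmas_adapt as ta
from tmas_adapt.errors import InsufficientSpikesError
from tmas_adapt.metrics import SpikeFrequencyCurve, SpikeTrain


def train(times, window=None):
    times = np.asarray(times, dtype=float)
    if window is None:
        window = (0.0, float(times[-1]) + 10.0)
    return SpikeTrain(times, window)


class TestDetectSpikes:
    def test_recovers_planted_template_spikes(self):
        st_in = train([50.0, 100.0, 200.0], window=(0.0, 250.0))
        tr = ta.synthetic_membrane_trace(st_in, dt=0.01)
        out = ta.detect_spikes(tr)
        assert len(out) == 3
        assert np.allclose(out.spike_times, st_in.spike_times, atol=0.01)

    def test_constant_subthreshold_trace_yields_flagged_empty_train(self):
        tr = ta.MembraneTrace(t0=0.0, dt=0.1,
                              V_series=np.full(1000, -65.0),
                              stimulus_series=np.zeros(1000))
        out = ta.detect_spikes(tr)
        assert len(out) == 0 and out.flagged_empty

    def test_noisy_double_crossing_is_suppressed(self):
        # two upward crossings 0.3 ms apart must count as one spike
        t = np.arange(0.0, 5.0, 0.05)
        V = np.full(t.size, -65.0)
        for t0 in (2.0, 2.3):
            V[np.isclose(t, t0)] = 10.0
            V[np.isclose(t, t0 + 0.05)] = -10.0
        tr = ta.MembraneTrace(t0=0.0, dt=0.05, V_series=V,
                              stimulus_series=np.zeros_like(V))
        assert len(ta.detect_spikes(tr, min_separation=1.0)) == 1


class TestSpikeFrequencyCurve:
    def test_two_interval_example(self):
        c = ta.spike_frequency_curve(train([10.0, 20.0, 40.0]))
        assert np.allclose(c.values, [100.0, 50.0])
        assert c(15.0) == 100.0 and c(25.0) == 50.0
        assert np.isnan(c(45.0))

    def test_uniform_train_is_constant(self):
        c = ta.spike_frequency_curve(train(np.arange(0.0, 100.0, 8.0)))
        assert np.allclose(c.values, 125.0)

    def test_insufficient_spikes(self):
        with pytest.raises(InsufficientSpikesError):
            ta.spike_frequency_curve(train([5.0]))

    @given(st.lists(st.floats(min_value=0.5, max_value=50.0),
                    min_size=2, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_onset_equals_first_curve_value(self, isis):
        times = np.concatenate([[1.0], 1.0 + np.cumsum(isis)])
        t = train(times, window=(0.0, float(times[-1]) + 1.0))
        assert ta.onset_frequency(t) == ta.spike_frequency_curve(t).values[0]


class TestSteadyStateFrequency:
    def test_constant_curve(self):
        c = ta.spike_frequency_curve(train(np.arange(0.0, 500.0, 8.0)))
        assert ta.steady_state_frequency(c, (0.0, 500.0)) == pytest.approx(125.0)

    def test_exponential_curve_tail_bound(self):
        spec = ta.SyntheticTrainSpec(f0=300.0, f_inf=120.0, tau=30.0,
                                     duration=500.0)
        c = ta.spike_frequency_curve(ta.synthetic_adapting_train(spec))
        f_inf = ta.steady_state_frequency(c, (0.0, 500.0))
        assert f_inf == pytest.approx(120.0, rel=0.01)

    def test_curve_outside_window_raises(self):
        c = ta.spike_frequency_curve(train([10.0, 20.0, 30.0]))
        with pytest.raises(InsufficientSpikesError):
            ta.steady_state_frequency(c, (400.0, 500.0))


class TestSettlingTime:
    def test_constant_curve_settles_at_first_breakpoint(self):
        c = ta.spike_frequency_curve(train(np.arange(5.0, 500.0, 8.0)))
        assert ta.settling_time(c, 125.0) == 5.0

    def test_exponential_curve_matches_analytic_settling(self):
        f0, f_inf, tau = 300.0, 120.0, 40.0
        spec = ta.SyntheticTrainSpec(f0=f0, f_inf=f_inf, tau=tau, duration=600.0)
        tr = ta.synthetic_adapting_train(spec)
        c = ta.spike_frequency_curve(tr)
        rel = 0.05
        T = ta.settling_time(c, f_inf, rel_tol=rel)
        T_analytic = tau * np.log((f0 - f_inf) / (rel * f_inf))
        max_isi = np.max(np.diff(tr.spike_times))
        assert abs(T - T_analytic) <= max_isi

    def test_monotone_nonincreasing_in_tolerance(self):
        spec = ta.SyntheticTrainSpec(f0=350.0, f_inf=120.0, tau=60.0,
                                     duration=500.0)
        c = ta.spike_frequency_curve(ta.synthetic_adapting_train(spec))
        tols = [0.01, 0.02, 0.05, 0.1, 0.2]
        times = [ta.settling_time(c, 120.0, rel_tol=r) for r in tols]
        assert all(t is not None for t in times)
        assert all(a >= b for a, b in zip(times, times[1:]))

    def test_never_settling_returns_sentinel(self):
        c = SpikeFrequencyCurve(np.array([0.0, 10.0, 20.0]),
                                np.array([300.0, 200.0]))
        assert ta.settling_time(c, 100.0) is None


class TestFiringPattern:
    def test_uniform_isis_are_spiking(self):
        assert ta.classify_firing_pattern(
            train(np.arange(0.0, 100.0, 5.0))) == "Spiking"

    def test_clustered_train_is_bursting(self):
        t = ta.synthetic_bursting_train(burst_rate=20.0, intra_burst_isi=3.0,
                                        spikes_per_burst=5, duration=500.0)
        assert ta.classify_firing_pattern(t) == "Bursting"

    def test_three_spike_minimum(self):
        with pytest.raises(InsufficientSpikesError):
            ta.classify_firing_pattern(train([1.0, 2.0]))


class TestMinFrequency:
    def test_excludes_inter_burst_gaps(self):
        t = ta.synthetic_bursting_train(burst_rate=10.0, intra_burst_isi=4.0,
                                        spikes_per_burst=5, duration=400.0)
        c = ta.spike_frequency_curve(t)
        # the raw curve minimum is the gap interval (~1000/84 Hz); the
        # within-burst minimum is the intra-burst rate
        assert c.values.min() < 50.0
        assert ta.min_frequency(c, (0.0, 400.0)) == pytest.approx(250.0)


def test_summarize_full_pipeline_on_synthetic_trace():
    spec = ta.SyntheticTrainSpec(f0=350.0, f_inf=120.0, tau=60.0, duration=500.0)
    st_in = ta.synthetic_adapting_train(spec)
    tr = ta.synthetic_membrane_trace(st_in, dt=0.01)
    s = ta.summarize(tr, (0.0, 500.0))
    assert s.f0 == pytest.approx(350.0, rel=0.03)
    assert s.f_inf == pytest.approx(120.0, rel=0.03)
    assert s.pattern == "Spiking"
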