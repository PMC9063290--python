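"""Stimulus model: Lorentz current amplitude, square-wave gate, waveform."""

import numpy as np
import pytest

import tmas_adapt as ta
from tmas_adapt.errors import InvalidParameterError
from tmas_adapt.params import SoftRangeWarning


def make(**kw):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SoftRangeWarning)
        return ta.StimulusParameters(**kw)


class TestCurrentAmplitude:
    def test_hand_computed_baseline(self):
        # sigma*B*sqrt(2*Gamma_SI/(rho*c0)) = 0.5*2*sqrt(6e4/(1120*1540))
        p = make(sigma=0.5, B_x=2.0, Gamma=3.0, rho=1120.0, c0=1540.0)
        assert ta.current_amplitude(p) == pytest.approx(0.18651, abs=5e-6)

    def test_zero_field_is_warned_and_gives_zero(self):
        with pytest.warns(SoftRangeWarning):
            p = ta.StimulusParameters(B_x=0.0)
        assert ta.current_amplitude(p) == 0.0

    def test_square_root_intensity_scaling(self):
        assert ta.current_amplitude(make(Gamma=4.0)) == pytest.approx(
            2.0 * ta.current_amplitude(make(Gamma=1.0)))

    @pytest.mark.parametrize("field", ["sigma", "B_x"])
    def test_linear_in_conductivity_and_field(self, field):
        base = make()
        scales = np.array([0.5, 1.0, 2.0, 3.5])
        amps = [ta.current_amplitude(make(**{field: getattr(base, field) * s}))
                for s in scales]
        assert np.allclose(amps, ta.current_amplitude(base) * scales)

    @pytest.mark.parametrize("bad", [dict(sigma=0.0), dict(rho=-1.0),
                                     dict(c0=0.0), dict(f_u=0.0),
                                     dict(RF=0.0), dict(DC=0.0), dict(DC=1.5)])
    def test_nonpositive_constants_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            ta.StimulusParameters(**bad)

    def test_out_of_range_values_warn_but_are_accepted(self):
        with pytest.warns(SoftRangeWarning):
            p = ta.StimulusParameters(B_x=12.0)
        assert p.B_x == 12.0


class TestModulationGate:
    @pytest.mark.parametrize("t,expected", [(0.25, 1), (0.75, 0), (1.25, 1),
                                            (0.0, 0), (0.5, 1), (0.5001, 0)])
    def test_half_open_on_phase(self, t, expected):
        assert ta.modulation_gate(t, RF=1.0, DC=0.5) == expected

    def test_periodicity(self):
        t = np.linspace(0.001, 0.999, 400)
        g0 = ta.modulation_gate(t, 5.0, 0.3)
        g1 = ta.modulation_gate(t + 3.0 / 5.0, 5.0, 0.3)
        assert np.array_equal(g0, g1)

    @pytest.mark.parametrize("dc", [0.1, 0.5, 0.95])
    def test_time_average_equals_duty_cycle(self, dc):
        t = (np.arange(200_000) + 0.5) / 200_000  # one period at RF=1
        assert ta.modulation_gate(t, 1.0, dc).mean() == pytest.approx(dc, abs=1e-4)

    def test_full_duty_cycle_is_continuous_wave(self):
        t = np.linspace(1e-6, 5.0, 1000)
        assert np.all(ta.modulation_gate(t, 7.0, 1.0) == 1)


class TestTmasCurrent:
    def test_off_phase_is_zero(self):
        p = make()
        t = np.linspace(0.51, 0.99, 50)  # first off-phase at RF=1, DC=0.5
        assert np.all(ta.tmas_current(t, p) == 0.0)

    def test_nonnegative_and_bounded(self):
        p = make()
        t = np.linspace(0.0, 2.0, 100_001)
        i = ta.tmas_current(t, p)
        amp = ta.A_PER_M2_TO_UA_PER_CM2 * ta.current_amplitude(p)
        assert np.all(i >= 0.0)
        assert np.all(i <= 2.0 * amp + 1e-12)

    def test_offset_cancels_at_carrier_trough(self):
        p = make()
        # sin(2 pi f_u t) = -1 at t = 3/(4 f_u)
        t = 3.0 / (4.0 * p.f_u_hz())
        assert ta.tmas_current(t, p) == pytest.approx(0.0, abs=1e-9)

    def test_cycle_average_is_mean_drive(self):
        p = make()
        cycle = 1.0 / p.f_u_hz()
        t = 0.1 + cycle * (np.arange(10_000) + 0.5) / 10_000
        assert ta.tmas_current(t, p).mean() == pytest.approx(18.651, rel=1e-4)

    def test_envelope_mode_equals_cycle_mean(self):
        p = make()
        assert ta.tmas_current(0.2, p, envelope=True) == pytest.approx(
            ta.A_PER_M2_TO_UA_PER_CM2 * ta.current_amplitude(p))

    def test_carrier_periodicity_within_on_phase(self):
        p = make()
        cycle = 1.0 / p.f_u_hz()
        t = 0.2 + np.linspace(0.0, cycle, 64, endpoint=False)
        assert np.allclose(ta.tmas_current(t, p),
                           ta.tmas_current(t + 5 * cycle, p))


def test_config_round_trip(tmp_path):
    p = make(B_x=3.0, Gamma=1.5)
    n = ta.NeuronParameters(g_M=4.0)
    path = tmp_path / "run.yaml"
    ta.save_config(path, stimulus=p, neuron=n, simulation={"duration": 250.0})
    loaded = ta.load_config(path)
    assert loaded["stimulus"] == p
    assert loaded["neuron"] == n
    assert loaded["simulation"]["duration"] == 250.0


def test_waveform_table_columns():
    from tmas_adapt.stimulus import waveform_table
    w = waveform_table(make(), duration_ms=1.0, dt_ms=0.001)
    assert w.shape[1] == 2
    assert np.all(np.diff(w[:, 0]) > 0)
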