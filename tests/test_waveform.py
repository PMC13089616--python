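"""Waveform generation, quantization rules and the transient circuit oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stimbalance import (
    CurrentWaveform,
    ElectrodeTissueModel,
    StimulationSettings,
    build_waveform,
    discharge_current,
    integrate_charge,
    quantize_current,
    quantize_time,
    transient_oracle,
    v_capacitor,
)
from stimbalance.waveform import CURRENT_MAX, CURRENT_STEP, TIME_STEP


def cap_settings(**overrides):
    base = dict(
        mode="cap_coupled",
        i_pos=0.5e-3,
        i_neg=0.5e-3,
        t_pos=200e-6,
        t_neg=200e-6,
        period=1e-3,
        c_source=0.1e-6,
        t_charge=150e-6,
    )
    base.update(overrides)
    return StimulationSettings(**base)


class TestQuantization:
    @pytest.mark.parametrize("i, expected", [
        (1.6e-3, 1.6e-3),          # full scale stays reachable via the clamp
        (0.0, 0.0),
        (10e-6, 12.6e-6),          # nearest 6.3 uA multiple
        (-10e-6, -12.6e-6),
        (2e-3, 1.6e-3),            # clamp above full scale
        (3.15e-6, 0.0),            # exact half-step tie rounds toward zero
        (-3.15e-6, 0.0),
    ])
    def test_current_examples(self, i, expected):
        assert quantize_current(i) == pytest.approx(expected, abs=1e-12)

    def test_current_brute_force_nearest(self):
        """Cross-check against an enumeration of all DAC codes."""
        codes = np.arange(0, 255) * CURRENT_STEP
        for i in (10e-6, 123.4e-6, 1.111e-3, 0.9e-3):
            nearest = codes[np.argmin(np.abs(codes - i))]
            assert quantize_current(i) == pytest.approx(min(nearest, CURRENT_MAX))

    @given(st.floats(min_value=-5e-3, max_value=5e-3))
    def test_current_idempotent(self, i):
        once = quantize_current(i)
        assert quantize_current(once) == once

    @given(st.floats(min_value=-5e-3, max_value=5e-3))
    def test_current_never_exceeds_requested_magnitude_or_clamp(self, i):
        q = quantize_current(i)
        assert abs(q) <= CURRENT_MAX
        # ties toward zero: quantization may round up by strictly less than half a step
        assert abs(q) <= abs(i) + CURRENT_STEP / 2

    @pytest.mark.parametrize("t, expected", [
        (136.4e-6, 136e-6),
        (0.0, 0.0),
        (17e-6, 17e-6),  # integer-microsecond fixed point
    ])
    def test_time_examples(self, t, expected):
        assert quantize_time(t) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(min_value=0, max_value=10.0))
    def test_time_idempotent(self, t):
        once = quantize_time(t)
        assert quantize_time(once) == once
        assert abs(once - t) <= TIME_STEP / 2 + 1e-12


class TestSourceCapacitor:
    @pytest.mark.parametrize("i, t, c, expected", [
        (0.5e-3, 150e-6, 0.1e-6, 0.75),
        (0.5e-3, 0.0, 0.1e-6, 0.0),
        (0.5e-3, 200e-6, 0.1e-6, 1.0),
    ])
    def test_charging_voltage(self, i, t, c, expected):
        assert v_capacitor(i, t, c) == pytest.approx(expected)

    def test_zero_capacitance_rejected(self):
        with pytest.raises(ValueError):
            v_capacitor(0.5e-3, 150e-6, 0.0)

    def test_discharge_initial_value(self, slow_rc_model):
        assert discharge_current(slow_rc_model, 1.0, 0.0) == pytest.approx(1 / 730)

    def test_discharge_decays_by_e_at_tau(self, slow_rc_model):
        tau = slow_rc_model.time_constant
        i0 = discharge_current(slow_rc_model, 1.0, 0.0)
        assert discharge_current(slow_rc_model, 1.0, tau) == pytest.approx(i0 / math.e)


class TestBuildWaveform:
    def test_symmetric_biphasic_integrates_to_zero(self):
        s = StimulationSettings("biphasic", 0.5e-3, 0.5e-3, 200e-6, 200e-6, 1e-3)
        w = build_waveform(s, dt=1e-7)
        assert abs(integrate_charge(w)) < 1e-3 * 0.5e-3 * 200e-6

    def test_cap_coupled_peak_matches_closed_form(self, slow_rc_model):
        s = cap_settings()
        w = build_waveform(s, model=slow_rc_model, dt=1e-7)
        peak = w.samples.max()
        assert peak == pytest.approx(s.v_cap() / 730.0, rel=1e-9)
        # i_pos quantizes to 497.7 uA, so v_cap sits just below the nominal 0.75 V
        assert peak == pytest.approx(0.75 / 730.0, rel=5e-3)

    def test_duration_covers_one_period(self, slow_rc_model):
        s = cap_settings()
        w = build_waveform(s, model=slow_rc_model, dt=1e-7)
        assert w.t_end == pytest.approx(s.period, abs=1e-7)

    def test_biphasic_samples_respect_dac_full_scale(self):
        s = StimulationSettings("biphasic", 1.6e-3, 1.6e-3, 200e-6, 200e-6, 1e-3)
        w = build_waveform(s, dt=1e-7)
        assert np.all(np.abs(w.samples) <= CURRENT_MAX + 1e-15)

    def test_cap_coupled_requires_model(self):
        with pytest.raises(ValueError, match="model"):
            build_waveform(cap_settings(), model=None)

    def test_cap_coupled_requires_source_capacitor(self):
        with pytest.raises(ValueError, match="c_source"):
            StimulationSettings("cap_coupled", 0.5e-3, 0.5e-3, 200e-6, 200e-6, 1e-3)

    def test_coarse_dt_rejected(self, slow_rc_model):
        with pytest.raises(ValueError):
            build_waveform(cap_settings(), model=slow_rc_model, dt=2e-6)


class TestIntegrateCharge:
    def test_square_pulse_charge(self):
        """0.5 mA over 200 us is 100 nC."""
        w = CurrentWaveform(dt=1e-7, samples=np.full(2001, 0.5e-3))
        assert integrate_charge(w, 0, 200e-6) == pytest.approx(100e-9, rel=1e-12)

    def test_zero_waveform(self):
        w = CurrentWaveform(dt=1e-7, samples=np.zeros(100))
        assert integrate_charge(w) == 0.0

    def test_reversed_bounds_rejected(self):
        w = CurrentWaveform(dt=1e-7, samples=np.zeros(100))
        with pytest.raises(ValueError):
            integrate_charge(w, 5e-6, 1e-6)

    def test_exponential_phase_matches_antiderivative(self, slow_rc_model):
        s = cap_settings()
        w = build_waveform(s, model=slow_rc_model, dt=1e-7)
        q = integrate_charge(w, s.t_neg, s.t_neg + s.t_pos)
        tau = slow_rc_model.time_constant
        closed = s.v_cap() / 730.0 * tau * (1 - math.exp(-s.t_pos / tau))
        assert q == pytest.approx(closed, rel=1e-3)

    def test_fractional_bounds_interpolate(self):
        w = CurrentWaveform(dt=1e-6, samples=np.full(11, 1e-3))
        assert integrate_charge(w, 0.5e-6, 9.5e-6) == pytest.approx(9e-9, rel=1e-9)


class TestTransientOracle:
    def test_charge_conservation_against_capacitor_drop(self, slow_rc_model):
        """Anodic charge equals the charge released by the source capacitor."""
        s = cap_settings()
        res = transient_oracle(slow_rc_model, s, dt=1e-7)
        k0 = int(round(s.t_neg / 1e-7))
        k1 = int(round((s.t_neg + s.t_pos) / 1e-7))
        q_cap = s.c_source * (res.v_source[k0] - res.v_source[k1])
        q_int = integrate_charge(res.waveform, s.t_neg, s.t_neg + s.t_pos)
        assert q_int == pytest.approx(q_cap, rel=1e-3)

    def test_charging_reaches_expected_voltage(self, slow_rc_model):
        s = cap_settings()
        res = transient_oracle(slow_rc_model, s, dt=1e-7)
        k0 = int(round(s.t_neg / 1e-7))
        assert res.v_source[k0] == pytest.approx(s.v_cap(), rel=1e-9)

    def test_refining_dt_changes_charge_below_tenth_percent(self, slow_rc_model):
        s = cap_settings()
        q1 = integrate_charge(
            transient_oracle(slow_rc_model, s, dt=1e-7).waveform, s.t_neg, s.t_neg + s.t_pos
        )
        q2 = integrate_charge(
            transient_oracle(slow_rc_model, s, dt=1e-8).waveform, s.t_neg, s.t_neg + s.t_pos
        )
        assert abs(q2 - q1) / abs(q2) < 1e-3

    def test_large_source_capacitor_approaches_voltage_source(self):
        """With Csource >> Cp the discharge follows the ideal-source step response."""
        model = ElectrodeTissueModel(220.0, 510.0, 1e-7)
        # i_neg = 0 so the tissue capacitor starts the discharge uncharged
        s = cap_settings(c_source=1e-3, t_neg=50e-6, t_charge=50e-6, i_neg=0.0,
                         t_pos=100e-6, i_pos=1.6e-3, period=160e-6)
        v0 = s.v_cap()
        res = transient_oracle(model, s, dt=2e-9)
        t = res.times
        sel = (t >= s.t_neg) & (t <= s.t_neg + s.t_pos)
        t_rel = t[sel] - s.t_neg
        # ideal voltage source V0 across Rs + (Rp || Cp): current steps from
        # V0/Rs down to V0/(Rs+Rp) with time constant (Rs||Rp)*Cp
        r_s, r_p, c_p = model.r_s, model.r_p, model.c_p
        tau = (r_s * r_p / (r_s + r_p)) * c_p
        ideal = v0 / (r_s + r_p) * (1 + (r_p / r_s) * np.exp(-t_rel / tau))
        # skip the first instants where Cp still carries cathodic charge
        mask = t_rel > 5 * tau
        err = np.max(np.abs(res.waveform.samples[sel][mask] - ideal[mask]) / ideal[mask])
        assert err < 0.01

    def test_small_tissue_capacitance_gives_single_rc_decay(self):
        """With Cp -> 0 the discharge is a pure RC decay with Csource*(Rs+Rp)."""
        model = ElectrodeTissueModel(220.0, 510.0, 1e-9)
        s = cap_settings(t_neg=50e-6, t_charge=50e-6, i_neg=0.0,
                         t_pos=150e-6, period=210e-6)
        res = transient_oracle(model, s, dt=2e-9)
        t = res.times
        sel = (t >= s.t_neg + 2e-6) & (t <= s.t_neg + s.t_pos)
        t_rel = t[sel] - s.t_neg
        tau_rc = s.c_source * (model.r_s + model.r_p)
        ideal = s.v_cap() / (model.r_s + model.r_p) * np.exp(-t_rel / tau_rc)
        err = np.max(np.abs(res.waveform.samples[sel] - ideal) / ideal.max())
        assert err < 0.01

    def test_unstable_dt_rejected(self, slow_rc_model):
        with pytest.raises(ValueError, match="stability"):
            transient_oracle(slow_rc_model, cap_settings(), dt=1e-6 * 500)

    def test_oracle_requires_cap_coupled_mode(self, slow_rc_model):
        s = StimulationSettings("biphasic", 0.5e-3, 0.5e-3, 200e-6, 200e-6, 1e-3)
        with pytest.raises(ValueError):
            transient_oracle(slow_rc_model, s)


class TestSettingsValidation:
    def test_currents_and_times_quantized_on_construction(self):
        s = StimulationSettings("biphasic", 10e-6, 0.5e-3, 136.4e-6, 200e-6, 1e-3)
        assert s.i_pos == pytest.approx(12.6e-6)
        assert s.t_pos == pytest.approx(136e-6)

    def test_period_bounds(self):
        with pytest.raises(ValueError, match="period"):
            StimulationSettings("biphasic", 0.5e-3, 0.5e-3, 1e-6, 1e-6, 5e-6)
        with pytest.raises(ValueError, match="period"):
            StimulationSettings("biphasic", 0.5e-3, 0.5e-3, 1e-3, 1e-3, 11.0)

    def test_phases_must_fit_in_period(self):
        with pytest.raises(ValueError, match="period"):
            StimulationSettings("biphasic", 0.5e-3, 0.5e-3, 600e-6, 600e-6, 1e-3)

    def test_t_charge_defaults_to_t_neg(self):
        s = StimulationSettings("cap_coupled", 0.5e-3, 0.5e-3, 200e-6, 300e-6,
                                1e-3, c_source=0.1e-6)
        assert s.t_charge == s.t_neg
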