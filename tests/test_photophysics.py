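"""Sensor forward model: quenching, dark-state kinetics, channel composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from clsense import configs
from clsense.photophysics import (
    IlluminationEvent,
    PhotophysicsParams,
    SensorState,
    dark_increment,
    dark_recovery,
    emitted_rate,
    emitted_signal,
    steady_state_dark,
    yfp_quench_factor,
)


def params(**over) -> PhotophysicsParams:
    return configs.default_photophysics(**over)


class TestQuench:
    def test_zero_chloride_is_unquenched(self):
        assert yfp_quench_factor(0.0, params()) == 1.0

    def test_half_quench_at_ec50(self):
        p = params(ec50=30.0, hill=1.0, residual_q=0.0)
        assert yfp_quench_factor(30.0, p) == pytest.approx(0.5, abs=1e-12)

    def test_negative_chloride_rejected(self):
        with pytest.raises(ValueError):
            yfp_quench_factor(-1.0, params())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.0, 500.0),
        ec50=st.floats(1.0, 100.0),
        hill=st.floats(0.5, 3.0),
        rq=st.floats(0.0, 0.5),
    )
    def test_bounded_and_decreasing(self, cl, ec50, hill, rq):
        p = params(ec50=ec50, hill=hill, residual_q=rq)
        q = yfp_quench_factor(cl, p)
        assert rq < q <= 1.0
        assert yfp_quench_factor(cl + 1.0, p) < q

    def test_quench_ratio_for_printed_f500_drop(self):
        """The resting/peak chloride pair of the N2a challenge has Q-ratio 0.784.

        Solving Q(cl_peak)/Q(cl_rest) = 1 - 0.216 for cl_peak and pushing
        both concentrations through the F500 channel reproduces the 21.6 %
        drop by construction of the quench model.
        """
        p = params(cl_ref=0.0)
        rest = 8.0
        q_rest = yfp_quench_factor(rest, p)
        peak = brentq(lambda c: yfp_quench_factor(c, p) / q_rest - 0.784, rest, 200)
        s = SensorState()
        f = [emitted_rate(500, c, s, p) for c in (rest, peak)]
        assert 100.0 * (f[0] - f[1]) / f[0] == pytest.approx(21.6, abs=1e-9)


class TestDarkStates:
    def test_zero_duration_is_identity(self):
        s = SensorState(dark_430=0.05)
        ev = IlluminationEvent(430, 0.0, 1.0)
        assert dark_increment(s, ev, params()) == s

    def test_increment_matches_independent_root_find(self):
        """Frozen (f_max, tau) solve the two printed 430 nm inhibition points.

        Independent oracle: brentq on the two-equation system
        f_max (1 - e^(-dose/tau)) = drop for (2.6 %, 20 ms), (30 %, 1 s).
        """
        def mismatch(tau):
            fmax = 0.30 / (1 - math.exp(-1.0 / tau))
            return fmax * (1 - math.exp(-0.02 / tau)) - 0.026

        tau = brentq(mismatch, 1e-3, 100)
        fmax = 0.30 / (1 - math.exp(-1.0 / tau))
        assert configs.FMAX_430 == pytest.approx(fmax, rel=1e-9)
        assert configs.TAU_INACT_430_S == pytest.approx(tau, rel=1e-9)
        s = dark_increment(SensorState(), IlluminationEvent(430, 0.02, 1.0), params())
        assert s.dark_430 == pytest.approx(0.026, abs=1e-9)
        assert s.dark_500 == 0.0

    def test_saturation_at_long_exposure(self):
        p = params()
        s = dark_increment(SensorState(), IlluminationEvent(430, 1e6, 1.0), p)
        assert s.dark_430 == pytest.approx(p.fmax_430, rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(t=st.floats(1e-4, 10.0), i=st.floats(0.01, 1.0),
           d0=st.floats(0.0, 0.2))
    def test_reciprocity_duration_times_intensity(self, t, i, d0):
        p = params()
        s0 = SensorState(dark_430=min(d0, p.fmax_430))
        a = dark_increment(s0, IlluminationEvent(430, t, i), p)
        b = dark_increment(s0, IlluminationEvent(430, t * i, 1.0), p)
        assert a.dark_430 == pytest.approx(b.dark_430, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dose1=st.floats(1e-3, 5.0), dose2=st.floats(1e-3, 5.0))
    def test_monotone_in_cumulative_dose(self, dose1, dose2):
        p = params()
        s1 = dark_increment(SensorState(), IlluminationEvent(430, dose1, 1.0), p)
        s2 = dark_increment(s1, IlluminationEvent(430, dose2, 1.0), p)
        assert s2.dark_430 >= s1.dark_430
        assert s2.dark_430 <= p.fmax_430

    def test_recovery_time_constant(self):
        p = params()
        s = SensorState(dark_430=0.1)
        out = dark_recovery(s, p.tau_rec_430, p)
        assert out.dark_430 == pytest.approx(0.1 / math.e, rel=1e-12)
        assert dark_recovery(s, 0.0, p) == s

    def test_five_minute_interval_gives_full_recovery(self):
        p = params(tau_rec_430=50.0)
        out = dark_recovery(SensorState(dark_430=0.2), 300.0, p)
        assert out.dark_430 / 0.2 < 0.003

    def test_negative_recovery_interval_rejected(self):
        with pytest.raises(ValueError):
            dark_recovery(SensorState(), -1.0, params())

    def test_slow_pool_partitions_increment(self):
        p = params(slow_pool_weight=0.4)
        s = dark_increment(SensorState(), IlluminationEvent(430, 1.0, 1.0), p)
        assert s.dark_430_slow == pytest.approx(s.dark_430 * 0.4 / 0.6, rel=1e-12)
        rec = dark_recovery(s, 100.0, p)
        assert rec.dark_430_slow / s.dark_430_slow > rec.dark_430 / s.dark_430


class TestSteadyState:
    def test_zero_dose_gives_zero(self):
        assert steady_state_dark(IlluminationEvent(430, 0.0, 1.0), 10.0, params()) == 0.0

    def test_closed_form_matches_iteration_on_random_parameters(self, rng):
        """Brute-force oracle: 500 pulse/recover cycles, |closed - iterated| < 1e-8."""
        for _ in range(20):
            p = params(
                fmax_430=rng.uniform(0.05, 0.8),
                tau_inact_430=rng.uniform(0.05, 5.0),
                tau_rec_430=rng.uniform(5.0, 200.0),
            )
            pulse = IlluminationEvent(430, rng.uniform(0.005, 0.5), 1.0)
            interval = rng.uniform(1.0, 60.0)
            s = SensorState()
            for _ in range(500):
                s = dark_increment(s, pulse, p)
                s = dark_recovery(s, interval, p)
            # after the recovery phase == at the onset of the next pulse
            assert steady_state_dark(pulse, interval, p) == pytest.approx(
                s.dark_430, abs=1e-8
            )

    def test_routine_430_protocol_plateau_level(self):
        """20 ms pulses every 10 s settle F430 at 97-98 % of initial."""
        p = params(cl_ref=7.0)
        d = steady_state_dark(IlluminationEvent(430, 0.02, 1.0), 10.0, p)
        f430 = (1 - p.alpha_rest) + p.alpha_rest * (1 - d)
        assert 0.97 <= f430 <= 0.98

    def test_routine_500_protocol_is_stable(self):
        """50 ms / 10 s 500 nm acquisition depresses F500 by < 0.5 % at steady state."""
        p = params()
        d = steady_state_dark(IlluminationEvent(500, 0.05, 1.0), 10.0, p)
        assert d < 0.005

    def test_interval_must_exceed_pulse(self):
        with pytest.raises(ValueError):
            steady_state_dark(IlluminationEvent(430, 11.0, 1.0), 10.0, params())


class TestEmittedSignal:
    def test_zero_expression_gives_background_only(self):
        s = SensorState(expression=0.0)
        ev = IlluminationEvent(500, 0.05, 1.0)
        out = emitted_signal(500, 10.0, s, ev, gain=1e4, background=123.0, p=params())
        assert out == 123.0

    def test_f500_linear_in_dark_survival(self):
        p = params()
        ev = IlluminationEvent(500, 0.05, 1.0)
        base = emitted_signal(500, 10.0, SensorState(), ev, 1e4, 0.0, p)
        d = 0.08
        out = emitted_signal(500, 10.0, SensorState(dark_500=d), ev, 1e4, 0.0, p)
        assert out == pytest.approx(base * (1 - d), rel=1e-12)

    def test_channel_composition_couples_the_printed_drops(self):
        """alpha_rest = 0.062/0.216 maps a 21.6 % F500 drop to 6.2 % in F430."""
        assert configs.ALPHA_REST == pytest.approx(0.062 / 0.216, rel=1e-12)
        rest = 8.0
        p = params(cl_ref=rest)
        q_rest = yfp_quench_factor(rest, p)
        peak = brentq(
            lambda c: yfp_quench_factor(c, p) / q_rest - (1 - 0.216), rest, 200
        )
        s = SensorState()
        f430 = [emitted_rate(430, c, s, p) for c in (rest, peak)]
        drop430 = 100.0 * (f430[0] - f430[1]) / f430[0]
        assert drop430 == pytest.approx(6.2, abs=1e-6)
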