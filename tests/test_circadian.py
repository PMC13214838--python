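"""Process L, oscillator dynamics and phase/amplitude markers."""

import numpy as np
import pytest

from circalux.circadian import (
    CircadianParams,
    CircadianState,
    average_amplitude,
    cbt_min_times,
    dlmo_times,
    light_drive,
    oscillator_derivatives,
    photic_activation,
    process_l_derivative,
    process_l_fixed_point,
)
from circalux.engine import compute_prc, simulate
from circalux.protocols import LightSchedule
from circalux.sleep import SleepParams, SleepState


class TestPhoticActivation:
    def test_darkness_gives_zero(self, default_cparams):
        assert photic_activation(0.0, default_cparams) == 0.0

    def test_half_scale_illuminance_returns_activation_scale(self, default_cparams):
        assert photic_activation(default_cparams.i_0, default_cparams) == pytest.approx(
            default_cparams.alpha_0
        )

    @pytest.mark.parametrize("p", np.linspace(0.5, 0.7, 5))
    def test_strictly_increasing_in_lux(self, p):
        cp = CircadianParams(p=p)
        lux = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])
        vals = [photic_activation(v, cp) for v in lux]
        assert np.all(np.diff(vals) > 0)

    def test_negative_lux_rejected(self, default_cparams):
        with pytest.raises(ValueError):
            photic_activation(-1.0, default_cparams)


class TestProcessL:
    def test_dark_fixed_point(self, default_cparams):
        assert process_l_derivative(CircadianState(n=0.0), 0.0, default_cparams) == 0.0

    def test_pure_decay_in_darkness(self, default_cparams):
        assert process_l_derivative(CircadianState(n=0.5), 0.0, default_cparams) < 0

    @pytest.mark.parametrize("lux", [100.0, 1000.0])
    def test_steady_state_matches_closed_form(self, lux, default_cparams):
        """Long constant-light integration converges to n* = a/(a+b)."""
        n_star = process_l_fixed_point(lux, default_cparams)
        assert 0.0 < n_star <= 1.0
        sched = LightSchedule(np.array([[0.0, 48.0, lux, lux]]), 2, "const")
        inert = SleepParams(mu=1e6, delta=1.0, h_wake_asymptote=1.0, wake_lux_threshold=np.inf)
        res = simulate(sched, default_cparams, inert)
        assert res.n[-1] == pytest.approx(n_star, abs=1e-6)


class TestLightDrive:
    def test_zero_in_darkness(self, default_cparams):
        assert light_drive(CircadianState(0.5, 0.5, 0.2), 0.0, default_cparams) == 0.0

    def test_zero_when_fully_saturated(self, default_cparams):
        assert light_drive(CircadianState(0.5, 0.5, 1.0), 1000.0, default_cparams) == 0.0

    def test_drive_scales_with_unsaturated_fraction(self, default_cparams):
        b_low = light_drive(CircadianState(0.0, 0.0, 0.8), 500.0, default_cparams)
        b_high = light_drive(CircadianState(0.0, 0.0, 0.2), 500.0, default_cparams)
        assert b_high == pytest.approx(4.0 * b_low)


class TestFreeRun:
    @pytest.mark.parametrize("tau", [23.8, 24.1, 24.4])
    def test_dark_period_matches_intrinsic(self, tau, dark_schedule_40d):
        cp = CircadianParams(tau_c=tau)
        res = simulate(dark_schedule_40d, cp, SleepParams(), store_every=5)
        periods = np.diff(res.cbt_min_series[-15:])
        assert np.mean(periods) == pytest.approx(tau, abs=0.05)

    def test_amplitude_independent_of_start(self, dark_schedule_40d, default_cparams):
        sp = SleepParams()
        r1 = simulate(dark_schedule_40d, default_cparams, sp,
                      initial=(CircadianState(-1.0, 0.0, 0.0), SleepState(10.0, False)))
        r2 = simulate(dark_schedule_40d, default_cparams, sp,
                      initial=(CircadianState(0.3, 0.6, 0.0), SleepState(10.0, False)))
        a1 = average_amplitude(r1.t, r1.x, r1.x_c)
        a2 = average_amplitude(r2.t, r2.x, r2.x_c)
        assert a1 == pytest.approx(a2, rel=0.01)


@pytest.fixture(scope="module")
def prc(default_cparams):
    return compute_prc(np.arange(0.0, 24.0, 1.0), cparams=default_cparams)


class TestPhaseResponseCurve:

    def test_morning_advance_evening_delay(self, prc):
        """Light after the x-minimum advances; evening light (midway
        through the subjective day-night, well before the next minimum)
        delays."""
        by_phase = prc.set_index("phase_h_after_cbtmin").shift_h
        assert by_phase.loc[2.0] > 0   # biological morning
        assert by_phase.loc[16.0] < 0  # biological evening
        assert by_phase.loc[19.0] < 0

    def test_sign_change_present(self, prc):
        assert (prc.shift_h > 0).any() and (prc.shift_h < 0).any()

    def test_no_extended_dead_zone(self, prc):
        """|shift| stays away from zero except at isolated crossovers."""
        small = np.abs(prc.shift_h.to_numpy()) < 1.0 / 60.0
        # no two consecutive tested phases may both be null
        assert not np.any(small[:-1] & small[1:])


class TestMarkers:
    def test_cosine_minima_at_expected_times(self):
        t = np.arange(0.0, 72.0, 0.01)
        mins = cbt_min_times(t, np.cos(2 * np.pi * t / 24.0))
        np.testing.assert_allclose(mins, [12.0, 36.0, 60.0], atol=1e-3)

    def test_refinement_agrees_with_dense_argmin(self, equilibration_run):
        _, _, res = equilibration_run
        mins = cbt_min_times(res.t, res.x)
        dt = res.t[1] - res.t[0]
        for lo in (mins[-3] - 12.0, mins[-2] - 12.0):
            mask = (res.t >= lo) & (res.t < lo + 24.0)
            brute = res.t[mask][np.argmin(res.x[mask])]
            nearest = mins[np.argmin(np.abs(mins - brute))]
            assert abs(nearest - brute) <= dt

    def test_entrained_markers_spaced_24h(self, equilibration_run):
        _, _, res = equilibration_run
        diffs = np.diff(res.cbt_min_series[-8:])
        assert np.all(np.abs(diffs - 24.0) < 1.0 / 60.0)

    def test_short_trajectory_gives_empty(self):
        assert len(cbt_min_times(np.array([0.0, 1.0]), np.array([0.0, 1.0]))) == 0

    def test_dlmo_is_cbtmin_minus_seven(self):
        cbt = np.array([29.0, 53.0])  # 05:00 on consecutive days
        np.testing.assert_allclose(dlmo_times(cbt), [22.0, 46.0])
        assert len(dlmo_times(np.array([]))) == 0
        np.testing.assert_allclose(dlmo_times(cbt + 1.0), dlmo_times(cbt) + 1.0)


class TestAverageAmplitude:
    def test_constant_radius(self):
        t = np.linspace(0.0, 48.0, 1000)
        assert average_amplitude(t, np.full_like(t, 3.0), np.zeros_like(t)) == pytest.approx(3.0)

    def test_unit_circle(self):
        t = np.linspace(0.0, 48.0, 5000)
        assert average_amplitude(t, np.cos(t), np.sin(t)) == pytest.approx(1.0)

    def test_trapezoid_agrees_with_fine_riemann(self, equilibration_run):
        _, _, res = equilibration_run
        val = average_amplitude(res.t, res.x, res.x_c)
        mask = res.t >= res.t[-1] - 24.0
        r = np.hypot(res.x[mask], res.x_c[mask])
        riemann = np.sum(0.5 * (r[1:] + r[:-1]) * np.diff(res.t[mask])) / (
            res.t[mask][-1] - res.t[mask][0]
        )
        assert val == pytest.approx(riemann, abs=1e-6)

    def test_window_outside_trajectory_rejected(self):
        t = np.linspace(0.0, 24.0, 100)
        with pytest.raises(ValueError):
            average_amplitude(t, t, t, window=(10.0, 30.0))
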