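"""Outcome metrics: SOL, phase shifts, bedtime/TST, heatmap, actogram,
ensemble summaries."""

import numpy as np
import pandas as pd
import pytest

from circalux.analysis import (
    _wrap_clock_diff_h,
    actogram_raster,
    amplitude_heatmap,
    bedtime_and_tst,
    condition_phase_difference,
    ebook_attributable_shift,
    make_actogram,
    phase_shift,
    scheduled_bedtimes,
    sleep_onset_latency,
    summarize_ensemble,
)
from circalux.circadian import CircadianParams
from circalux.engine import simulate
from circalux.protocols import ConditionOrder, LightSchedule, ProtocolSpec, build_chang_schedule
from circalux.sleep import SleepParams

from conftest import make_fake_result


def test_clock_difference_wraps_at_midnight():
    assert _wrap_clock_diff_h(5.0, 4.5) == pytest.approx(0.5)
    assert _wrap_clock_diff_h(0.5, 23.5) == pytest.approx(1.0)
    assert _wrap_clock_diff_h(23.5, 0.5) == pytest.approx(-1.0)


def test_scheduled_bedtimes_of_chang_protocol():
    sched = build_chang_schedule(ProtocolSpec())
    bts = scheduled_bedtimes(sched)
    assert len(bts) == 14
    np.testing.assert_allclose(bts % 24.0, 22.0)


class TestSleepOnsetLatency:
    def test_definition_from_fake_episodes(self):
        sched = build_chang_schedule(ProtocolSpec())
        eps = [(22.0 + 10.0 / 60.0, 30.0, True), (46.0, 54.0, True)]  # 22:10 then 22:00 sharp
        res = make_fake_result(t_end_h=sched.t_end, episodes=eps,
                               event_times=[t for e in eps for t in e[:2]])
        sol = sleep_onset_latency(res, sched)
        assert sol.sol_min[0] == pytest.approx(10.0)
        assert sol.sol_min[1] == pytest.approx(0.0)
        assert np.isnan(sol.sol_min[2])  # night with no sleep is missing, not zero

    def test_agrees_with_dense_scan_of_sleep_flag(self, equilibration_run, default_cparams, default_sparams):
        cs, ss, _ = equilibration_run
        sched = build_chang_schedule(ProtocolSpec())
        res = simulate(sched, default_cparams, default_sparams, initial=(cs, ss))
        sol = sleep_onset_latency(res, sched).dropna()
        dt_min = (res.t[1] - res.t[0]) * 60.0
        for _, row in sol.iterrows():
            mask = res.t >= row.bedtime_h
            first_asleep = res.t[mask][np.argmax(res.asleep[mask])]
            assert abs(row.onset_h - first_asleep) * 60.0 <= dt_min + 1e-6


class TestPhaseShift:
    def test_zero_for_identical_clock_times(self):
        res = make_fake_result(t_end_h=14 * 24.0, cbt_min=[6 * 24.0 + 4.5, 12 * 24.0 + 4.5])
        assert phase_shift(res, (7, 13)) == pytest.approx(0.0)

    def test_sign_convention_delay_positive(self):
        res = make_fake_result(t_end_h=14 * 24.0, cbt_min=[6 * 24.0 + 4.5, 12 * 24.0 + 5.0])
        assert phase_shift(res, (7, 13)) == pytest.approx(30.0)

    def test_missing_marker_rejected(self):
        res = make_fake_result(t_end_h=14 * 24.0, cbt_min=[6 * 24.0 + 4.5])
        with pytest.raises(ValueError):
            phase_shift(res, (7, 13))

    def test_ebook_shift_sign_flips_with_order(self):
        cbt = [6 * 24.0 + 4.0, 12 * 24.0 + 4.75]
        res = make_fake_result(t_end_h=14 * 24.0, cbt_min=cbt)
        s_ef = ebook_attributable_shift(res, ConditionOrder.EBOOK_FIRST)
        s_bf = ebook_attributable_shift(res, ConditionOrder.BOOK_FIRST)
        assert s_ef == pytest.approx(-45.0)
        assert s_bf == pytest.approx(45.0)
        assert s_ef == -s_bf

    def test_pair_wrapper_requires_matching_parameters(self):
        res_a = make_fake_result(t_end_h=14 * 24.0, cbt_min=[6 * 24.0 + 4.0, 12 * 24.0 + 4.5])
        res_b = make_fake_result(t_end_h=14 * 24.0, cbt_min=[6 * 24.0 + 4.0, 12 * 24.0 + 4.5],
                                 sparams=SleepParams(mu=18.0))
        with pytest.raises(ValueError):
            condition_phase_difference((res_a, res_b))
        out = condition_phase_difference((res_a, res_a))
        assert out["ebook-first"] == -out["book-first"]

    def test_null_protocol_shift_is_order_antisymmetric(
        self, equilibration_run, default_cparams, default_sparams
    ):
        """With identical light in both conditions the two order schedules
        coincide, so the attributed shifts are exactly opposite: any
        residual day-7 vs day-13 difference reflects ongoing entrainment
        into the protocol, not the reading condition."""
        cs, ss, _ = equilibration_run
        shifts = {}
        for order in ConditionOrder:
            spec = ProtocolSpec(ebook_lux=3.0 + 1e-9, order=order)  # both windows ~3 lux
            sched = build_chang_schedule(spec)
            res = simulate(sched, default_cparams, default_sparams, initial=(cs, ss), store_every=5)
            shifts[order] = ebook_attributable_shift(res, order)
        assert shifts[ConditionOrder.EBOOK_FIRST] == pytest.approx(
            -shifts[ConditionOrder.BOOK_FIRST], abs=1e-9
        )


class TestBedtimeAndTst:
    def test_single_episode(self):
        res = make_fake_result(t_end_h=48.0, episodes=[(23.0, 31.0, False)],
                               event_times=[23.0, 31.0])
        bed, tst = bedtime_and_tst(res, 1)
        assert bed == pytest.approx(23.0)
        assert tst == pytest.approx(480.0)

    def test_midnight_crossing_attributed_to_onset_day(self):
        res = make_fake_result(t_end_h=72.0, episodes=[(23.5, 31.0, False)],
                               event_times=[23.5, 31.0])
        bed, tst = bedtime_and_tst(res, 1)
        assert bed == pytest.approx(23.5) and tst == pytest.approx(450.0)
        bed2, tst2 = bedtime_and_tst(res, 2)
        assert np.isnan(bed2) and np.isnan(tst2)

    def test_day_not_simulated_rejected(self):
        res = make_fake_result(t_end_h=48.0)
        with pytest.raises(ValueError):
            bedtime_and_tst(res, 5)

    def test_tst_agrees_with_flag_integration(self, equilibration_run):
        """Event-based TST matches integrating the stored sleep flag from
        the day's first onset to the following day's onset."""
        _, _, res = equilibration_run
        day = 29
        _, tst = bedtime_and_tst(res, day)
        lo = 24.0 * (day - 1)
        onsets = np.array([e.onset_h for e in res.sleep_episodes])
        first = onsets[(onsets >= lo) & (onsets < lo + 24.0)][0]
        nxt = onsets[onsets > first]
        hi = nxt[0] if len(nxt) else res.t[-1]
        mask = (res.t >= first) & (res.t < hi)
        dt_h = res.t[1] - res.t[0]
        integral = np.sum(res.asleep[mask]) * dt_h * 60.0
        assert tst == pytest.approx(integral, abs=2.0 * dt_h * 60.0)


def test_heatmap_cell_composes_single_simulation(default_cparams):
    """A 1x1 amplitude grid equals a direct simulate + average call."""
    from circalux.engine import equilibrate
    from circalux.protocols import build_pulse_schedule
    import warnings

    df = amplitude_heatmap([500.0], [7.0], n_days=6, dt=0.02)
    sp = SleepParams(wake_lux_threshold=np.inf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        initial = equilibrate(default_cparams, SleepParams(), dt=0.02)
    res = simulate(build_pulse_schedule(500.0, 7.0, n_days=6), default_cparams, sp,
                   initial=initial, dt=0.02, store_every=5)
    assert df.loc[500.0, 7.0] == pytest.approx(res.average_amplitude_last_day())


class TestActogram:
    def test_raster_cells_sample_schedule_lux(self, equilibration_run):
        _, _, res = equilibration_run
        from circalux.protocols import build_equilibration_schedule

        sched = build_equilibration_schedule(6.0, 30)
        lux, asleep = actogram_raster(res, sched, bin_h=0.5)
        assert lux.shape == (29, 96)
        d, c = 10, 30  # day 11, 15:00 -> lit
        t_cell = 24.0 * d + (c + 0.5) * 0.5
        assert lux[d, c] == sched.lux(t_cell)

    def test_entrained_sleep_band_is_vertically_aligned(self, equilibration_run):
        _, _, res = equilibration_run
        from circalux.protocols import build_equilibration_schedule

        sched = build_equilibration_schedule(6.0, 30)
        _, asleep = actogram_raster(res, sched, bin_h=0.5)
        onset_cols = np.argmax(asleep[10:28] > 0.5, axis=1)
        assert np.ptp(onset_cols) <= 1

    def test_free_run_band_drifts(self, dark_schedule_40d, default_cparams):
        res = simulate(dark_schedule_40d, default_cparams, SleepParams(), store_every=5)
        onsets = np.array([e.onset_h % 24.0 for e in res.sleep_episodes if e.onset_h > 10 * 24.0])
        drift = np.diff(np.unwrap(onsets, period=24.0))
        assert np.mean(drift) == pytest.approx(0.2, abs=0.1)

    def test_figure_renders(self, equilibration_run):
        _, _, res = equilibration_run
        from circalux.protocols import build_equilibration_schedule

        fig = make_actogram(res, build_equilibration_schedule(6.0, 30))
        assert fig is not None


class TestSummarizeEnsemble:
    def test_single_set_mean_equals_median(self):
        table = pd.DataFrame(
            {"set_id": [0], "condition": ["ebook"], "order": ["ebook-first"], "sol_min": [12.0]}
        )
        summary = summarize_ensemble(table)
        agg = summary.aggregates
        assert agg[("sol_min", "mean")].iloc[0] == agg[("sol_min", "median")].iloc[0] == 12.0

    def test_delta_zero_for_identical_conditions(self):
        table = pd.DataFrame(
            {
                "set_id": [0, 0],
                "condition": ["ebook", "book"],
                "order": ["ebook-first"] * 2,
                "sol_min": [8.0, 8.0],
            }
        )
        assert summarize_ensemble(table).delta_sol_min == 0.0

    def test_median_matches_sorting_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.0, 60.0, 101)
        table = pd.DataFrame({"set_id": np.arange(101), "condition": "ebook", "sol_min": vals})
        med = summarize_ensemble(table).aggregates[("sol_min", "median")].iloc[0]
        assert med == np.sort(vals)[50]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_ensemble(pd.DataFrame())
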