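"""Tests for schedule transforms and the counterfactual scenario runner."""

import numpy as np
import pandas as pd
import pytest

from namdsim import (
    DEFAULT_PARAMETERS,
    InjectionSchedule,
    ScenarioSpec,
    apply_covid_thinning,
    covid_injection_probability,
    delay_loss_curve,
    make_3l_q8w_schedule,
    make_covid_rate_series,
    no_treatment_solution,
    redistribute_with_loading,
    redistribute_without_loading,
    run_scenario,
    shift_delay,
)
from namdsim.scenarios import InjectionRateSeries

M18 = 547.875


# ---------------------------------------------------------------------------
# fixed 3-loading + q8w pattern
# ---------------------------------------------------------------------------

def test_3l_q8w_enumeration_to_month18():
    sch = make_3l_q8w_schedule(M18, dose=0.5)
    assert sch.times.tolist() == [0, 28, 56, 112, 168, 224, 280, 336, 392, 448, 504]
    assert len(sch) == 11
    assert np.all(sch.doses == 0.5)


def test_3l_q8w_short_window_is_loading_only():
    assert make_3l_q8w_schedule(60.0).times.tolist() == [0, 28, 56]


def test_3l_q8w_first_year_count_is_eight():
    sch = make_3l_q8w_schedule(M18)
    assert int((sch.times <= 365.0).sum()) == 8


# ---------------------------------------------------------------------------
# delay shifting
# ---------------------------------------------------------------------------

def test_zero_cap_puts_first_injection_at_day_zero():
    sch = InjectionSchedule.from_arrays([20.0, 60.0, 130.0], 0.5)
    out = shift_delay(sch, delay=20.0, max_delay=0.0)
    assert out.times.tolist() == [0.0, 40.0, 110.0]


def test_delay_within_cap_is_untouched():
    sch = InjectionSchedule.from_arrays([10.0, 40.0], 0.5)
    assert shift_delay(sch, delay=10.0, max_delay=14.0).times.tolist() == [10.0, 40.0]


def test_cap_preserves_gaps_exactly():
    sch = InjectionSchedule.from_arrays([30.0, 75.0, 140.0, 260.0], 0.5)
    out = shift_delay(sch, delay=30.0, max_delay=14.0)
    assert out.times[0] == pytest.approx(14.0)
    assert np.allclose(np.diff(out.times), np.diff(sch.times))
    assert len(out) == len(sch)


def test_first_event_before_stated_delay_rejected():
    sch = InjectionSchedule.from_arrays([5.0, 40.0], 0.5)
    with pytest.raises(ValueError):
        shift_delay(sch, delay=10.0, max_delay=0.0)


# ---------------------------------------------------------------------------
# redistribution
# ---------------------------------------------------------------------------

def test_loading_redistribution_skeleton_without_jitter():
    rng = np.random.default_rng(0)
    sch = InjectionSchedule.from_arrays([0.0, 10.0, 20.0, 30.0, 40.0, 50.0], 0.5)
    out = redistribute_with_loading(sch, M18, rng, loading_sigma=0.0, maint_sigma=0.0)
    step = (M18 - 56.0) / 3.0
    expected = [0.0, 28.0, 56.0, 56.0 + step, 56.0 + 2 * step, M18]
    assert np.allclose(out.times, expected)


def test_redistribution_preserves_injection_count():
    rng = np.random.default_rng(1)
    for k in (1, 2, 3, 5, 9):
        sch = InjectionSchedule.from_arrays(np.linspace(5.0, 400.0, k), 0.5)
        assert len(redistribute_with_loading(sch, M18, rng)) == k
        assert len(redistribute_without_loading(sch, M18)) == k


def test_jitter_sigmas_are_as_configured():
    # first event at day 30 so the clip at t >= 0 never truncates the jitter
    rng = np.random.default_rng(2)
    sch = InjectionSchedule.from_arrays([30.0, 60.0, 90.0, 200.0, 300.0, 400.0], 0.5)
    loading_dev, maint_dev = [], []
    step = (M18 - 86.0) / 3.0
    nominal = np.array([30.0, 58.0, 86.0, 86.0 + step, 86.0 + 2 * step, M18])
    for _ in range(10_000):
        out = redistribute_with_loading(sch, M18, rng)
        dev = np.sort(out.times) - nominal
        loading_dev.extend(dev[:3])
        maint_dev.extend(dev[3:])
    assert np.std(loading_dev) == pytest.approx(4.0, abs=0.15)
    assert np.std(maint_dev) == pytest.approx(7.0, abs=0.25)


def test_no_loading_redistribution_examples():
    one = InjectionSchedule.from_arrays([12.0], 0.5)
    assert redistribute_without_loading(one, 540.0).times.tolist() == [12.0]
    four = InjectionSchedule.from_arrays([0.0, 50.0, 60.0, 70.0], 0.5)
    out = redistribute_without_loading(four, 540.0)
    assert np.allclose(out.times, [0.0, 180.0, 360.0, 540.0])
    gaps = np.diff(out.times)
    assert gaps.max() - gaps.min() < 1e-9


# ---------------------------------------------------------------------------
# pandemic thinning
# ---------------------------------------------------------------------------

def _series(level: float) -> InjectionRateSeries:
    return make_covid_rate_series(
        waves=[{"start": "2020-01-06", "weeks": 60, "level": level}],
        start="2020-01-06",
        end="2021-03-01",
    )


def test_injection_probability_parity_half_and_cap():
    s = make_covid_rate_series(waves=[])
    assert covid_injection_probability(s, "2020-06-01") == 1.0
    assert covid_injection_probability(_series(0.5), "2020-06-01") == 0.5
    over = InjectionRateSeries(
        week_start_dates=pd.date_range("2020-01-06", periods=10, freq="7D"),
        performed=np.full(10, 1200.0),
        reference=1000.0,
    )
    assert covid_injection_probability(over, "2020-02-03") == 1.0


def test_injection_probability_outside_coverage_rejected():
    with pytest.raises(ValueError, match="coverage"):
        covid_injection_probability(_series(0.5), "2019-01-01")


def test_thinning_at_parity_keeps_everything():
    rng = np.random.default_rng(3)
    sch = InjectionSchedule.from_arrays([0.0, 56.0, 112.0], 0.5)
    out = apply_covid_thinning(sch, "2020-02-03", make_covid_rate_series(waves=[]), rng)
    assert out.times.tolist() == sch.times.tolist()


def test_thinning_at_zero_rate_empties_schedule():
    rng = np.random.default_rng(4)
    sch = InjectionSchedule.from_arrays([0.0, 56.0, 112.0], 0.5)
    assert len(apply_covid_thinning(sch, "2020-02-03", _series(0.0), rng)) == 0


def test_thinning_keep_fraction_is_binomial():
    rng = np.random.default_rng(5)
    sch = InjectionSchedule.from_arrays([10.0], 0.5)
    series = _series(0.7)
    kept = sum(
        len(apply_covid_thinning(sch, "2020-02-03", series, rng)) for _ in range(10_000)
    )
    assert kept / 10_000 == pytest.approx(0.7, abs=0.01)


def test_postpone_mode_delays_instead_of_dropping():
    rng = np.random.default_rng(6)
    sch = InjectionSchedule.from_arrays([10.0, 60.0], 0.5)
    out = apply_covid_thinning(sch, "2020-02-03", _series(0.0), rng, postpone_days=28.0)
    assert len(out) == 2
    assert out.times.tolist() == [38.0, 88.0]


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def test_no_treatment_scenario_reduces_to_closed_form(small_cohort, params):
    res = run_scenario(small_cohort, ScenarioSpec(kind="no_treatment"), params)
    ends = np.array([min(p.obs_end, M18) for p in small_cohort.patients])
    expected = np.array(
        [
            no_treatment_solution(p.g0, params, e)
            for p, e in zip(small_cohort.patients, ends)
        ]
    )
    assert np.max(np.abs(res.per_patient_end_va - expected)) < 0.01


def test_unknown_scenario_kind_rejected():
    with pytest.raises(ValueError):
        ScenarioSpec(kind="time_travel")


def test_scenario_runner_is_deterministic(small_cohort, params):
    a = run_scenario(
        small_cohort,
        ScenarioSpec(kind="loading_redistributed"),
        params,
        rng=np.random.default_rng(77),
    )
    b = run_scenario(
        small_cohort,
        ScenarioSpec(kind="loading_redistributed"),
        params,
        rng=np.random.default_rng(77),
    )
    assert np.array_equal(a.per_patient_end_va, b.per_patient_end_va)
    assert np.array_equal(a.mean_curve.mean_gain, b.mean_curve.mean_gain)
    assert a.patient_ids == b.patient_ids


def test_count_conserving_transforms_preserve_counts(small_cohort, params):
    rng = np.random.default_rng(8)
    before = [len(s) for s in small_cohort.schedules]
    for kind in ("zero_delay", "capped_delay", "loading_redistributed", "no_loading_redistributed"):
        from namdsim.scenarios import _transform_schedules

        after = [
            len(s)
            for s in _transform_schedules(
                small_cohort, ScenarioSpec(kind=kind, options={"max_delay": 14.0}), rng
            )
        ]
        assert after == before, kind


def test_harbor_style_population_and_schedule(params):
    res = run_scenario(
        None,
        ScenarioSpec(kind="harbor_style", window_end=12 * 30.4375, options={"n": 150}),
        params,
        rng=np.random.default_rng(9),
    )
    assert len(res.patient_ids) == 150
    # q4w loading then q8w gives a positive first-year mean gain
    assert res.mean_curve.mean_gain[-1] > 0.0


def test_delay_loss_zero_at_zero_and_flattens(small_cohort, params):
    grid = np.arange(0.0, 169.0, 14.0)
    dl = delay_loss_curve(small_cohort, params, grid)
    loss = dl["mean_va_loss"].to_numpy()
    assert loss[0] == pytest.approx(0.0, abs=1e-9)
    assert np.all(np.diff(loss) >= -1e-9)
    # slope flattens for long delays: the late slope is well below the early one
    early_slope = (loss[2] - loss[0]) / (grid[2] - grid[0])
    late_slope = (loss[-1] - loss[-3]) / (grid[-1] - grid[-3])
    assert late_slope < 0.5 * early_slope
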