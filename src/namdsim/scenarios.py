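"""Counterfactual treatment-pattern scenarios and the scenario runner.

Each scenario is a declarative transformation of the observed per-patient
injection schedules (the cohort identity — n, baselines, observation windows
— is never altered), except for the pandemic-thinning and external-trial
scenarios which define their own populations:

- ``as_observed``           the schedules as generated/recorded
- ``no_treatment``          all injections removed (natural course)
- ``fixed_3l_q8w``          3 monthly loading injections then 8-weekly, no delay
- ``zero_delay``            every schedule shifted so the first injection is at day 0
- ``capped_delay``          delay capped at ``max_delay`` days (shift forward)
- ``loading_redistributed`` 3 q4w loading injections then the remaining
                            injections equally spaced to the window end (jittered)
- ``no_loading_redistributed`` all injections after the first equally spaced
- ``covid_thinned``         injections dropped per a weekly performed/reference
                            rate series (pandemic undertreatment)
- ``harbor_style``          external-trial-profile arm: normal age/VA draws,
                            treatment-naive, 3x q4w + q8w to month 12
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import MeanCurve, mean_curve_with_pi
from .model import (
    DAYS_PER_MONTH,
    MONTH18,
    grid_values_at,
    simulate_cohort_grid,
)
from .params import ModelParameters
from .types import InjectionSchedule, PatientBaseline, VATrajectory

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioSpec",
    "ScenarioResult",
    "InjectionRateSeries",
    "make_3l_q8w_schedule",
    "shift_delay",
    "redistribute_with_loading",
    "redistribute_without_loading",
    "covid_injection_probability",
    "apply_covid_thinning",
    "run_scenario",
    "delay_loss_curve",
    "covid_cohort_experiment",
]

SCENARIO_KINDS = (
    "as_observed",
    "no_treatment",
    "fixed_3l_q8w",
    "zero_delay",
    "capped_delay",
    "loading_redistributed",
    "no_loading_redistributed",
    "covid_thinned",
    "harbor_style",
)


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str
    window_end: float = MONTH18
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.window_end <= 0:
            raise ValueError("window_end must be > 0")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    mean_curve: MeanCurve
    per_patient_end_va: np.ndarray
    patient_ids: list
    seed: int | None = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class InjectionRateSeries:
    """Weekly performed injections vs the pre-pandemic reference rate."""

    week_start_dates: object  # pandas DatetimeIndex
    performed: np.ndarray
    reference: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.performed) < 0):
            raise ValueError("performed counts must be >= 0")
        if self.reference <= 0:
            raise ValueError("reference must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start": self.week_start_dates,
                "performed": self.performed,
                "reference": self.reference,
            }
        )


# ---------------------------------------------------------------------------
# schedule transforms
# ---------------------------------------------------------------------------

def make_3l_q8w_schedule(window_end: float, dose: float = 0.5) -> InjectionSchedule:
    """Loading (days 0, 28, 56) then 8-weekly maintenance while <= window_end."""
    if window_end < 56:
        raise ValueError("window_end must be >= 56 d for a full loading phase")
    times = [0.0, 28.0, 56.0]
    t = 112.0
    while t <= window_end:
        times.append(t)
        t += 56.0
    return InjectionSchedule.from_arrays(np.array(times), dose)


def shift_delay(
    schedule: InjectionSchedule, delay: float, max_delay: float
) -> InjectionSchedule:
    """Cap the treatment delay at ``max_delay`` by shifting injections forward.

    The whole schedule is advanced by (delay - max_delay) so the first
    injection lands at ``max_delay``; the number and relative timing of later
    injections is unchanged (the treatment-free gap moves to the end of the
    observation window).
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    if schedule.times[0] < delay - 1e-9:
        raise ValueError(
            f"first injection at {schedule.times[0]:.3f} d is earlier than the "
            f"stated delay {delay:.3f} d"
        )
    if delay <= max_delay:
        return schedule
    return schedule.shifted(-(delay - max_delay))


def redistribute_with_loading(
    schedule: InjectionSchedule,
    window_end: float,
    rng: np.random.Generator,
    loading_sigma: float = 4.0,
    maint_sigma: float = 7.0,
) -> InjectionSchedule:
    """Same injection count, re-timed: 3 q4w loading injections at the
    observed delay, the rest equally spaced to ``window_end``.

    Loading times are jittered with N(0, loading_sigma^2) d, maintenance with
    N(0, maint_sigma^2) d; the result is re-sorted and clipped to t >= 0.
    With fewer than 3 injections all of them become loading-style.
    """
    k = len(schedule)
    if k == 0:
        return schedule
    delay = float(schedule.times[0])
    loading = delay + np.array([0.0, 28.0, 56.0])[: min(k, 3)]
    times = [loading]
    if k > 3:
        m = k - 3
        step = (window_end - (delay + 56.0)) / m
        maint = delay + 56.0 + step * np.arange(1, m + 1)
        times.append(maint)
    times = np.concatenate(times)
    jitter = np.concatenate(
        [
            rng.normal(0.0, loading_sigma, size=min(k, 3)),
            rng.normal(0.0, maint_sigma, size=max(k - 3, 0)),
        ]
    )
    out = np.sort(np.clip(times + jitter, 0.0, None))
    # break exact ties that the clip/sort may create
    out = _strictly_increasing(out)
    return InjectionSchedule.from_arrays(out, schedule.doses)


def redistribute_without_loading(
    schedule: InjectionSchedule, window_end: float
) -> InjectionSchedule:
    """Same count: first injection at the observed delay, the remaining
    injections equally spaced over (delay, window_end]."""
    k = len(schedule)
    if k == 0:
        return schedule
    delay = float(schedule.times[0])
    if k == 1:
        return schedule
    step = (window_end - delay) / (k - 1)
    times = delay + step * np.arange(k)
    return InjectionSchedule.from_arrays(times, schedule.doses)


def _strictly_increasing(times: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    out = times.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


# ---------------------------------------------------------------------------
# pandemic thinning
# ---------------------------------------------------------------------------

def covid_injection_probability(series: InjectionRateSeries, t) -> float:
    """P(injection performed | week of t) = min(performed/reference, 1)."""
    t = pd.Timestamp(t)
    weeks = pd.DatetimeIndex(series.week_start_dates)
    if t < weeks[0] or t >= weeks[-1] + pd.Timedelta(days=7):
        raise ValueError(f"date {t.date()} outside rate-series coverage")
    i = int(weeks.searchsorted(t, side="right")) - 1
    return min(float(series.performed[i]) / series.reference, 1.0)


def apply_covid_thinning(
    schedule: InjectionSchedule,
    baseline_date,
    series: InjectionRateSeries,
    rng: np.random.Generator,
    postpone_days: float | None = None,
) -> InjectionSchedule:
    """Independently keep each injection with the weekly performed-rate
    probability; dates outside the series coverage are at parity (p = 1).

    Missed injections are dropped.  With ``postpone_days`` set (sensitivity
    mode) a missed injection is instead pushed back by that many days once.
    """
    if len(schedule) == 0:
        return schedule
    baseline_date = pd.Timestamp(baseline_date)
    weeks = pd.DatetimeIndex(series.week_start_dates)
    lo, hi = weeks[0], weeks[-1] + pd.Timedelta(days=7)
    kept_times, kept_doses = [], []
    for t_ev, d_ev in schedule.events:
        date = baseline_date + pd.Timedelta(days=float(t_ev))
        p = 1.0 if (date < lo or date >= hi) else covid_injection_probability(series, date)
        if rng.random() < p:
            kept_times.append(t_ev)
            kept_doses.append(d_ev)
        elif postpone_days is not None:
            kept_times.append(t_ev + postpone_days)
            kept_doses.append(d_ev)
    if not kept_times:
        return InjectionSchedule()
    order = np.argsort(kept_times)
    return InjectionSchedule.from_arrays(
        _strictly_increasing(np.asarray(kept_times)[order]),
        np.asarray(kept_doses)[order],
    )


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def _transform_schedules(cohort, spec: ScenarioSpec, rng: np.random.Generator):
    opts = spec.options
    out = []
    for p, s in zip(cohort.patients, cohort.schedules):
        if spec.kind == "as_observed":
            out.append(s)
        elif spec.kind == "no_treatment":
            out.append(InjectionSchedule())
        elif spec.kind == "fixed_3l_q8w":
            out.append(
                make_3l_q8w_schedule(spec.window_end, opts.get("dose", 0.5))
            )
        elif spec.kind == "zero_delay":
            out.append(shift_delay(s, p.delay, 0.0) if len(s) else s)
        elif spec.kind == "capped_delay":
            cap = opts.get("max_delay", 14.0)
            out.append(shift_delay(s, p.delay, cap) if len(s) else s)
        elif spec.kind == "loading_redistributed":
            out.append(
                redistribute_with_loading(
                    s,
                    spec.window_end,
                    rng,
                    loading_sigma=opts.get("loading_sigma", 4.0),
                    maint_sigma=opts.get("maint_sigma", 7.0),
                )
            )
        elif spec.kind == "no_loading_redistributed":
            out.append(redistribute_without_loading(s, spec.window_end))
        else:  # pragma: no cover - guarded by ScenarioSpec
            raise ValueError(f"unsupported transform {spec.kind!r}")
    return out


def run_scenario(
    cohort,
    spec: ScenarioSpec,
    params: ModelParameters,
    rng: np.random.Generator | None = None,
    dt: float = 0.25,
    bin_width: float = DAYS_PER_MONTH,
    clip: bool = False,
) -> ScenarioResult:
    """Transform schedules per the scenario kind, simulate every patient to
    min(obs_end, window_end), and aggregate the mean gain curve."""
    rng = np.random.default_rng(0) if rng is None else rng
    if spec.kind == "harbor_style":
        cohort = _harbor_cohort(spec, rng)
        schedules = cohort.schedules
    elif spec.kind == "covid_thinned":
        raise ValueError(
            "covid_thinned defines its own population; use covid_cohort_experiment"
        )
    else:
        schedules = _transform_schedules(cohort, spec, rng)

    grid, va = simulate_cohort_grid(
        cohort.patients, schedules, params, spec.window_end, dt=dt, clip=clip
    )
    end_times = np.array(
        [min(p.obs_end, spec.window_end) for p in cohort.patients]
    )
    end_va = grid_values_at(grid, va, end_times)

    trajs = []
    for i, p in enumerate(cohort.patients):
        t_max = min(p.obs_end, spec.window_end)
        t_eval = np.arange(0.0, t_max + 1e-9, bin_width)
        trajs.append(
            VATrajectory(
                patient_id=p.patient_id,
                times=t_eval,
                va=np.interp(t_eval, grid, va[i]),
            )
        )
    curve = mean_curve_with_pi(trajs, bin_width=bin_width)
    return ScenarioResult(
        spec=spec,
        mean_curve=curve,
        per_patient_end_va=end_va,
        patient_ids=[p.patient_id for p in cohort.patients],
    )


def _harbor_cohort(spec: ScenarioSpec, rng: np.random.Generator):
    """Simulated external-trial arm: normal draws of age and baseline VA,
    treatment-naive, 3 monthly loading injections then q8w to month 12."""
    from .cohort import Cohort  # local import to avoid cycle

    opts = spec.options
    n = int(opts.get("n", 275))
    age_mean, age_sd = opts.get("age_mean", 78.8), opts.get("age_sd", 8.4)
    va_mean, va_sd = opts.get("va_mean", 54.2), opts.get("va_sd", 13.3)
    month12 = 12 * DAYS_PER_MONTH
    age = np.clip(rng.normal(age_mean, age_sd, size=n), 50.0, None)
    va = np.clip(rng.normal(va_mean, va_sd, size=n), 0.0, 100.0)
    sched = make_3l_q8w_schedule(month12, opts.get("dose", 0.5))
    patients = [
        PatientBaseline(
            patient_id=f"H{i + 1:04d}",
            age=float(age[i]),
            g0=float(va[i]),
            pretreatment="naive",
            delay=0.0,
            obs_end=month12,
        )
        for i in range(n)
    ]
    return Cohort(patients=patients, schedules=[sched] * n)


def delay_loss_curve(
    cohort,
    params: ModelParameters,
    delay_grid,
    dt: float = 0.25,
    window_end: float = MONTH18,
) -> pd.DataFrame:
    """Mean VA loss at month 18 as a function of a uniform treatment delay.

    Every treated patient's schedule is shifted so its first injection falls
    at the grid delay (gaps preserved); loss is the month-18 mean VA at
    delay 0 minus at delay d, reported positive.
    """
    delay_grid = np.asarray(delay_grid, dtype=float)
    if np.any(delay_grid < 0):
        raise ValueError("delays must be >= 0")
    treated = [
        (p, s) for p, s in zip(cohort.patients, cohort.schedules) if len(s) > 0
    ]
    if not treated:
        raise ValueError("no treated patients in cohort")
    patients = [p for p, _ in treated]
    end_times = np.array([min(p.obs_end, window_end) for p in patients])

    def mean_end_va(d):
        shifted = [s.shifted(d - s.times[0]) for _, s in treated]
        grid, va = simulate_cohort_grid(patients, shifted, params, window_end, dt=dt)
        return float(np.mean(grid_values_at(grid, va, end_times)))

    ref = mean_end_va(0.0)
    rows = [
        {"delay_days": float(d), "mean_va_loss": ref - mean_end_va(float(d))}
        for d in delay_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pandemic cohort experiment
# ---------------------------------------------------------------------------

def covid_cohort_experiment(
    profile,
    params: ModelParameters,
    series: InjectionRateSeries,
    rng: np.random.Generator,
    n: int = 4500,
    baseline_window: tuple = ("2019-09-01", "2021-03-01"),
    sim_end: str = "2021-03-01",
    dt: float = 0.25,
) -> pd.DataFrame:
    """Population-scale missed-injection experiment.

    ``n`` treatment-naive patients get baseline dates uniform in
    ``baseline_window`` and regular injection patterns from the cohort
    profile; each injection is then thinned by the weekly rate series.  Each
    patient is simulated with and without thinning until ``sim_end`` and the
    VA difference at the end is the pandemic-attributable loss.

    Returns one row per patient: n_missed, early_miss (a missed injection
    within 30 d of the planned treatment start), va_loss (letters, positive
    = loss), days_observed.
    """
    from .cohort import sample_baselines, sample_injection_pattern

    lo = pd.Timestamp(baseline_window[0])
    hi = pd.Timestamp(baseline_window[1])
    end = pd.Timestamp(sim_end)
    patients = sample_baselines(profile.with_(n_patients=n), rng)
    patients = [replace(p, pretreatment="naive") for p in patients]
    offsets = rng.uniform(0.0, (hi - lo).days, size=n)
    base_dates = [lo + pd.Timedelta(days=float(o)) for o in offsets]
    rows = []
    full_scheds, thin_scheds, sim_patients = [], [], []
    for p, bdate in zip(patients, base_dates):
        horizon = (end - bdate).days
        if horizon <= 1:
            horizon = 1.0
        p = replace(p, obs_end=float(horizon))
        full = sample_injection_pattern(p, profile, rng)
        thin = apply_covid_thinning(full, bdate, series, rng)
        missed = len(full) - len(thin)
        early_miss = False
        if missed and len(full):
            kept = set(np.round(thin.times, 6).tolist())
            start = full.times[0]
            for t_ev in full.times:
                if round(float(t_ev), 6) not in kept and t_ev - start <= 30.0:
                    early_miss = True
                    break
        sim_patients.append(p)
        full_scheds.append(full)
        thin_scheds.append(thin)
        rows.append({"n_missed": missed, "early_miss": early_miss, "days_observed": p.obs_end})

    t_end = max(p.obs_end for p in sim_patients)
    grid, va_full = simulate_cohort_grid(sim_patients, full_scheds, params, t_end, dt=dt)
    _, va_thin = simulate_cohort_grid(sim_patients, thin_scheds, params, t_end, dt=dt)
    end_times = np.array([p.obs_end for p in sim_patients])
    loss = grid_values_at(grid, va_full, end_times) - grid_values_at(
        grid, va_thin, end_times
    )
    out = pd.DataFrame(rows)
    out.insert(0, "patient_id", [p.patient_id for p in sim_patients])
    out["va_loss"] = loss
    return out
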