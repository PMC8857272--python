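"""Synthetic virtual-patient cohorts with a real-world treatment profile.

The generator emulates the covariate and treatment profile of a large German
observational nAMD cohort: baseline VA 52.1 +/- 21.3 letters, age 77.8 +/- 8.2
years, a 73.2/17.4/9.5% treatment-naive / pretreated / possibly-pretreated
mixture, a mean treatment delay of 20.3 d (SD 19.4, 43.7% under 2 weeks,
29.1% over 4 weeks), 4.47 +/- 2.21 injections in the first year, and
retention of 3631 -> 2943 -> 2424 -> 1928 patients at months 0/6/12/18.

Distribution families are package choices: moment-matched truncated normals
for VA and age, a calibrated two-component gamma mixture for the delay, a
negative-binomial first-year injection count with a widening-gap placement
process, and a piecewise-exponential dropout hazard.  Only the published
moments, quantiles and counts are calibration targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model import DAYS_PER_MONTH, MONTH24, simulate_trajectory
from .params import ModelParameters
from .types import InjectionSchedule, PatientBaseline, VAObservation

__all__ = [
    "CohortProfile",
    "DelayTargets",
    "DelayDistribution",
    "OCEAN_PROFILE",
    "Cohort",
    "calibrate_delay_distribution",
    "sample_baselines",
    "sample_dropout",
    "sample_injection_pattern",
    "generate_observations",
    "generate_cohort",
    "make_covid_rate_series",
]


@dataclass(frozen=True)
class DelayTargets:
    """Calibration targets for the treatment-delay distribution (days)."""

    mean: float = 20.3
    sd: float = 19.4
    p_under_14: float = 0.437
    p_over_28: float = 0.291


@dataclass(frozen=True)
class DelayDistribution:
    """Two-component gamma mixture for the diagnosis-to-injection delay.

    Component 1 captures promptly treated patients, component 2 the long
    tail.  ``achieved`` records the fitted moments/quantiles vs targets.
    """

    weight1: float
    shape1: float
    scale1: float
    shape2: float
    scale2: float
    achieved: dict = field(default_factory=dict)
    point_mass_zero: bool = False

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.point_mass_zero:
            return np.zeros(n)
        comp = rng.random(n) < self.weight1
        out = np.where(
            comp,
            rng.gamma(self.shape1, self.scale1, size=n),
            rng.gamma(self.shape2, self.scale2, size=n),
        )
        return out

    def mean(self) -> float:
        if self.point_mass_zero:
            return 0.0
        return (
            self.weight1 * self.shape1 * self.scale1
            + (1 - self.weight1) * self.shape2 * self.scale2
        )

    def sd(self) -> float:
        if self.point_mass_zero:
            return 0.0
        m = self.mean()
        second = self.weight1 * (
            self.shape1 * self.scale1**2 + (self.shape1 * self.scale1) ** 2
        ) + (1 - self.weight1) * (
            self.shape2 * self.scale2**2 + (self.shape2 * self.scale2) ** 2
        )
        return math.sqrt(max(second - m * m, 0.0))

    def cdf(self, x: float) -> float:
        if self.point_mass_zero:
            return 1.0 if x >= 0 else 0.0
        return float(
            self.weight1 * stats.gamma.cdf(x, self.shape1, scale=self.scale1)
            + (1 - self.weight1) * stats.gamma.cdf(x, self.shape2, scale=self.scale2)
        )


@dataclass(frozen=True)
class CohortProfile:
    """Distributional recipe for a synthetic cohort."""

    n_patients: int = 3631
    baseline_va_mean: float = 52.1
    baseline_va_sd: float = 21.3
    va_bounds: tuple = (0.0, 100.0)
    age_mean: float = 77.8
    age_sd: float = 8.2
    age_min: float = 50.0
    pretreatment_mix: tuple = (0.732, 0.174, 0.095)  # naive, pretreated, possibly
    delay_targets: DelayTargets = field(default_factory=DelayTargets)
    injections_per_year_mean: float = 4.47
    injections_per_year_sd: float = 2.21
    retention: tuple = (2943 / 3631, 2424 / 3631, 1928 / 3631)  # months 6/12/18
    dose_mg: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.pretreatment_mix) < 0 or sum(self.pretreatment_mix) <= 0:
            raise ValueError("invalid pretreatment mixture")
        if list(self.retention) != sorted(self.retention, reverse=True):
            raise ValueError("retention fractions must be decreasing")

    @property
    def pretreatment_probs(self) -> np.ndarray:
        mix = np.asarray(self.pretreatment_mix, dtype=float)
        return mix / mix.sum()

    def with_(self, **kwargs) -> "CohortProfile":
        return replace(self, **kwargs)


OCEAN_PROFILE = CohortProfile()


@dataclass
class Cohort:
    """A generated cohort: baselines plus per-patient schedules."""

    patients: list
    schedules: list

    def __len__(self) -> int:
        return len(self.patients)

    def schedule_for(self, patient_id: str) -> InjectionSchedule:
        for p, s in zip(self.patients, self.schedules):
            if p.patient_id == patient_id:
                return s
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# delay distribution calibration
# ---------------------------------------------------------------------------

def calibrate_delay_distribution(targets: DelayTargets = DelayTargets()) -> DelayDistribution:
    """Fit the gamma-mixture delay distribution to the stated targets.

    Minimizes the squared mismatch of {mean, sd, P(<14 d), P(>28 d)} over
    the five mixture parameters.  Raises if the residual exceeds tolerance.
    """
    if targets.mean == 0.0 and targets.sd == 0.0:
        return DelayDistribution(
            1.0, 1.0, 1.0, 1.0, 1.0,
            achieved={"mean": 0.0, "sd": 0.0, "p_under_14": 1.0, "p_over_28": 0.0},
            point_mass_zero=True,
        )
    return _calibrate_delay_cached(
        targets.mean, targets.sd, targets.p_under_14, targets.p_over_28
    )


@lru_cache(maxsize=8)
def _calibrate_delay_cached(mean, sd, p14, p28) -> DelayDistribution:
    # prompt-component shape fixed at 2 so the system is exactly determined
    k1_fixed = 2.0

    def unpack(theta):
        w = 1.0 / (1.0 + math.exp(-theta[0]))
        s1, k2, s2 = np.exp(theta[1:])
        return w, k1_fixed, s1, k2, s2

    def residuals(theta):
        w, k1, s1, k2, s2 = unpack(theta)
        dist = DelayDistribution(w, k1, s1, k2, s2)
        return np.array(
            [
                (dist.mean() - mean) / 1.0,
                (dist.sd() - sd) / 1.0,
                (dist.cdf(14.0) - p14) / 0.005,
                ((1.0 - dist.cdf(28.0)) - p28) / 0.005,
            ]
        )

    # init: prompt component mean ~8 d, tail component mean ~35 d
    theta0 = np.array([0.2, math.log(4.0), math.log(3.5), math.log(10.0)])
    sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=5000)
    w, k1, s1, k2, s2 = unpack(sol.x)
    dist = DelayDistribution(w, k1, s1, k2, s2)
    achieved = {
        "mean": dist.mean(),
        "sd": dist.sd(),
        "p_under_14": dist.cdf(14.0),
        "p_over_28": 1.0 - dist.cdf(28.0),
    }
    ok = (
        abs(achieved["mean"] - mean) < 0.5
        and abs(achieved["sd"] - sd) < 1.0
        and abs(achieved["p_under_14"] - p14) < 0.02
        and abs(achieved["p_over_28"] - p28) < 0.02
    )
    if not ok:
        raise RuntimeError(
            f"delay calibration failed: achieved {achieved} vs targets "
            f"mean={mean}, sd={sd}, p14={p14}, p28={p28}"
        )
    return DelayDistribution(w, k1, s1, k2, s2, achieved=achieved)


# ---------------------------------------------------------------------------
# truncated-normal moment matching
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _match_truncnorm(mean, sd, lo, hi):
    """Parent (mu, sigma) so that the [lo, hi]-truncated normal hits mean/sd."""

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(moments, [mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(np.array(moments(sol.x)))) > 1e-6:
        raise RuntimeError(
            f"infeasible truncated-normal moment match: mean={mean}, sd={sd}, "
            f"bounds=({lo}, {hi})"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _truncnorm_rvs(mean, sd, lo, hi, n, rng):
    mu, sigma = _match_truncnorm(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# sampling operations
# ---------------------------------------------------------------------------

def sample_baselines(
    profile: CohortProfile, rng: np.random.Generator, n: int | None = None
) -> list:
    """Draw ``n`` patient baselines from the profile (obs_end set to 24 mo).

    VA and age come from moment-matched truncated normals, pre-treatment from
    the renormalized mixture, delay from the calibrated gamma mixture.
    """
    n = profile.n_patients if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = profile.va_bounds
    va = _truncnorm_rvs(profile.baseline_va_mean, profile.baseline_va_sd, lo, hi, n, rng)
    age = _truncnorm_rvs(profile.age_mean, profile.age_sd, profile.age_min, np.inf, n, rng)
    status = rng.choice(
        ["naive", "pretreated", "possibly_pretreated"],
        size=n,
        p=profile.pretreatment_probs,
    )
    delay = calibrate_delay_distribution(profile.delay_targets).rvs(n, rng)
    width = len(str(n))
    return [
        PatientBaseline(
            patient_id=f"P{i + 1:0{width}d}",
            age=float(age[i]),
            g0=float(va[i]),
            pretreatment=str(status[i]),
            delay=float(delay[i]),
            obs_end=MONTH24,
        )
        for i in range(n)
    ]


def sample_dropout(
    profile: CohortProfile, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw per-patient observation ends (days) from a piecewise-exponential
    dropout hazard calibrated to the retention targets at months 6/12/18.

    Patients surviving month 18 are completers with obs_end = 24 months.
    """
    s6, s12, s18 = profile.retention
    if not (1.0 >= s6 >= s12 >= s18 > 0.0):
        raise ValueError("infeasible retention targets")
    seg = 6 * DAYS_PER_MONTH
    bounds = np.array([0.0, seg, 2 * seg, 3 * seg])
    surv = np.array([1.0, s6, s12, s18])
    lam = -np.diff(np.log(surv)) / seg  # hazard per segment

    u = rng.random(n)
    obs_end = np.full(n, MONTH24)
    drop = u > s18  # dropout within the 18-month window
    uu = u[drop]
    t = np.empty_like(uu)
    for k in range(3):
        in_seg = (uu <= surv[k]) & (uu > surv[k + 1])
        # invert S(t) = surv[k] * exp(-lam[k] (t - bounds[k])) = u
        t[in_seg] = bounds[k] + np.log(surv[k] / uu[in_seg]) / lam[k]
    obs_end[drop] = t
    return obs_end


def _negbin_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var <= mean:
        # Poisson limit; use a large dispersion parameter
        r = 1e6
    else:
        r = mean * mean / (var - mean)
    p = r / (r + mean)
    return r, p


def sample_injection_pattern(
    patient: PatientBaseline,
    profile: CohortProfile,
    rng: np.random.Generator,
) -> InjectionSchedule:
    """Draw one patient's injection schedule.

    The first injection happens at the patient's delay.  A first-year count
    is drawn from a negative binomial matching the profile mean/SD; the
    events are placed with gaps that start near q4-q6w and widen (or tighten)
    geometrically so the drawn count fits within the first year.  Maintenance
    continues with jittered gaps until obs_end (capped at 24 months).  A
    drawn count of zero yields an empty schedule.
    """
    if patient.obs_end < patient.delay:
        return InjectionSchedule()
    r, p = _negbin_params(profile.injections_per_year_mean, profile.injections_per_year_sd)
    n1 = int(rng.negative_binomial(r, p))
    if n1 == 0:
        return InjectionSchedule()

    delay = patient.delay
    year_end = 365.0
    times = [delay]
    if n1 > 1 and delay < year_end - 14.0:
        span = (year_end - delay) * rng.uniform(0.80, 0.97)
        gap1 = rng.uniform(28.0, 42.0)
        m = n1 - 1

        def total(ratio):
            if abs(ratio - 1.0) < 1e-9:
                return gap1 * m
            return gap1 * (ratio**m - 1.0) / (ratio - 1.0)

        lo_r, hi_r = 0.30, 8.0
        if total(lo_r) > span:
            gaps = np.full(m, span / m)  # squeeze: equal spacing
        elif total(hi_r) < span:
            gaps = gap1 * hi_r ** np.arange(m)
        else:
            ratio = optimize.brentq(lambda rr: total(rr) - span, lo_r, hi_r)
            gaps = gap1 * ratio ** np.arange(m)
        gaps = gaps * np.exp(rng.normal(0.0, 0.12, size=m))
        gaps = gaps * (span / gaps.sum())
        times.extend((delay + np.cumsum(gaps)).tolist())

    # maintenance beyond the first year, widening-gap continuation; the
    # first-year count stays exactly the drawn n1
    horizon = min(patient.obs_end, MONTH24)
    last_gap = times[-1] - times[-2] if len(times) > 1 else 56.0
    t = max(times[-1], year_end)
    while True:
        gap = float(np.clip(last_gap * math.exp(rng.normal(0.05, 0.15)), 28.0, 240.0))
        t = t + gap
        if t > horizon or t > MONTH24:
            break
        times.append(t)
        last_gap = gap

    times = [t for t in times if t <= horizon]
    if not times:
        return InjectionSchedule()
    return InjectionSchedule.from_arrays(np.array(times), profile.dose_mg)


def generate_observations(
    patient: PatientBaseline,
    schedule: InjectionSchedule,
    params: ModelParameters,
    visit_times: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator,
) -> list:
    """Noisy VA measurements at clinic visits.

    The model trajectory is evaluated at the visit times (a t=0 visit is
    always included), i.i.d. Gaussian noise of ``noise_sd`` letters is added
    and the result clipped to [0, 100].
    """
    visit_times = np.asarray(visit_times, dtype=float)
    visit_times = visit_times[(visit_times >= 0) & (visit_times <= patient.obs_end)]
    visit_times = np.unique(np.concatenate([[0.0], visit_times]))
    traj = simulate_trajectory(patient, schedule, params, visit_times)
    noisy = traj.va + rng.normal(0.0, noise_sd, size=len(visit_times)) if noise_sd > 0 else traj.va.copy()
    noisy = np.clip(noisy, 0.0, 100.0)
    return [
        VAObservation(patient_id=patient.patient_id, time=float(t), va=float(v))
        for t, v in zip(visit_times, noisy)
    ]


def monthly_visit_times(obs_end: float) -> np.ndarray:
    """Default visit grid: monthly from baseline to obs_end."""
    return np.arange(0.0, obs_end + 1e-9, DAYS_PER_MONTH)


def generate_cohort(
    profile: CohortProfile,
    rng: np.random.Generator,
    n: int | None = None,
    with_dropout: bool = True,
) -> Cohort:
    """Full cohort draw: baselines, dropout-censored windows, schedules."""
    patients = sample_baselines(profile, rng, n)
    if with_dropout:
        obs_end = sample_dropout(profile, rng, len(patients))
        patients = [replace(p, obs_end=float(e)) for p, e in zip(patients, obs_end)]
    schedules = [sample_injection_pattern(p, profile, rng) for p in patients]
    return Cohort(patients=patients, schedules=schedules)


# ---------------------------------------------------------------------------
# synthetic weekly injection-rate series (pandemic scenario input)
# ---------------------------------------------------------------------------

def make_covid_rate_series(
    waves: Sequence[dict] | None = None,
    start: str = "2020-01-01",
    end: str = "2021-03-01",
    reference: float = 1000.0,
):
    """Weekly performed-injection series at parity except during dip waves.

    Each wave is a dict with keys ``start`` (ISO date), ``weeks`` (duration)
    and ``level`` (fraction of the pre-pandemic rate, in [0, 1]).  The
    default emulates a shallow but long first wave and a deeper, shorter
    second wave.  Returns an :class:`~namdsim.scenarios.InjectionRateSeries`.
    """
    from .scenarios import InjectionRateSeries  # local import to avoid cycle
    import pandas as pd

    if waves is None:
        waves = [
            {"start": "2020-03-16", "weeks": 12, "level": 0.75},
            {"start": "2020-12-14", "weeks": 5, "level": 0.55},
        ]
    week_starts = pd.date_range(start=start, end=end, freq="7D")
    performed = np.full(len(week_starts), reference)
    covered = np.zeros(len(week_starts), dtype=bool)
    for wave in waves:
        if not (0.0 <= wave["level"] <= 1.0):
            raise ValueError("wave level must be in [0, 1]")
        w0 = pd.Timestamp(wave["start"])
        mask = (week_starts >= w0) & (week_starts < w0 + pd.Timedelta(days=7 * wave["weeks"]))
        if np.any(covered & np.asarray(mask)):
            raise ValueError("overlapping waves")
        covered |= np.asarray(mask)
        performed[np.asarray(mask)] = reference * wave["level"]
    return InjectionRateSeries(
        week_start_dates=week_starts, performed=performed, reference=reference
    )
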