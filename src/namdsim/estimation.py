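"""Least-squares calibration and goodness-of-fit machinery.

The model is calibrated by ordinary (unweighted) least squares on all VA
observations simultaneously.  Positive parameters are optimized on the log
scale (which also guarantees the returned parameters satisfy their domain
invariants), the pre-treatment scaling on the logit scale.  A short
Nelder-Mead pre-pass is followed by a trust-region least-squares refinement;
a configurable number of multi-starts jittered around the initial point
(fixed seed) guards against local minima.

Goodness of fit follows the study design: mean VA-gain curves in monthly
bins with normal-approximation 95% intervals for the mean, adjusted R^2
between predicted and observed mean curves, and a sweep of adjusted R^2
versus sample size (draws without replacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import DAYS_PER_MONTH, grid_values_at, simulate_cohort_grid
from .params import ModelParameters
from .types import VAObservation

__all__ = [
    "FitConfig",
    "FitResult",
    "MeanCurve",
    "observations_frame",
    "residual_vector",
    "fit_parameters",
    "mean_curve_with_pi",
    "adjusted_r2",
    "r2_vs_sample_size",
]

#: Parameters estimated by default; ec50 is fixed (weakly identified jointly
#: with the Emax parameters under a single dose level).
DEFAULT_ESTIMATED = (
    "g_ss",
    "k_out",
    "emax0_ss",
    "d_emax0",
    "k_emax",
    "beta",
    "alpha_pretreated",
)

_LOG_SCALE = {"g_ss", "k_out", "ec50", "emax0_ss", "d_emax0", "k_emax"}
_LOGIT_SCALE = {"alpha_pretreated"}


@dataclass(frozen=True)
class FitConfig:
    estimate: tuple = DEFAULT_ESTIMATED
    n_starts: int = 5
    jitter: float = 0.2
    seed: int = 0
    dt: float = 0.25
    nm_maxiter: int = 150
    max_nfev: int = 400

    def __post_init__(self) -> None:
        if len(self.estimate) > 8:
            raise ValueError("at most 8 parameters can be estimated")
        unknown = set(self.estimate) - (_LOG_SCALE | _LOGIT_SCALE | {"beta"})
        if unknown:
            raise ValueError(f"cannot estimate parameters: {sorted(unknown)}")


@dataclass
class FitResult:
    params: ModelParameters
    sse: float
    n_obs: int
    converged: bool
    n_params_estimated: int
    n_starts: int = 1
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "sse": self.sse,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_params_estimated": self.n_params_estimated,
            "n_starts": self.n_starts,
            "warnings": list(self.warnings),
        }


@dataclass
class MeanCurve:
    """Mean VA gain from baseline per time bin, with 95% PI for the mean."""

    times: np.ndarray
    mean_gain: np.ndarray
    pi_low: np.ndarray
    pi_high: np.ndarray
    n_at_time: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "mean_gain": self.mean_gain,
                "pi_low": self.pi_low,
                "pi_high": self.pi_high,
                "n": self.n_at_time,
            }
        )

    def at_time(self, t: float) -> float:
        """Mean gain at the bin nearest to ``t``."""
        return float(self.mean_gain[np.argmin(np.abs(self.times - t))])


# ---------------------------------------------------------------------------
# observations plumbing
# ---------------------------------------------------------------------------

def observations_frame(observations) -> pd.DataFrame:
    """Normalize observations to a (patient_id, time_days, va_letters) frame."""
    if isinstance(observations, pd.DataFrame):
        df = observations.rename(
            columns={"time": "time_days", "va": "va_letters"}
        )[["patient_id", "time_days", "va_letters"]].copy()
    else:
        df = pd.DataFrame(
            {
                "patient_id": [o.patient_id for o in observations],
                "time_days": [o.time for o in observations],
                "va_letters": [o.va for o in observations],
            }
        )
    return df.sort_values(["patient_id", "time_days"], kind="mergesort").reset_index(
        drop=True
    )


def residual_vector(
    params: ModelParameters,
    patients,
    schedules,
    observations,
    dt: float = 0.25,
) -> np.ndarray:
    """Observed minus model-predicted VA, one entry per observation.

    Deterministic order: sorted by patient_id, then time.  ``schedules`` is
    a mapping patient_id -> InjectionSchedule or a list aligned to patients.
    """
    df = observations_frame(observations)
    sched_map = _schedule_map(patients, schedules)
    known = {p.patient_id for p in patients}
    orphans = sorted(set(df["patient_id"]) - known)
    if orphans:
        raise ValueError(f"observations for unknown patients: {orphans}")

    order = sorted(patients, key=lambda p: p.patient_id)
    t_end = float(df["time_days"].max())
    grid, va = simulate_cohort_grid(
        order, [sched_map[p.patient_id] for p in order], params, max(t_end, dt), dt=dt
    )
    row = {p.patient_id: i for i, p in enumerate(order)}
    rows = df["patient_id"].map(row).to_numpy()
    times = df["time_days"].to_numpy()
    idx = np.clip(np.searchsorted(grid, times), 1, len(grid) - 1)
    w = (times - grid[idx - 1]) / (grid[idx] - grid[idx - 1])
    pred = va[rows, idx - 1] * (1 - w) + va[rows, idx] * w
    return df["va_letters"].to_numpy() - pred


def _schedule_map(patients, schedules) -> dict:
    if isinstance(schedules, dict):
        return schedules
    return {p.patient_id: s for p, s in zip(patients, schedules)}


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def _to_theta(params: ModelParameters, names) -> np.ndarray:
    out = []
    for name in names:
        v = getattr(params, name)
        if name in _LOG_SCALE:
            out.append(math.log(max(v, 1e-12)))
        elif name in _LOGIT_SCALE:
            v = min(max(v, 1e-6), 1 - 1e-6)
            out.append(math.log(v / (1 - v)))
        else:
            out.append(v)
    return np.array(out)


def _from_theta(theta: np.ndarray, names, base: ModelParameters) -> ModelParameters:
    kwargs = {}
    for name, x in zip(names, theta):
        if name in _LOG_SCALE:
            kwargs[name] = math.exp(x)
        elif name in _LOGIT_SCALE:
            kwargs[name] = 1.0 / (1.0 + math.exp(-x))
        else:
            kwargs[name] = x
    return base.with_(**kwargs)


def fit_parameters(
    patients,
    schedules,
    observations,
    init: ModelParameters,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Calibrate the model by ordinary least squares on all observations.

    ``k_drug`` is always held fixed.  Deterministic given data, ``init`` and
    the config seed.  Returns the best parameters across multi-starts with
    convergence diagnostics; if no start converges the best-so-far point is
    returned with ``converged=False``.
    """
    names = list(config.estimate)
    df = observations_frame(observations)
    n_obs = len(df)
    if n_obs < len(names):
        raise ValueError("need at least one observation per estimated parameter")
    sched_map = _schedule_map(patients, schedules)

    def resid(theta):
        try:
            p = _from_theta(theta, names, init)
        except (ValueError, OverflowError):
            return np.full(n_obs, 1e6)
        return residual_vector(p, patients, sched_map, df, dt=config.dt)

    def sse(theta):
        r = resid(theta)
        return float(r @ r)

    theta0 = _to_theta(init, names)
    sse0 = sse(theta0)
    rng = np.random.default_rng(config.seed)
    starts = [theta0] + [
        theta0 + rng.normal(0.0, config.jitter, size=len(theta0))
        for _ in range(max(config.n_starts - 1, 0))
    ]

    best_theta, best_sse, best_res = theta0, sse0, None
    for theta_start in starts:
        nm = optimize.minimize(
            sse,
            theta_start,
            method="Nelder-Mead",
            options={"maxiter": config.nm_maxiter, "xatol": 1e-4, "fatol": 1e-4},
        )
        ls = optimize.least_squares(
            resid, nm.x, method="trf", max_nfev=config.max_nfev, xtol=1e-10
        )
        s = float(ls.cost * 2.0)
        if s < best_sse:
            best_theta, best_sse, best_res = ls.x, s, ls

    converged = best_res is not None and best_res.status > 0
    warnings: list = []
    if best_res is not None:
        jac = best_res.jac
        sv = np.linalg.svd(jac, compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        if cond > 1e8:
            warnings.append(
                f"near-singular information matrix (condition number {cond:.2e}); "
                "some parameters are not identified by these data"
            )
    params = _from_theta(best_theta, names, init)
    return FitResult(
        params=params,
        sse=min(best_sse, sse0),
        n_obs=n_obs,
        converged=bool(converged),
        n_params_estimated=len(names),
        n_starts=len(starts),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def mean_curve_with_pi(
    data,
    bin_width: float = DAYS_PER_MONTH,
    level: float = 0.95,
) -> MeanCurve:
    """Mean VA gain from baseline per time bin with a normal-approximation
    interval for the mean (mean +/- z * sd / sqrt(n)).

    ``data`` may be a list of :class:`VATrajectory`, a list of
    :class:`VAObservation`, or an observations DataFrame.  Each patient's
    baseline is their value at t = 0 (required).  Patients contribute to a
    bin only while under observation; empty bins are dropped.
    """
    if isinstance(data, pd.DataFrame):
        df = observations_frame(data)
    elif len(data) and isinstance(data[0], VAObservation):
        df = observations_frame(data)
    else:  # trajectories
        df = pd.concat(
            [
                pd.DataFrame(
                    {"patient_id": tr.patient_id, "time_days": tr.times, "va_letters": tr.va}
                )
                for tr in data
            ],
            ignore_index=True,
        )
    base = (
        df[df["time_days"] == 0.0].set_index("patient_id")["va_letters"]
    )
    missing = set(df["patient_id"]) - set(base.index)
    if missing:
        raise ValueError(f"patients without a t=0 value: {sorted(missing)[:5]} ...")
    gain = df["va_letters"].to_numpy() - base.loc[df["patient_id"]].to_numpy()
    bin_idx = np.round(df["time_days"].to_numpy() / bin_width).astype(int)
    g = pd.DataFrame({"bin": bin_idx, "gain": gain}).groupby("bin")["gain"]
    mean = g.mean()
    sd = g.std(ddof=1).fillna(0.0)
    n = g.count()
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * sd.to_numpy() / np.sqrt(n.to_numpy())
    return MeanCurve(
        times=mean.index.to_numpy() * bin_width,
        mean_gain=mean.to_numpy(),
        pi_low=mean.to_numpy() - half,
        pi_high=mean.to_numpy() + half,
        n_at_time=n.to_numpy(),
    )


def adjusted_r2(observed: MeanCurve, predicted: MeanCurve, n_params: int) -> float:
    """Adjusted R^2 of the predicted vs observed mean-gain curves.

    R^2 = 1 - SS_res / SS_tot over the common bins, adjusted as
    1 - (1 - R^2)(n - 1)/(n - p - 1) with n bins and p model parameters.
    """
    common, io, ip = np.intersect1d(
        np.round(observed.times, 6), np.round(predicted.times, 6), return_indices=True
    )
    n = len(common)
    if n < n_params + 2:
        raise ValueError(
            f"need at least n_params + 2 = {n_params + 2} common bins, got {n}"
        )
    obs = observed.mean_gain[io]
    pred = predicted.mean_gain[ip]
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def r2_vs_sample_size(
    cohort,
    observations,
    params: ModelParameters,
    sample_sizes,
    rng: np.random.Generator,
    draws_per_size: int = 30,
    n_params: int = len(DEFAULT_ESTIMATED),
    dt: float = 0.25,
) -> pd.DataFrame:
    """Adjusted R^2 between model-predicted and noisy observed mean curves
    as a function of sample size (draws without replacement).

    Returns a frame with columns n, mean_adj_r2, pi_low, pi_high (empirical
    2.5/97.5 percentiles over ``draws_per_size`` draws).
    """
    df = observations_frame(observations)
    ids = np.array(sorted({p.patient_id for p in cohort.patients}))
    order = sorted(cohort.patients, key=lambda p: p.patient_id)
    sched = _schedule_map(cohort.patients, cohort.schedules)

    # model prediction at every observation time (noise-free)
    t_end = float(df["time_days"].max())
    grid, va = simulate_cohort_grid(
        order, [sched[p.patient_id] for p in order], params, max(t_end, dt), dt=dt
    )
    row = {p.patient_id: i for i, p in enumerate(order)}
    rows = df["patient_id"].map(row).to_numpy()
    times = df["time_days"].to_numpy()
    idx = np.clip(np.searchsorted(grid, times), 1, len(grid) - 1)
    w = (times - grid[idx - 1]) / (grid[idx] - grid[idx - 1])
    pred_df = df.copy()
    pred_df["va_letters"] = va[rows, idx - 1] * (1 - w) + va[rows, idx] * w

    out = []
    for size in sample_sizes:
        size = int(size)
        if size > len(ids):
            raise ValueError(f"sample size {size} exceeds cohort size {len(ids)}")
        n_draws = 1 if size == len(ids) else draws_per_size
        vals = []
        for _ in range(n_draws):
            chosen = set(rng.choice(ids, size=size, replace=False).tolist())
            mask = df["patient_id"].isin(chosen).to_numpy()
            obs_curve = mean_curve_with_pi(df[mask])
            pred_curve = mean_curve_with_pi(pred_df[mask])
            vals.append(adjusted_r2(obs_curve, pred_curve, n_params))
        vals = np.array(vals)
        out.append(
            {
                "n": size,
                "mean_adj_r2": vals.mean(),
                "pi_low": np.percentile(vals, 2.5),
                "pi_high": np.percentile(vals, 97.5),
            }
        )
    return pd.DataFrame(out)
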