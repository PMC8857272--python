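"""CSV/JSON/YAML interchange for cohorts, schedules, observations and results.

All tabular files are plain CSV.  Files written by the pipeline carry a
provenance header comment (config hash + seed); readers skip ``#`` lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortProfile, DelayTargets
from .types import InjectionSchedule, PatientBaseline, VAObservation

__all__ = [
    "patients_to_frame",
    "patients_from_frame",
    "schedules_to_frame",
    "schedules_from_frame",
    "observations_to_frame",
    "observations_from_frame",
    "write_cohort",
    "read_cohort",
    "write_csv",
    "read_csv",
    "profile_to_yaml",
    "profile_from_yaml",
]


def write_csv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    # round_trip parsing so exported cohorts re-import bit-identically
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# -- patients ---------------------------------------------------------------

def patients_to_frame(patients) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "baseline_va": [p.g0 for p in patients],
            "pretreatment": [p.pretreatment for p in patients],
            "delay_days": [p.delay for p in patients],
            "obs_end_days": [p.obs_end for p in patients],
        }
    )


def patients_from_frame(df: pd.DataFrame) -> list:
    return [
        PatientBaseline(
            patient_id=str(r.patient_id),
            age=float(r.age),
            g0=float(r.baseline_va),
            pretreatment=str(r.pretreatment),
            delay=float(r.delay_days),
            obs_end=float(r.obs_end_days),
        )
        for r in df.itertuples()
    ]


# -- schedules --------------------------------------------------------------

def schedules_to_frame(patients, schedules) -> pd.DataFrame:
    rows = []
    for p, s in zip(patients, schedules):
        for t, d in s.events:
            rows.append({"patient_id": p.patient_id, "time_days": t, "dose_mg": d})
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "dose_mg"])


def schedules_from_frame(df: pd.DataFrame, patient_ids) -> list:
    out = []
    grouped = dict(tuple(df.groupby("patient_id"))) if len(df) else {}
    for pid in patient_ids:
        g = grouped.get(pid)
        if g is None or len(g) == 0:
            out.append(InjectionSchedule())
        else:
            g = g.sort_values("time_days")
            out.append(
                InjectionSchedule.from_arrays(
                    g["time_days"].to_numpy(), g["dose_mg"].to_numpy()
                )
            )
    return out


# -- observations -----------------------------------------------------------

def observations_to_frame(observations) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in observations],
            "time_days": [o.time for o in observations],
            "va_letters": [o.va for o in observations],
        }
    )


def observations_from_frame(df: pd.DataFrame) -> list:
    return [
        VAObservation(
            patient_id=str(r.patient_id), time=float(r.time_days), va=float(r.va_letters)
        )
        for r in df.itertuples()
    ]


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    return pd.concat(
        [
            pd.DataFrame(
                {"patient_id": tr.patient_id, "time_days": tr.times, "va_letters": tr.va}
            )
            for tr in trajectories
        ],
        ignore_index=True,
    )


# -- cohort bundles ---------------------------------------------------------

def write_cohort(
    cohort: Cohort,
    out_dir,
    observations=None,
    header_lines: list[str] | None = None,
) -> dict:
    """Write patients.csv + schedules.csv (+ observations.csv); returns paths."""
    out_dir = Path(out_dir)
    paths = {
        "patients": out_dir / "patients.csv",
        "schedules": out_dir / "schedules.csv",
    }
    write_csv(patients_to_frame(cohort.patients), paths["patients"], header_lines)
    write_csv(
        schedules_to_frame(cohort.patients, cohort.schedules),
        paths["schedules"],
        header_lines,
    )
    if observations is not None:
        paths["observations"] = out_dir / "observations.csv"
        obs_df = (
            observations
            if isinstance(observations, pd.DataFrame)
            else observations_to_frame(observations)
        )
        write_csv(obs_df, paths["observations"], header_lines)
    return paths


def read_cohort(in_dir) -> tuple[Cohort, pd.DataFrame | None]:
    in_dir = Path(in_dir)
    patients = patients_from_frame(read_csv(in_dir / "patients.csv"))
    schedules = schedules_from_frame(
        read_csv(in_dir / "schedules.csv"), [p.patient_id for p in patients]
    )
    obs_path = in_dir / "observations.csv"
    observations = read_csv(obs_path) if obs_path.exists() else None
    return Cohort(patients=patients, schedules=schedules), observations


# -- profile ----------------------------------------------------------------

def profile_to_yaml(profile: CohortProfile, path) -> None:
    d = {
        "n_patients": profile.n_patients,
        "baseline_va": {"mean": profile.baseline_va_mean, "sd": profile.baseline_va_sd},
        "age": {"mean": profile.age_mean, "sd": profile.age_sd, "min": profile.age_min},
        "pretreatment_mix": list(profile.pretreatment_mix),
        "delay": {
            "mean": profile.delay_targets.mean,
            "sd": profile.delay_targets.sd,
            "p_under_14": profile.delay_targets.p_under_14,
            "p_over_28": profile.delay_targets.p_over_28,
        },
        "injections_per_year": {
            "mean": profile.injections_per_year_mean,
            "sd": profile.injections_per_year_sd,
        },
        "retention": list(profile.retention),
        "dose_mg": profile.dose_mg,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def profile_from_yaml(path) -> CohortProfile:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return CohortProfile(
        n_patients=int(d["n_patients"]),
        baseline_va_mean=float(d["baseline_va"]["mean"]),
        baseline_va_sd=float(d["baseline_va"]["sd"]),
        age_mean=float(d["age"]["mean"]),
        age_sd=float(d["age"]["sd"]),
        age_min=float(d["age"].get("min", 50.0)),
        pretreatment_mix=tuple(d["pretreatment_mix"]),
        delay_targets=DelayTargets(
            mean=float(d["delay"]["mean"]),
            sd=float(d["delay"]["sd"]),
            p_under_14=float(d["delay"]["p_under_14"]),
            p_over_28=float(d["delay"]["p_over_28"]),
        ),
        injections_per_year_mean=float(d["injections_per_year"]["mean"]),
        injections_per_year_sd=float(d["injections_per_year"]["sd"]),
        retention=tuple(d["retention"]),
        dose_mg=float(d["dose_mg"]),
    )


def rate_series_to_csv(series, path, header_lines=None) -> None:
    write_csv(series.to_frame(), path, header_lines)


def rate_series_from_csv(path):
    from .scenarios import InjectionRateSeries

    df = read_csv(path)
    return InjectionRateSeries(
        week_start_dates=pd.DatetimeIndex(pd.to_datetime(df["week_start"])),
        performed=df["performed"].to_numpy(dtype=float),
        reference=float(df["reference"].iloc[0]),
    )
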