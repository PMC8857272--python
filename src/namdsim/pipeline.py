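"""Configuration-driven pipeline: cohort -> (fit) -> scenarios -> report CSVs.

The YAML run configuration looks like::

    seed: 1
    cohort:
      source: profile          # or: csv
      n_patients: 2000         # profile mode
      path: results/cohort     # csv mode (dir with patients/schedules[/observations].csv)
    params:
      source: defaults         # or: json (path:), or: fit
      path: params.json
    scenarios:
      - {kind: as_observed}
      - {kind: no_treatment}
      - {kind: fixed_3l_q8w}
    delay_loss_grid: [0, 7, 14, 28, 56]   # optional
    covid:                                 # optional pandemic experiment
      n_patients: 4500
    output_dir: results/run
    report: {bin_width: 30.4375, pi_level: 0.95, clip: false}

Every CSV written carries a header comment with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cohort import OCEAN_PROFILE, generate_cohort, make_covid_rate_series, monthly_visit_times, generate_observations
from .estimation import FitConfig, fit_parameters, observations_frame
from .model import DAYS_PER_MONTH, MONTH18
from .params import DEFAULT_PARAMETERS, ModelParameters
from .scenarios import ScenarioSpec, covid_cohort_experiment, delay_loss_curve, run_scenario

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("namdsim")


@dataclass
class RunConfig:
    seed: int
    scenarios: list
    output_dir: str
    cohort: dict = field(default_factory=lambda: {"source": "profile", "n_patients": 2000})
    params: dict = field(default_factory=lambda: {"source": "defaults"})
    delay_loss_grid: list | None = None
    covid: dict | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        for s in self.scenarios:
            ScenarioSpec(kind=s["kind"], options=s.get("options", {}))
        if self.cohort.get("source") not in ("profile", "csv"):
            raise ValueError("cohort.source must be 'profile' or 'csv'")
        if self.params.get("source") not in ("defaults", "json", "fit"):
            raise ValueError("params.source must be 'defaults', 'json' or 'fit'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            seed=d.get("seed"),
            scenarios=d.get("scenarios", []),
            output_dir=d.get("output_dir", "results/run"),
            cohort=d.get("cohort", {"source": "profile", "n_patients": 2000}),
            params=d.get("params", {"source": "defaults"}),
            delay_loss_grid=d.get("delay_loss_grid"),
            covid=d.get("covid"),
            report=d.get("report", {}),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scenarios": self.scenarios,
            "output_dir": self.output_dir,
            "cohort": self.cohort,
            "params": self.params,
            "delay_loss_grid": self.delay_loss_grid,
            "covid": self.covid,
            "report": self.report,
        }

    def hash(self) -> str:
        # output_dir is run metadata, not content: identical configs written
        # to different directories must produce identical artifacts
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _resolve_cohort(config: RunConfig, rng: np.random.Generator):
    src = config.cohort
    if src["source"] == "csv":
        path = Path(src["path"])
        if not path.exists():
            raise FileNotFoundError(f"cohort path does not exist: {path}")
        return nio.read_cohort(path)
    profile = OCEAN_PROFILE.with_(n_patients=int(src.get("n_patients", 2000)))
    cohort = generate_cohort(profile, rng)
    return cohort, None


def _resolve_params(config: RunConfig, cohort, observations, rng) -> tuple[ModelParameters, dict | None]:
    src = config.params
    if src["source"] == "defaults":
        return DEFAULT_PARAMETERS, None
    if src["source"] == "json":
        path = Path(src["path"])
        if not path.exists():
            raise FileNotFoundError(f"params file does not exist: {path}")
        return ModelParameters.from_json(path), None
    # fit: needs observations; synthesize them at defaults if absent
    if observations is None:
        obs = []
        for p, s in zip(cohort.patients, cohort.schedules):
            obs.extend(
                generate_observations(
                    p, s, DEFAULT_PARAMETERS, monthly_visit_times(p.obs_end), 5.0, rng
                )
            )
        observations = observations_frame(obs)
    fit = fit_parameters(
        cohort.patients,
        cohort.schedules,
        observations,
        init=DEFAULT_PARAMETERS,
        config=FitConfig(seed=int(config.seed)),
    )
    return fit.params, fit.to_dict()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured pipeline; returns a dict of written artifact paths.

    On failure, files already written for this run are removed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.hash()}", f"seed={config.seed}"]
    written: list[Path] = []

    fh = logging.FileHandler(out_dir / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        log.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))
        rng = np.random.default_rng(config.seed)
        cohort, observations = _resolve_cohort(config, rng)
        log.info("cohort: %d patients", len(cohort))
        params, fit_info = _resolve_params(config, cohort, observations, rng)
        if fit_info is not None:
            p = out_dir / "fit.json"
            with open(p, "w") as f:
                json.dump({**fit_info, "seed": config.seed, "config_hash": config.hash()}, f, indent=2)
            written.append(p)

        bin_width = float(config.report.get("bin_width", DAYS_PER_MONTH))
        months = [3, 6, 12, 18]
        comparison_rows = []
        paths = {}
        for s in config.scenarios:
            spec = ScenarioSpec(
                kind=s["kind"],
                window_end=float(s.get("window_end", MONTH18)),
                options=s.get("options", {}),
            )
            res = run_scenario(
                cohort,
                spec,
                params,
                rng=rng,
                bin_width=bin_width,
                clip=bool(config.report.get("clip", False)),
            )
            p = out_dir / f"{spec.kind}_mean_curve.csv"
            nio.write_csv(res.mean_curve.to_frame(), p, header)
            written.append(p)
            paths[spec.kind] = p
            row = {"scenario": spec.kind}
            for m in months:
                t = m * DAYS_PER_MONTH
                if t <= res.mean_curve.times.max() + 1e-9:
                    i = int(np.argmin(np.abs(res.mean_curve.times - t)))
                    row[f"gain_m{m}"] = res.mean_curve.mean_gain[i]
                    row[f"pi_low_m{m}"] = res.mean_curve.pi_low[i]
                    row[f"pi_high_m{m}"] = res.mean_curve.pi_high[i]
            comparison_rows.append(row)
            log.info("scenario %s done", spec.kind)

        p = out_dir / "scenario_comparison.csv"
        nio.write_csv(pd.DataFrame(comparison_rows), p, header)
        written.append(p)
        paths["comparison"] = p

        if config.delay_loss_grid:
            dl = delay_loss_curve(cohort, params, config.delay_loss_grid)
            p = out_dir / "delay_loss_curve.csv"
            nio.write_csv(dl, p, header)
            written.append(p)
            paths["delay_loss"] = p

        if config.covid:
            series = make_covid_rate_series(config.covid.get("waves"))
            table = covid_cohort_experiment(
                OCEAN_PROFILE,
                params,
                series,
                rng,
                n=int(config.covid.get("n_patients", 4500)),
            )
            p = out_dir / "covid_losses.csv"
            nio.write_csv(table, p, header)
            written.append(p)
            strata = (
                table[table["n_missed"].isin([1, 2])]
                .groupby(["n_missed", "early_miss"])["va_loss"]
                .agg(["mean", "count"])
                .reset_index()
                .rename(columns={"mean": "mean_va_loss", "count": "n_patients"})
            )
            p = out_dir / "covid_strata.csv"
            nio.write_csv(strata, p, header)
            written.append(p)
            paths["covid"] = p

        return paths
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
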