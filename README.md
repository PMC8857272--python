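# namdsim

Simulation and calibration of visual-acuity outcomes under anti-VEGF
treatment patterns in neovascular age-related macular degeneration (nAMD).

Real-world nAMD cohorts receive fewer injections, later, than trial
populations — and lose vision relative to what trials promise. Because
real-world data have no "optimal treatment" control arm, the size of that
loss cannot be measured directly. This package implements a drug–disease
model that provides the missing counterfactuals: it simulates each patient's
ETDRS-letter visual acuity (VA) under *any* injection schedule, so the same
cohort can be re-run under no treatment, under a fixed
3-loading + 8-weekly (3l-q8w) reference pattern, with its treatment delay
removed or capped, with its injections re-timed at a fixed count, or with
pandemic-style missed injections.

It is written for modellers and outcomes researchers in ophthalmology /
pharmacometrics. Since individual-level study data are not public, the
package ships a calibrated synthetic-cohort generator reproducing the
published profile of a large German real-world cohort (baseline VA
52.1 ± 21.3 letters, age 77.8 ± 8.2 y, delay 20.3 ± 19.4 d, 4.47 ± 2.21
injections in year one, retention 3631 → 2943 → 2424 → 1928), so every
analysis runs end-to-end without any download.

## Model

An indirect-response PK/PD turnover model. Untreated,

    dgᵢ/dt = k_in − k_out·gᵢ,   g_ss = k_in/k_out,   gᵢ(0) = g₀ᵢ,

and under treatment the drug stimulates production through a Hill term in
the vitreous drug amount C(t) (superposed first-order-eliminated boluses,
fixed k_drug):

    dgᵢ/dt = k_in·(1 + Emaxᵢ(t)·Cᵢ(t)/(EC50 + Cᵢ(t))) − k_out·gᵢ
    Emaxᵢ(t) = Emaxᵢˢˢ + αᵢ·ΔEmax⁰·e^(−k_Emax·t)
    log Emaxᵢˢˢ = log Emax₀ˢˢ + β·log(ageᵢ/77)

The Emax transient decays from *diagnosis*, not from first injection — which
is why delayed treatment start permanently costs letters. Parameters are
calibrated by least squares on all VA observations jointly. Details, default
values and numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from namdsim import (DEFAULT_PARAMETERS, PatientBaseline, InjectionSchedule,
                     make_3l_q8w_schedule, simulate_trajectory)

patient = PatientBaseline("P1", age=77, g0=52.1, pretreatment="naive",
                          delay=0.0, obs_end=730.5)
months = np.arange(19) * 30.4375
treated = simulate_trajectory(patient, make_3l_q8w_schedule(547.875),
                              DEFAULT_PARAMETERS, months)
untreated = simulate_trajectory(patient, InjectionSchedule(),
                                DEFAULT_PARAMETERS, months)
for m in (3, 6, 12, 18):
    print(f"month {m:2d}: treated {treated.va[m]:.1f}  untreated {untreated.va[m]:.1f}")
```

prints

```
month  3: treated 62.4  untreated 48.6
month  6: treated 64.4  untreated 45.8
month 12: treated 65.6  untreated 41.9
month 18: treated 65.3  untreated 39.3
```

i.e. under the default parameters a 3l-q8w-treated average patient gains
about 13 letters by month 18 while the same patient untreated loses about
13 — the difference the model attributes to guideline-intensity treatment.

The numbered drivers under `analysis/` run the full studies and write their
tables under `results/`:

```bash
python analysis/01_generate_cohort.py     # synthetic cohort + calibration check
python analysis/02_fit_recovery.py        # parameter-recovery experiment (n=500)
python analysis/03_r2_vs_sample_size.py   # mean-curve predictability vs n
python analysis/04_treatment_scenarios.py # counterfactual scenario battery (n=2000)
python analysis/05_covid_impact.py        # pandemic missed-injection experiment
```

A `namdsim` CLI (`generate`, `fit`, `simulate`, `report`) wraps the same
library for config-driven runs; see `namdsim --help`.

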