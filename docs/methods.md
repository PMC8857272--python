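# Methods

## Model

Visual acuity (VA, ETDRS letters) of patient *i* follows an indirect-response
pharmacokinetic/pharmacodynamic turnover model. Without treatment,

    dg_i/dt = k_in − k_out · g_i,        g_i(0) = g_{0,i},

so VA relaxes exponentially toward the untreated steady state
`g_ss = k_in / k_out`. `k_out` (1/day) is the deterioration rate caused by
the disease; `k_in` is never stored or estimated separately — it is always
derived as `g_ss · k_out`.

Intravitreal ranibizumab stimulates the production rate through a Hill
function (coefficient 1) of the vitreous drug amount C(t):

    dg_i/dt = k_in · (1 + Emax_i(t) · C_i(t) / (EC50 + C_i(t))) − k_out · g_i.

C(t) is a superposition of first-order-eliminated boluses,
`C(t) = Σ dose_j · exp(−k_drug (t − t_j))` for injections at times t_j ≤ t.
The elimination constant is fixed, not estimated; the default corresponds to
a 9-day vitreous half-life (`k_drug = ln 2 / 9 ≈ 0.077`/day), a typical
ranibizumab value, and is exposed in configuration.

The maximum effect decays from a baseline value toward an age-dependent
steady state:

    Emax_i(t) = Emax_ss(age_i) + α_i · ΔEmax0 · exp(−k_emax · t),
    log Emax_ss(age) = log emax0_ss + β · log(age / 77).

The decay clock starts at study baseline (diagnosis), *not* at the first
injection. This is deliberate and is the mechanism by which treatment delay
destroys benefit: a patient treated late receives their injections after the
transient high-responsiveness window has partly decayed. For pre-treated
patients the clock likewise starts at study baseline (their historical
treatment history is unobserved). α scales the transient by pre-treatment
status: treatment-naive patients have α = 1 by convention, pre-treated
patients an estimated α ∈ [0, 1], and "possibly pre-treated" patients
default to the pre-treated value (separately configurable).

### Units

No vitreous volume is modelled. C(t) is carried in dose units (mg remaining
in the eye) and `ec50` absorbs the volume scale; only the ratio C/EC50 ever
enters the dynamics, so an absolute concentration scale would not be
identifiable anyway.

### Default parameters

The defaults are pilot-calibrated package values chosen to give realistic
curve shapes — roughly −10 letters/year untreated decline from a mid-50s
baseline, +9 letters after 3 months of fixed 3-loading + q8w treatment, and
a real-world curve that peaks around month 4–5 and then drifts down. They
are **not** estimates from any study dataset.

| parameter  | default | units | meaning |
|------------|---------|-------|---------|
| g_ss       | 35.0    | letters | untreated steady-state VA |
| k_out      | 0.0025  | 1/day | VA deterioration rate (time constant 400 d) |
| ec50       | 0.04    | mg (dose units) | half-effect drug amount |
| emax0_ss   | 1.5     | —     | steady-state Emax at age 77 |
| d_emax0    | 1.5     | —     | baseline (loading-phase) Emax increment |
| k_emax     | 0.01    | 1/day | decay of the baseline increment (τ = 100 d) |
| beta       | −2.0    | —     | age exponent on log-Emax |
| alpha_pretreated | 0.3 | — | transient-effect scaling if pre-treated |
| k_drug     | ln 2 / 9 | 1/day | fixed PK elimination (9-day half-life) |

### Numerical integration

Two paths, asserted against each other in the test suite:

- **Reference**: adaptive LSODA with rtol = atol = 1e−8 and every injection
  time registered as an integration breakpoint, so the discontinuous forcing
  is never stepped over. Used for single-patient work, oracles, and
  observation generation.
- **Cohort grid**: a vectorized exponential-trapezoidal fixed-step scheme on
  a shared 0.25-day grid. The drug state is propagated exactly between
  nodes; bolus times are snapped to the nearest node (≤ 0.125 d, worth
  ≲ 0.03 letters per injection); the VA update integrates the smooth forcing
  with exponentially weighted trapezoids. Agreement with the reference path
  is < 0.01 letters on grid-aligned schedules and < 0.05 letters including
  snapping. Used for fitting and scenario runs, where it is two to three
  orders of magnitude faster than per-patient adaptive solves.

The ODE state is never clamped; exported VA can optionally be clipped to
[0, 100] letters (off by default). One month is 30.4375 days in all schedule
arithmetic.

## Estimation

Ordinary (unweighted) least squares over all observations jointly. Positive
parameters are optimized on the log scale and the pre-treatment scaling on
the logit scale, which guarantees the returned parameters satisfy their
domain constraints. Each start runs a short Nelder–Mead pre-pass on the sum
of squares followed by a trust-region least-squares refinement; multi-starts
are jittered around the initial point with a fixed seed, making the fit
deterministic given data, init and config. `ec50` is fixed by default: under
a single dose level it is only weakly identified jointly with the Emax
parameters (a flag enables estimating it). The condition number of the final
Jacobian is checked and a near-singular information matrix (e.g. fitting
drug-effect parameters with no injections in the data) is reported as a
warning on the result.

Goodness of fit: mean VA-gain curves in monthly bins (observations assigned
to the nearest bin center, patients contributing while under observation),
with normal-approximation 95% intervals for the mean (mean ± z·sd/√n);
adjusted R² between predicted and observed mean curves,
`1 − (1 − R²)(n − 1)/(n − p − 1)` with n bins and p = number of estimated
model parameters (7 by default) — a package convention, stated explicitly
because several adjustments are in use in the field. The sample-size sweep
draws patients without replacement (30 draws per size) and reports the mean
and empirical 2.5/97.5 percentiles of adjusted R².

In the recovery experiment (500 synthetic patients, 5-letter noise,
real-world schedules, deliberately wrong init) the fit recovers `k_out`,
`emax0_ss` within ~2% and `k_emax` within ~13%, and the fitted mean curve
explains the noise-free truth curve with adjusted R² ≈ 0.998.

## Synthetic cohort generator

The generator reproduces the *published summary profile* of a large German
real-world nAMD cohort; the families are package choices because only
moments, quantiles and counts are published:

- **Baseline VA / age**: truncated normals (VA on [0, 100], age ≥ 50) whose
  parent parameters are moment-matched numerically so the *realized*
  mean/SD hit the targets (52.1 ± 21.3 letters; 77.8 ± 8.2 years).
- **Pre-treatment**: categorical 73.2 / 17.4 / 9.5% (renormalized).
- **Delay**: a two-component gamma mixture (prompt component with fixed
  shape 2, free scale; free tail component; free weight) calibrated by least
  squares to mean 20.3 d, SD 19.4 d, P(< 14 d) = 43.7%, P(> 28 d) = 29.1%.
  All four targets are met within tolerance simultaneously.
- **Injection pattern**: the first injection at the patient's delay; a
  first-year count from a negative binomial with mean 4.47 and SD 2.21; the
  remaining first-year events placed with a first gap of 4–6 weeks and
  geometrically widening (or tightening) gaps scaled to fit the drawn count
  into the first year, with log-normal jitter; maintenance continues with
  jittered widening gaps from month 12 to the observation end. Only the
  first-year count statistics are calibration-constrained; the gap process
  is invented structure.
- **Dropout**: piecewise-exponential hazard on (0, 6], (6, 12], (12, 18]
  months solved in closed form from the retention fractions
  3631 → 2943 → 2424 → 1928; survivors of month 18 are completers at
  month 24.
- **Observations**: model trajectory at monthly visits plus i.i.d. Gaussian
  noise (default σ = 5 letters), clipped to [0, 100].

What the generator does *not* emulate: the true joint covariate structure
(covariates are drawn independently), per-center effects, visit-time
irregularity, informative dropout (worse courses dropping out earlier), or
any drug other than ranibizumab 0.5 mg. Passing tests therefore demonstrate
internal consistency of the method under the published marginal profile, not
fidelity to unpublished individual-level data.

## Scenarios

All schedule counterfactuals preserve cohort identity (n, baselines,
observation windows) and — where applicable — per-patient injection counts:
delay shifting moves the whole schedule forward (the treatment-free gap
moves to the end of the window); redistribution keeps the observed count and
re-times events (3 q4w loading + equally spaced rest, jittered σ = 4 d
loading / σ = 7 d maintenance, re-sorted and clipped to t ≥ 0; or no loading
and all-equal spacing). The redistribution window runs to month 18 even
though counts are the full observed counts — kept as specified upstream and
noted here as an inconsistency of the source description. Pandemic thinning
keeps each injection independently with probability
min(performed/reference, 1) from a weekly rate series; missed injections are
dropped (a postpone mode exists for sensitivity analysis). Dates outside the
series coverage are at parity. The pandemic experiment uses 4,500 patients
by default — a 1% desk-scale stand-in for a ~450,000-patient national
population, configurable. The external-trial-style validation arm draws age
and baseline VA from normal distributions (78.8 ± 8.4 y; 54.2 ± 13.3
letters), assumes no pre-treatment, and treats with 3 q4w loading then q8w
to month 12 (n = 275 by default). The source material describes that arm's
regimen inconsistently (monthly dosing in its cohort table vs loading + q8w
in its validation text); the validation-text regimen is implemented.

## Known limitations and scope choices

- Mean-level prediction only; no inter-individual random effects, so
  individual trajectories are not predictable (by design).
- Horizons beyond ~18 months are extrapolation; scenarios default to a
  month-18 window.
- The "earlier injection never hurts" leverage property holds while the
  transient Emax component dominates (shifts on the 0–12-week delay scale
  for the default rates); at a fixed horizon and long shifts the persistent
  effect component makes timing neutral-to-late-favorable. The cohort-level
  delay-loss curve is monotone over the delay range studied.
- Problem sizes used in tests and analyses (500 for recovery, 2,000 for
  scenario orderings, 4,500 for the pandemic experiment, 3,631 for
  generator calibration) are the package's chosen desk-scale study
  conditions.
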