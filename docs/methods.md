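# Methods

## Scope and data situation

The package simulates and re-estimates a population PK/PD system for a
once-weekly 40 kDa Y-shaped PEG-rhGH in pediatric GHD. The clinical datasets
behind the original analysis are private and the fitted model parameters
were never published, so the package is built around three substitutes:

* a **nominal parameter set**, calibrated once against published summary
  statistics (below) and shipped as versioned data;
* a **synthetic-cohort generator** that reproduces the published baseline
  moments and study designs;
* a **parameter-recovery study** that takes the place of a comparison with
  the unpublished estimates.

## Structural models

**PK.** One-compartment disposition, first-order subcutaneous absorption,
linear elimination. The compartmental structure is a package design choice:
it is the parsimonious default for a large PEG conjugate (small volume,
slow absorption, multi-day half-life) and makes every multiple-dose
quantity analytic — the single-dose curve is the Bateman function, multiple
dosing is propagated exactly segment-by-segment through the depot/central
state, and interval AUCs are closed-form integrals of that state. The
module is written so a richer disposition model can replace it behind the
same interface. Allometric scaling uses CL ∝ (WT/25)^0.75, V ∝ (WT/25)^1.0
with the 25 kg reference at the mid-range of the banded target weights.
Between-subject variability is lognormal on CL, V and ka; residual error is
proportional plus a small additive floor.

**IGF-1.** Turnover model with stimulation of production (type-III
indirect response). The production rate is tied to the individual baseline
(k_in,i = k_out·R0,i), so the system is at homeostasis without drug and the
drug effect is a pure displacement. The solver holds the stimulus
piecewise-constant at mid-interval concentrations and applies the exact
exponential one-step update; on a uniform grid this is a first-order IIR
recursion evaluated by `scipy.signal.lfilter`, which makes cohort-scale
simulation cheap. Against adaptive ODE integration the error is < 0.2 %
on hourly grids; the constant-concentration steady state is exact.

**IGF-1 SDS.** Lognormal age/sex standardization:
SDS = (ln R − μ_ln(age,sex))/σ_ln(age,sex). During a simulation the
untreated baseline is assumed to track the reference median as the child
ages, so the drug-induced displacement is age-invariant:
SDS(t) = SDS₀ + ln(R(t)/R₀)/σ_ln. This deliberately separates drug effect
from maturational drift; absolute IGF-1 values depend on the synthetic
reference and carry no clinical meaning.

**GV.** Direct effect of exposure with first-order attenuation:
GV(t) = [E0_i + (E_max + η_i)·AUCτ/(AUC50 + AUCτ)]·e^(−λt), where AUCτ is
the AUC of the dosing interval preceding the measurement, held constant
within each week. E0_i is the subject's observed pre-treatment GV. The
e^(−λt) term is required to reproduce the universal first-to-second-year
GV decline at constant dose; with λ = 0 the two treatment years are
identical by construction. Height is the running integral of GV
(piecewise-linear, weekly); annualized GV at month m is H(m) − H(m−12), so
the 24-month value is second-year velocity. This convention is stated
explicitly because "annualized GV at 24 months" is ambiguous in common
usage; under it, arm convergence at 24 months is a saturation statement
about the second treatment year.

## Nominal parameters and calibration

`src/pegsim/data/nominal_params.yaml` is the single source of parameter
values. PK values were chosen directly: t½ ≈ 3.3 days gives ≥ 95 %
accumulation well before week 12 (steady state by the week-12 read-out) and
a tmax of ~2.5 days, both consistent with once-weekly dosing of a large
conjugate. The four PD shape parameters (E_max, AUC50, λ, S_max) were
calibrated once by `scripts/calibrate.py` (least squares on a fixed
200-subject cohort) against the published summary benchmarks kept in
`pegsim.params.BENCHMARKS`: baseline GV 3.57 ± 1.06 cm/year, 12-month
arm-mean GVs in the 9.5–9.9 band ordered by escalation rate, second-year
convergence near 9.35 cm/year in every arm, and 12-month trough IGF-1 SDS
near 0.37/0.73 for the slowest/fastest arms. The GV random-effect SD was
then set so the simulated 12-month GV SD is near the published 2.35.
Because six targets constrain four parameters, the fit is a compromise: the
shipped set reproduces the levels and the orderings, with a smaller
between-arm 12-month spread (≈ 0.1 cm/year) than printed. The calibration
is frozen; it is not re-run by tests or the acceptance script.

## Synthetic data

The generators are pure functions of (configuration, seed); all randomness
flows from one master seed through named `SeedSequence` child streams.

* **GHD cohort** (default n = 292): ages uniform 4–12 y, 1:1 sexes
  (Bernoulli), weights/heights ~1.5 SD below the healthy reference
  channels, baseline GV ~ N(3.57, 1.06) truncated at 0 (p ≈ 4·10⁻⁴,
  redrawn), baseline IGF-1 SDS ~ N(−1.27, 0.55).
* **Banded cohort**: 7 strengths × 10 subjects (5 M/5 F), weights exactly
  at the five band scenario points; ages back-solved from the GHD-shifted
  weight channel and clamped to 3–16 y; baseline SDS standardized to −1.
  Within a (strength, sex) cell the five scenario subjects share one
  baseline GV, so scenario contrasts isolate the weight effect.
* **Growth/IGF-1 references**: smooth synthetic median tables for ages
  2–18 y with constant lognormal spread, shipped as CSV. They are
  interface stand-ins, not clinical references; every downstream
  computation touches them only through the lookup API.
* **Observation designs**: a rich single-dose adult PK study (five mg/kg
  dose levels, 15 samples over 336 h per subject) and a sparse pediatric
  design with weekly dose records and quarterly pre-dose PK, IGF-1 and GV
  observations. Residual errors (15 % proportional PK, 10 % proportional
  IGF-1, 0.5 cm/year additive GV) are applied only by the observation
  generators, never inside the simulators. For the estimation pathway the
  body weight is held at baseline so the exposure model is time-invariant;
  the trial simulators, by contrast, update weight quarterly.

What the generator does **not** emulate: real covariate structure (age
effects on response, puberty), adherence and dropout, assay quirks, or
time-varying weight in the estimation datasets. Passing tests therefore
demonstrate internal consistency of the method under the stated model, not
predictions for real children.

## Trial simulators

* **Up-titration study**: the full cohort is simulated under each
  escalation arm with shared subjects and shared random effects, so arm
  contrasts are paired and free of cohort-sampling noise. Weight-based
  doses are recomputed at quarterly visits from the channel-projected
  weight; titrated unit doses use the published rounded schedule by
  default (a flag switches to exact multipliers). Quarterly safety
  read-outs are pre-dose trough SDS (0.1 h before the next dose, i.e.
  167.9 h after the preceding one).
* **Banded study**: replicate Monte Carlo (default 500; 100 in tests and
  the acceptance script) over the 70-subject cohort at steady state
  (week 12, 13 simulated weeks, weight frozen over this short window).
  Replicate eta draws are shared across the five weight scenarios within a
  strength/sex cell, making the GV difference against the target-weight
  scenario an exact paired contrast — its sign and the narrow-within-wide
  ordering are then structural, not sampling accidents. Outputs: GV
  mean (SD) and difference per scenario (reported raw and at 1 dp), and
  90 % prediction bands of the SDS time course over the week-12 interval
  with a time-averaged Jaccard overlap against the reference band.

## Estimation

FOCE-style approximation: per-subject conditional eta modes by a
vectorized Levenberg–Marquardt Gauss–Newton iteration (etas clipped to
±6 SD), Laplace marginal likelihood with the residual variance evaluated at
the conditional predictions ("with interaction"), outer L-BFGS-B over
log-transformed fixed effects, SDs and sigmas with finite-difference
gradients (step 10⁻⁴). The inner search always restarts from the prior
mode so the outer objective is deterministic. A restart that cannot
improve the objective meaningfully is accepted as stationary, which
absorbs spurious line-search terminations on the slightly jagged Laplace
surface. `naive_pooled` (weighted least squares at zero etas) serves the
noise-free fixed-point tests. Convergence is always reported explicitly;
nothing fails silently.

Sequential strategy = IPP: empirical-Bayes PK etas from each pediatric
subject's trough PK rows are frozen; individual concentration grids and
weekly AUCs are rebuilt from the dataset's dose records at those
parameters; then the IGF-1 and GV sub-models are fitted.

Identifiability decisions, made once and fixed:

* **k_out fixed** in the IDR fit — quarterly troughs contain almost no
  turnover-rate information (IGF-1 reaches quasi-steady state within
  days). Fixing turnover from prior knowledge is standard for trough-only
  designs.
* **SC50 fixed by default** — therapeutic trough concentrations
  (≤ ~1.2 mg/L) never approach the nominal SC50 (3.5 mg/L), so only the
  S_max/SC50 ratio is identifiable; estimating both produces paired
  ridge drift. `fixed={}` forces joint estimation.
* **Recovery design is dose-ranging**: the n = 50 recovery cohort is split
  across flat 0.02 and 0.05 mg/kg/week arms and the fastest titration arm,
  mirroring a dose-finding stage; without exposure spread the Emax/EC50
  pairs of the PD models are not separable. The IGF-1 baseline estimand in
  that study is the cohort geometric-mean baseline (the generator derives
  baselines from the age/sex reference).

On this design, 20-seed mean biases are ≲ 2 % for PK fixed effects and
≲ 4 % for the IDR and GV fixed effects, with omegas recovered within ~25 %
at n = 50 — the quantities the test suite and acceptance script recompute.

## Numerical choices

Hours are the internal time unit; the week is exactly 168 h and a month
730.5 h. Simulation grids are hourly (2-hourly inside the PD fit; the
difference is < 0.1 % on trough quantities). PK propagation and AUCs are
analytic; the ka → ke degenerate case switches to the limiting Bateman
form. Titrated unit doses round half-up to 2 dp of the compound value;
band-edge arithmetic operates on 2-dp rounded targets (matching the
printed convention, e.g. 14.29 − 3.57 = 10.72), and the narrow half-width
1.78 kg is the half-to-even rounding of 3.57/2. Strength assignment
breaks exact-tie distances toward the lower strength, with distances
rounded at 10⁻⁹ kg so floating-point noise cannot flip a tie. Prediction
bands are empirical percentiles; the band-overlap of two degenerate
(zero-width) identical bands is defined as 1.

## Problem sizes

The shipped studies run the full published sizes (292 subjects × 3 arms ×
24 months; 70 subjects × 100 replicates × 13 weeks) in seconds to minutes
on one CPU. The recovery study uses n = 50 cohorts over 20 seeds, a size
at which the bias bands above are stable; `scripts/calibrate.py` used a
200-subject calibration cohort.

## Known limitations

* GV depends on age only through exposure, so the banded study does not
  reproduce the higher absolute GV of the youngest (lightest) groups seen
  in practice — only within-strength contrasts are meaningful.
* The 12-month between-arm GV spread is compressed relative to the
  published 0.37 cm/year (see calibration compromise above).
* Tail probabilities (proportion of SDS > +2) are somewhat lighter than
  published; the SDS mean/SD structure, orderings and saturation pattern
  are the calibrated quantities.
* The synthetic references make absolute IGF-1/weight/height values
  non-clinical by construction.
* Only diagonal covariance matrices for random effects; no covariate
  search, no standard errors beyond optimizer diagnostics, no bootstrap.
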