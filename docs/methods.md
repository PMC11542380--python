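# Methods

This note records the modelling assumptions, parameter conventions,
numerical choices and limitations of `alpopk`. It documents what the code
does and why; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Structural PK model

One-compartment disposition with zero-order absorption and first-order
elimination. Absorption has no lag time; each dose delivers at the constant
rate dose/Tk₀ for Tk₀ hours. Parameters and units:

| parameter | meaning                          | unit | typical values (day 1 / 14 / 28) |
| --------- | -------------------------------- | ---- | -------------------------------- |
| Tk₀       | zero-order absorption duration   | h    | 0.85 / 1.11 / 0.95               |
| V         | apparent volume of distribution  | L    | 42.82 / 32.57 / 32               |
| Cl        | apparent clearance               | L/h  | 20.9 / 17.2 / 16.13              |

kₑ = Cl/V ≈ 0.49–0.53 h⁻¹, i.e. a half-life of ~1.3–1.4 h. With once-daily
dosing kₑ·τ ≈ 12, so steady-state accumulation is a factor
1/(1−e^(−kₑτ)) − 1 < 10⁻⁵: multi-dose peaks are indistinguishable from
single-dose peaks, which is why simulated efficacy is insensitive to course
duration (90 vs 365 days) and why skipping individual doses barely moves a
patient's Cmax.

Degenerate inputs: Tk₀ = 0 (an instantaneous bolus) is outside the model and
rejected; a dose amount of 0 encodes a skipped dose and contributes nothing.
The closed form is cross-checked against an adaptive Runge–Kutta (DOP853)
integration of the two-state system, split at every absorption-rate
breakpoint; agreement is ≤ 10⁻⁶ mg/L over randomized multi-dose instances.

Cmax search: for non-overlapping absorption windows every local maximum of a
superposition profile lies at an absorption end t_dose + Tk₀, so the search
evaluates those candidates plus a 0.01-h fallback grid (the grid guards the
API against parameter regimes where windows overlap). The vectorised
simulator path exploits the same fact with a geometric recursion
S_k = S_{k−1}·e^(−kₑτ) + D_k over dose ends; it requires Tk₀ < τ and is
tested against the grid search.

## Random effects and the %CV convention

Each parameter carries one random effect, independent across parameters and
across occasions (diagonal Ω; no correlations are reported for this
compound, and occasions are modelled as three separate populations rather
than nested inter-occasion variability).

Two distribution kinds are supported. The printed dispersion (%CV) columns
of the three occasion tables are mutually consistent only under a mixed
assignment, which the presets therefore encode and the tests pin:

* Tk₀ and Cl: **lognormal** on all three occasions
  (CV% = 100·√(exp(ω²)−1); e.g. ω = 0.51 → 54.5% vs printed 54.88).
* V: **normal** on days 1 and 14 (CV% = 100·ω/V; 13.2/42.82 → 30.83% vs
  printed 30.82) and **lognormal** on day 28 (ω = 0.25 → 25.4% vs printed
  25.03).

Whether the day-28 switch was deliberate in the source analysis is unknowable
from the published tables; both kinds are first-class here. Normal-kind
draws that land ≤ 0 are rejected and redrawn — never clipped — with a hard
error after 1000 failed rounds (at the bundled values P(V ≤ 0) ≈ Φ(−3.24),
so resampling is essentially never triggered).

Residual error is the combined model y = f + g(f)·ε with g = a + b·f
("combined-1") by default. The source tables publish only the two
coefficients, not the variant, so g = √(a² + (b·f)²) ("combined-2") is
available behind the `error_form` switch. Simulated observations that come
out negative are floored at 0 and flagged (`FLOOR` column) rather than
dropped; no below-quantification rule is published.

## Synthetic trial generator

The concentration data behind the study are not public, so `alpopk.trial`
generates stand-in datasets reproducing the design: 15 subjects at 1,000 mg
once daily sampled on day 1, and 16 titration subjects
(1,000 → 1,500 → 2,000 mg) sampled on days 14 and 28, 12 samples per
occasion at 0–8 h post-dose. Choices worth knowing:

* The study text reports 32 PK patients while the arm arithmetic gives
  15 + 16 = 31; the generator defaults to 31 and exposes the counts as
  configuration.
* Sampling-day doses for the titration arm: day 14 is dosed at 1,000 mg
  (last day of that block) and day 28 at 1,500 mg; the publication does not
  state which dose was given on sampling days. Dose amounts are recorded in
  the dataset, so estimation is unaffected by this choice.
* Carry-over from previous daily doses on a sampling day is < 10⁻⁵ of Cmax
  (see above) and is omitted: each occasion is simulated as a single dose at
  occasion time 0.
* Covariates (sex ~ Bernoulli(0.5), age ~ N(63, 8²) yr, weight ~ N(58, 9²)
  kg, height ~ N(160, 8²) cm) are synthetic plausible defaults — no
  demographics table is published — and deliberately carry **no** effect on
  the PK parameters, matching the finding that no screened covariate
  improved the model. Passing covariate-screen tests therefore demonstrate
  type-I control, not detection on real data.
* File format: CSV with columns ID, OCC, TIME, AMT, DV, EVID, MDV, FLOOR,
  SEX, AGE, WT, HT (EVID 1/MDV 1 = dose row; TIME in hours within the
  occasion; DV in mg/L; OCC ∈ {day1, day14, day28}). Validation is strict,
  with row-numbered errors and a warning for positive pre-dose
  concentrations.

What the generator does not emulate: assay error structure beyond the
combined model, dropout, sparse/irregular sampling, dose-recording errors.
Parameter-recovery results below therefore speak to the estimator under the
declared model, not to robustness against real-data pathologies.

## SAEM estimation

Transformed scale φ = (log Tk₀, V, log Cl) (log entries for lognormal
kinds). Defaults: 300 exploratory iterations (step size 1) then 200
smoothing iterations (step size 1/k); per iteration, one componentwise
independence Metropolis sweep proposing from the current prior followed by
2 random-walk sweeps whose proposal SDs adapt toward 30–50% acceptance
during exploration. Two stabilisers proved necessary at this sample size
(16 subjects × 12 observations):

* the **prior-independence sweep** keeps a component's chain alive when its
  random-walk scale has adapted down;
* an **annealing guard** lets each ω shrink at most 5% per exploratory
  iteration. Without these, the V chain can freeze early (all subjects
  stuck at the population mean), ω_V collapses to its floor (10⁻⁶, with a
  warning) and the fit silently degenerates.

M-step: μ and ω² from stochastically-approximated first and second moments
of φ (closed form; with a covariate, a 2-column linear regression). The
error pair (a, b) minimises the approximated conditional deviance
Σ[2·log g + r²/g²] by Nelder–Mead in (log a, log b), warm-started each
iteration. Initial values: pooled nonlinear least squares for the typicals
(trust-region reflective, bounded), ω = 0.3 (log scale) or 0.3·typical
(natural scale), a = 10% of the mean observation, b = 0.2. Convergence is
declared when every parameter's trailing-50-iteration coefficient of
variation is below 5%; non-convergence warns and returns the last state.

Likelihood: OFV = −2 log L by importance sampling around each subject's
conditional mode (numerical 3×3 Hessian, Gaussian proposal), with a
delta-method Monte-Carlo SE; mc_size < 100 is rejected. A deterministic
Laplace approximation of the same quantity backs the optional
Fisher-information standard errors (numerical Hessian of the Laplace OFV at
the estimates) and the covariate screen. In the ω → 0 limit both reduce to
the independent-Gaussian deviance, which the tests verify analytically.

Information criteria: AIC = OFV + 2k, BIC = OFV + k·ln N_subjects, and BICc
with the hybrid penalty — parameters tied to random effects (typicals and
ω's; k − 2 of the k = 8 per occasion) penalised by ln N_subjects, the two
residual-error coefficients by ln n_obs. BICc is cited but not defined in
the source; this hybrid definition is the package's choice.

Recovery at study scale (computed by the acceptance suite): across 20
seeded replicates of the day-1 design, median estimates land within a few
percent of the generating values and ≥ 80% of replicates recover each fixed
effect within ±20%.

## Covariate screening

Forward addition of one covariate at a time to each of Tk₀/V/Cl: a power
model on continuous covariates (coefficient on the centred log-ratio to the
median) and a fractional shift on sex, acting on the parameter's
transformed-scale mean. Two design points differ from a naive
refit-per-candidate scheme, and both were forced by measurement:

* **Profile, not refit.** Two SAEM fits of the *same* model differ by
  several OFV units through Monte-Carlo variation alone — more than the
  χ²₁ signal a real covariate would add at n = 16. The screen therefore
  profiles the covariate coefficient on the deterministic Laplace
  likelihood with the base parameters held fixed (near-quadratic profile:
  3-point stencil, vertex jump, re-evaluated null with an equally refined
  conditional-mode cache). The reported ΔOFV isolates the covariate term
  exactly and is reproducible.
* **Familywise threshold.** Flagging any of the 12 (covariate, parameter)
  pairs at per-test α = 0.05 would produce a false positive in roughly half
  of all null datasets, so a screen meant to conclude "no covariate
  improves the model" must control the family. The default flag is
  ΔOFV < −χ²₁(α/12) ≈ −8.2 together with ΔBIC < 0; `familywise=False`
  restores the per-test −3.84 rule for users who want the classical forward
  step. Measured null behaviour of the default at study scale: zero flags
  in 19 of 20 replicates.

Because V influences observations only through kₑ = Cl/V under zero-order
absorption, a true covariate effect on V may be attributed to Cl (or split);
the screen's unit of conclusion is the covariate, not the parameter.

## Diagnostics

GOF tables report population predictions (typical parameters), individual
predictions (conditional modes) and weighted residuals
IWRES = (y − f_ind)/(a + b·f_ind) (population analogue on typical
predictions). The VPC simulates ≥ 100 replicate datasets at the observed
design, reports the across-replicate 2.5–97.5% band of each requested
percentile per sampling-time bin, and flags observed percentiles outside
their band. Both emit tidy tables; plotting is left to the caller.

## Regimen simulation and adherence

`SimulationSpec` draws independent random effects per occasion model. The
default response rule (`all_occasions`) requires the Cmax cut-off to be met
under *every* occasion model; `single_occasion` (day 28 by default) is the
documented alternative. Rationale: single-occasion typical Cmax already
exceeds the progression cut-off at 1,500 mg, which is incompatible with the
published intermediate response rates; the conjunction over occasions moves
the dose–response curve into the plausible range. This remains a
calibration choice — the source does not state which fitted model(s) or
occasion logic produced its predictions — so the published 100%-adherence
series (progression 96/83/55/27/12%, mortality 66/50/29/12/3% across
1,000–3,000 mg) is treated as a calibration reference with an ordering
property, not as an exact target.

Classification uses the model-predicted individual Cmax without residual
error (the cut-offs are exposure thresholds, not assay readouts); an
error-inclusive variant is a one-line change via `residual_observe` and is
deliberately not the default.

Adherence defaults to **patient-level** Bernoulli gating: with probability
1 − p a patient takes (effectively) none of the course and loses both
responder flags. The published adherence-degraded efficacies are numerically
consistent with this thinning (event% ≈ 100 − p·(100 − base%)); dose-level
skipping is retained for sensitivity analysis but cannot reproduce them,
because with a 1.4-h half-life a skipped dose only removes that day's own
peak and leaves the per-patient maximum essentially unchanged — the tests
demonstrate both facts.

Grids use common random numbers (same virtual patients across regimens and
adherence levels within a replicate) so monotonicity in dose and adherence
is not blurred by between-cell sampling noise. Default sizes are 1,000
patients and 200 replicates; the dose-ordering check in the acceptance
suite uses 400 replicates for the single-occasion rule because the mortality
event probabilities at 2,500/3,000 mg are ~10⁻⁵/10⁻⁶·5 and resolving their
order needs that many draws.

## Contingency statistics

OR = ad/bc with the Woolf log-scale 95% CI; the Haldane–Anscombe +0.5
correction applies to all four cells iff any cell is zero (and can be
disabled, making zero cells an error). Chi-square is the uncorrected
Pearson 1-df form (Yates behind a flag); NNT = 1/(risk difference),
reported unrounded and rounded up. Simulated percentages are converted to
counts at a configurable effective arm size (default 13, the evaluable arm
size) and every result row carries the n used — published ORs for this
study are not reconstructible from the stated proportions and arm sizes, so
no claim of matching them is made. All formulas are verified against
exhaustive first-principles enumeration on small tables.

## Pipeline and recommendation

`run_pipeline` chains generate/load → per-occasion SAEM → validation
(predicted vs observed arm-level efficacy) → regimen × adherence grid →
comparisons → recommendation, fully deterministic given the config seed,
with a config-hash + seed provenance record beside every artifact. The
recommendation rule formalises the study's reasoning: among regimens with
progression ≤ 30% and mortality ≤ 15% at full adherence, take the minimal
capsule count. Capsule counts use the published dose↔capsule pairs
(1,000→9, 1,500→14, 2,000→18, 2,500→23, 3,000→28); note 3,000 mg is
published as 28 capsules although round(3000/111.1) = 27, so the pairs are
a lookup table and the 111.1-mg arithmetic only covers unlisted doses.
Hematological toxicity is reported as a static annotation (an external
model's "< 5%"), never computed. Under the bundled occasion models the rule
selects 2,500 mg (23 capsules).

## Limitations

* The efficacy base rates produced by the simulator differ from the
  published series by up to ~20 pp at the extremes (e.g. 1,000-mg mortality);
  the under-specified simulation provenance in the source makes closer
  calibration guesswork, and only the dose ordering is asserted.
* SAEM standard errors use a Laplace-based numerical Fisher information;
  stochastic-approximation SEs as produced by commercial tools may differ.
* The covariate screen's profile likelihood holds base parameters fixed;
  it is slightly conservative relative to a full joint refit.
* Occasions are independent fits; a pooled multi-occasion model with
  inter-occasion variability is out of scope, as is any time-to-event or
  toxicity modelling.
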