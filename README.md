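# alpopk

Population pharmacokinetic/pharmacodynamic modelling and Monte-Carlo dose
prediction for the total bioactivity of *Atractylodes lancea* (AL), a
standardized herbal capsule formulation (CMC-AL) studied in patients with
advanced-stage intrahepatic cholangiocarcinoma (iCCA).

The package is aimed at pharmacometricians and quantitative clinical
pharmacologists who want to reproduce, stress-test or extend the dose-finding
workflow behind a phase-2A study of this compound: fit a population PK model
to concentration–time data, simulate virtual patients under candidate
once-daily regimens, classify each patient's predicted clinical outcome from
an exposure threshold, degrade efficacy under imperfect medication adherence,
and compare regimens with contingency statistics.

## Model

**Structural model.** One compartment with zero-order absorption (no lag) and
linear elimination. A dose *D* given at time 0 enters the central compartment
at constant rate *D*/Tk₀ for Tk₀ hours; with V the apparent volume, Cl the
clearance and kₑ = Cl/V:

```
C(t) = D/(Tk0·Cl) · (1 − exp(−ke·t))                          0 ≤ t ≤ Tk0
C(t) = D/(Tk0·Cl) · (1 − exp(−ke·Tk0)) · exp(−ke·(t − Tk0))   t > Tk0
```

Multi-dose profiles are superpositions of shifted single-dose profiles.

**Statistical model.** Diagonal random effects per occasion:
pᵢ = p_pop·exp(η) (lognormal) or pᵢ = p_pop + η (normal), η ~ N(0, ω²),
with combined residual error y = f + (a + b·f)·ε, ε ~ N(0, 1). Three
bundled occasion models (`table1_day1`, `table2_day14`, `table3_day28`)
carry the published fixed effects, ω's and error coefficients for study
day 1, day 14 and day 28. Estimation is by SAEM (stochastic approximation
EM) with a Metropolis E-step; the marginal −2 log-likelihood (OFV) is
computed by importance sampling and summarized as AIC/BIC/BICc.

**Dose prediction.** 1000 virtual patients per replicate are drawn from the
occasion models; a patient responds when the model-predicted Cmax over the
course reaches the exposure cut-offs Cmax ≥ 32.39 mg/L (tumor-progression
inhibition) and ≥ 21.42 mg/L (death prevention). Adherence is modelled as
patient-level Bernoulli compliance (probability *p*; non-adherent patients
are counted as events), with a dose-level skipping mode for sensitivity
analysis. Regimens are compared with odds ratios (Woolf CI), chi-square
tests and number-needed-to-treat.

## Worked example

```python
from alpopk import StructuralParams, DoseEvent, cmax, PRESETS
from alpopk.regimen import (SimulationSpec, Regimen, AdherenceScenario,
                            EfficacyCriteria, run_efficacy_grid)

# typical day-28 subject, single 2,000-mg dose
p = PRESETS["table3_day28"].typical_params
peak, t_peak = cmax(p, [DoseEvent(0.0, 2000.0)], window=(0.0, 24.0))
print(f"typical day-28 Cmax after 2,000 mg: {peak:.2f} mg/L at {t_peak:.2f} h")

spec = SimulationSpec(tuple(PRESETS.values()), "all_occasions", n_patients=1000)
grid = run_efficacy_grid(
    spec,
    regimens=[Regimen(d, duration_days=90) for d in (2000.0, 2500.0, 3000.0)],
    scenarios=[AdherenceScenario(1.0), AdherenceScenario(0.5)],
    criteria=EfficacyCriteria(),
    n_replicates=50, seed=11,
)
cols = ["daily_dose_mg", "adherence", "progression_pct", "mortality_pct"]
print(grid[cols].round(1).to_string(index=False))
```

prints

```
typical day-28 Cmax after 2,000 mg: 49.66 mg/L at 0.95 h
 daily_dose_mg  adherence  progression_pct  mortality_pct
        2000.0        1.0             41.1            3.5
        2000.0        0.5             70.7           51.8
        2500.0        1.0             12.3            1.0
        2500.0        0.5             56.2           50.5
        3000.0        1.0              3.7            0.4
        3000.0        0.5             51.9           50.2
```

The typical-subject peak lands at the end of absorption (Tk₀ = 0.95 h).
In the virtual population, predicted tumor progression at full adherence
falls from 41% at 2,000 mg to 4% at 3,000 mg, but halving adherence
erases most of that advantage — progression rises above 50% for every
regimen, which is why capsule burden (a driver of adherence) enters the
dose recommendation. Under the default ceilings (progression ≤ 30%,
mortality ≤ 15% at full adherence, then minimal capsule count) the
pipeline recommends the once-daily 2,500-mg regimen (23 capsules):

```
alpopk pipeline --seed 11 --use-presets --out results/
# -> recommended once-daily dose: 2500 mg (23 capsules); ...
```

The same stages are scriptable individually: `alpopk generate` (synthetic
phase-2A-like trial), `alpopk fit` (SAEM, one occasion), `alpopk simulate`
(regimen × adherence grid), `alpopk stats` (regimen comparisons).

## Layout

| module               | contents                                                        |
| -------------------- | --------------------------------------------------------------- |
| `alpopk.pk`          | closed-form structural model, Cmax search, ODE oracle           |
| `alpopk.population`  | random-effect distributions, %CV conventions, residual error    |
| `alpopk.trial`       | synthetic trial generator, NONMEM-dialect CSV dataset I/O       |
| `alpopk.estimation`  | SAEM, OFV/AIC/BIC/BICc, covariate screen, GOF, VPC              |
| `alpopk.regimen`     | virtual-patient simulation, thresholds, adherence               |
| `alpopk.stats`       | odds ratios, chi-square, NNT, regimen comparisons               |
| `alpopk.workflow`    | end-to-end pipeline and dose recommendation                     |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
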