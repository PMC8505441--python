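# labmi — missingness characterization and multiple-imputation benchmarking for EHR laboratory data

Laboratory values in electronic health records are missing for reasons that
are rarely random: tests arrive in panels, sicker patients are tested more,
and a patient who skips one test tends to skip every rarer test as well.
`labmi` is a pipeline for studying that structure and for benchmarking
multiple-imputation (MI) strategies against it. It is aimed at
biostatisticians and clinical-informatics researchers who need to decide
*which* imputation model to trust for lab panels anchored to a disease
index date (one value before the event, one after), when 35–75% of each
analyte is missing.

Because real cohorts of this kind cannot be shared, the package starts from
a fully synthetic but structurally faithful cohort generator, and every
claim the pipeline makes is tested against that generator's known truth.

## What is implemented

**Missingness diagnostics.** For the response indicator
$r_{ij}\in\{0,1\}$ ($1$ = observed) over $n$ subjects and $p$ variables:

- influx $I_j = \#\{(i,k): r_{ij}=0,\ r_{ik}=1\}/\sum_{i,k} r_{ik}$ and
  outflux $O_j = \#\{(i,k): r_{ij}=1,\ r_{ik}=0\}/\sum_{i,k}(1-r_{ik})$,
  the standard fluxplot coordinates;
- a **monotone violation index**: sort variables by missingness, count the
  fraction of (subject, adjacent-pair) cells with the rarer variable
  observed while the commoner one is missing (0 = perfectly nested);
- Welch *t*-tests of comorbidity principal-component scores between
  observed and missing subjects — the probe for an informative
  (not-at-random) mechanism.

**Imputation engines**, written from scratch:

- Type-1 **predictive mean matching** (PMM): Bayesian draw
  $(\dot\beta,\dot\sigma)$ from the normal linear posterior, predictions
  $X\hat\beta$ for donors and $X\dot\beta$ for missing rows, imputation by
  copying one of the $k$ nearest-prediction donors (ties broken uniformly
  per row);
- a **two-level Gibbs sampler** for the random-intercept model
  $y_{it} = x_{it}'\beta + u_i + \varepsilon_{it}$,
  $u_i\sim N(0,\tau^2)$, $\varepsilon_{it}\sim N(0,\sigma_e^2)$
  (homogeneous residual variance, inverse-gamma priors), with imputations
  drawn from the posterior predictive;
- both engines run under a single ordered **monotone** pass or iterated
  **FCS** (chained-equations) sweeps, with repeated MI (m completed sets)
  and Rubin pooling $T = W + (1+1/m)B$.

**Evaluation harness.** Two holdout policies — HV (random observed values
per analyte; MAR-like) and HC (entire complete cases; informative,
monotone-like) — scored by nRMSE $=\sqrt{\tfrac1n\sum(\hat Y_i-Y_i)^2}\,/\,\delta$
(δ = observed-data SD), coverage rate and average width of per-holdout
intervals across the m sets, running mean/SE checkpoints, and
Levene/Shapiro–Wilk/t comparisons with Bonferroni correction.

## Worked example

```python
import numpy as np
from labmi import (preset, generate_complete_cohort, impose_missingness,
                   holdout_values, run_repeated_mi, ImputationSpec,
                   coverage_and_width, nrmse)

cfg, mcfg = preset("gnsis-like", n_patients=2000, n_analytes=12, seed=11)
bundle = impose_missingness(generate_complete_cohort(cfg), mcfg)
table = bundle.observed_labs

masked, mask = holdout_values(table, 20, np.random.default_rng(0))
spec = ImputationSpec(method="multilevel", procedure="fcs", m=10,
                      fcs_iterations=5, gibbs_sweeps=20, seed=0)
sets = run_repeated_mi(masked, spec)
print(coverage_and_width(sets, mask).head(3))
```

prints

```
  analyte    cr         aw  n_holdouts
0   cbc01  0.90   3.575027          20
1   cbc02  0.95  13.226839          20
2   cbc03  0.90  21.476539          20
```

i.e. for each analyte the fraction of the 20 held-out values whose
imputation interval (mean ± t·SD over the 10 sets) contains the truth
(`cr`, nominal 0.95) and the mean interval width in analyte units (`aw`).

The numbered drivers under `analysis/` run the full study on a reduced
cohort and write their tables under `results/`:

```
python analysis/01_synthesize_cohort.py     # cohort files + summary
python analysis/02_profile_missingness.py   # flux, monotone index, PC tests
python analysis/03_benchmark_imputation.py  # policy x algorithm grid
python analysis/04_case_study_auxiliaries.py
```

`03_benchmark_imputation.py`, for example, prints (5 replicate cohorts,
m = 10):

```
HV policy, median nRMSE per algorithm:
algorithm
multilevel-fcs         0.997
multilevel-monotone    1.055
pmm-fcs                1.120
multilevel-FCS below PMM-FCS for 12/12 analytes (7/12 significant after Bonferroni)
FCS at or below monotone for 10/12 analytes
multilevel-FCS by policy (HC = informative complete-case holdout):
         mean  median
policy
HC      1.503   1.494
HV      1.013   1.004
```

— the three qualitative findings the harness is built to measure: the
two-level model beats cross-sectional PMM, FCS iteration beats the single
monotone pass under HV, and holding out complete cases (the informative
missingness scenario) inflates both the error and its run-to-run spread.

A `labmi` command-line interface wraps the same stages
(`labmi synth | profile | impute | benchmark | casestudy`); every command
writes a JSON manifest with the configuration and seeds so any stochastic
output is reproducible from the manifest alone.

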