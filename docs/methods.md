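# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions, and the deliberate design choices behind `labmi`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## The data model

The unit of analysis is a wide **LabTable**: one row per patient, one
numeric cell per (analyte, time block), where the two blocks are the last
valid observation *before* and the first observation *after* the patient's
index date (the first date the disease definition is met). Time is coded
0 = pre, 1 = post everywhere. Preprocessing turns long-format records into
this table by window-limited extraction (a same-day draw counts as
"before"; duplicate records at one offset are averaged with a warning),
masks values outside `[Q1 − k·IQR, Q3 + k·IQR]` per analyte (k = 3 by
default, quartiles by linear interpolation, fences pooled over both
blocks), drops analytes with ≥ 75% pre-block missingness (strict
inequality keeps 74.9%), log-transforms named skewed analytes, and drops
comorbidity codes below 20% prevalence ("at least 20%" keeps a code at
exactly the threshold).

## Missingness diagnostics

With response indicator r (1 = observed), the influx of variable j counts
subject-variable pairs in which j is missing while another variable is
observed, normalized by the total observed-cell count; outflux swaps the
roles and normalizes by the missing-cell count. A 0/0 coefficient is
reported as flagged-undefined rather than 0 or 1 so degenerate variables
are never silently ranked. The monotone index sorts variables by
missingness and counts adjacent-pair nesting violations per subject; under
an MCAR mask at rate q on two variables its expectation is q(1−q), while a
perfectly thresholded utilization pattern scores 0. Mechanism probing runs
PCA on the centered (unscaled by default) binary comorbidity matrix — sign
convention: each component's largest-magnitude loading is positive — and
Welch-tests each component's scores between observed and missing subjects
per variable, Bonferroni-corrected across variables.

## Imputation engines

**Bayesian linear draw.** `beta_hat` is unridged least squares (so an
exact linear fit degenerates to RSS = 0, `sigma* = 0`, `beta* = beta_hat`
exactly); `sigma*^2 = RSS/g`, `g ~ chi2(n − q)`; `beta* = beta_hat +
sigma* L^{-T} z` with `L L^T` the Cholesky factor of the ridge-stabilized
Gram matrix (ridge 1e−5 relative to the mean diagonal — correlated panel
analytes make near-singular designs routine). Over draws, `Cov(beta*) ∝
(X'X)^{-1}` (checked to 15% in Frobenius norm at 5000 draws).

**Type-1 PMM.** Donor predictions use `beta_hat`, missing-row predictions
use `beta*`; each missing row draws uniformly among its k = 5
nearest-prediction donors and copies that donor's actual value, so
imputations are always elements of the observed pool. The k nearest donors
are located in a 2k window of the prediction-sorted donors (verified
equivalent to exhaustive search); exact distance ties at the pool boundary
are broken uniformly and independently per missing row — a shared
tie-break would make all rows copy the same donors and inflate
between-imputation variance severalfold (this failure mode is what the
per-row scheme was written against).

**Two-level Gibbs sampler.** The random-intercept model
`y_it = x_it' beta + u_i + e_it`, `u_i ~ N(0, tau2)`,
`e_it ~ N(0, sigma2_e)` homogeneous across patients, is sampled by full
conjugate sweeps: u given (beta, variances) via per-cluster precisions
(empty clusters fall out of the formula as prior draws), beta given
(u, sigma2_e) under a flat prior, then both variances from inverse-gamma
full conditionals with IG(0.001, 0.001) priors (weakly informative
conjugate defaults; exposed in `GibbsPriors`). Imputations are posterior
predictive draws at the final state. Parameter recovery (beta within 0.15,
variances within 0.25 of truth on 500 clusters × 2 rows, 2000 sweeps) is
an acceptance test. A random TIME slope is deliberately not implemented as
a default — the two-row-per-cluster design gives it essentially no
identification — and the fixed TIME effect plus random intercept is the
model the benchmark exercises.

**Procedures.** The monotone procedure imputes targets in ascending order
of missingness, each conditioned on initially complete variables and
previously imputed ones; FCS starts from uniform draws of each variable's
observed values and revisits every incomplete variable in column order for
a configurable number of sweeps, emitting a per-sweep imputed-cell
mean/SD trace as the convergence diagnostic (the default 20 sweeps is a
desk-scale choice; the trace is how a user verifies adequacy, and chains
are stationarity-tested under MCAR in the suite). Predictor sets encode
the cross-sectional vs longitudinal contrast that the benchmark is about:
PMM (the cross-sectional benchmark) sees only same-block columns, while
the multilevel method stacks both blocks of the target with TIME and
same-block covariates, so post-event information reaches a missing
pre-event value only through the shared patient intercept. Per-target
predictor overrides are available on `ImputationSpec`.

Randomness is keyed per (sweep, variable) event from a root drawn once
from the caller's generator; repeated MI derives one child stream per
completed set from `(seed, set index)`, so any single set is reproducible
in isolation and FCS with one sweep on a single incomplete variable
coincides exactly with the monotone pass.

## Evaluation conventions

nRMSE divides the holdout RMSE by the analyte's **observed (non-held-out)
pre-block SD** — the only scale available at prediction time (truth-SD is
available as an option). One "repeat" is one completed imputation set.

Per-holdout intervals are `mean ± t(0.95, m−1) · SD` of the m imputed
values. The SD of the imputed values — not the SD of their mean — is the
spread of plausible values for that cell, and it is the quantity a
calibrated imputer should cover the truth with at the nominal rate; an
interval built on SD/√m shrinks to zero as m grows and makes nominal
coverage unattainable for any imputer, so it cannot be the intended
diagnostic. A zero-width interval covers iff it equals the truth to 1e−12,
which makes the degenerate all-sets-identical cases well defined.

The case-study metrics compute a truth-imputation Pearson R per completed
set, then average: SE = SD(R)/√m, CV = SD(R)/mean(R), and CR/AW are the
proportion of per-set Fisher-z 95% intervals containing the average R and
their mean width. Both coverage conventions (holdout-truth for
`coverage_and_width`, R-based for `case_study_metrics`) are intentional
and serve different questions.

Algorithm comparisons follow the benchmark recipe literally: Levene
(center = mean) for variance equality, Shapiro–Wilk on the per-repeat
difference for normality, and an **unpaired** two-sided t-test (kept
unpaired deliberately, although the vectors are paired by repeat) with
Bonferroni threshold alpha / n_tests.

## The synthetic cohort generator

Complete values follow
`value = mean_j + time_effect_j · t + sd_j · z`, with latent
`z = (lambda · burden + u + e) / normalizer`: `burden ~ N(0,1)` is the
patient's disease-burden factor (lambda = 0.35 in the presets; 0 by
default so the intraclass-correlation arithmetic of the base config is
exact), `u` the patient intercept shared across blocks, and `e` the
per-block residual, both panel-correlated (compound symmetry 0.5 within /
0.1 between panels). The before/after correlation is
`(sd_u^2 + lambda^2)/(sd_u^2 + lambda^2 + sd_e^2)` ≈ 0.5 in the presets,
the center of the range real cohorts show. Comorbidity codes are Bernoulli
with `logit = logit(p_k) + burden`, marginal prevalences spanning 5–50% so
the 20% prevalence filter has something to drop.

Missingness under the informative mechanism thresholds a utilization score
`u_i = loading · burden_i + noise` per variable in ascending target-rate
order — one score, nested thresholds, hence a monotone pattern in which
sicker patients (positive loading) are observed more. A fraction
`1 − monotone_weight` (default 0.2) of each rate is an arbitrary Bernoulli
admixture OR-ed on top, with its propensity correlated within panels
(Gaussian copula, 0.95 in the presets): providers order or skip panels,
not single analytes, and per-cell-independent noise would leave
essentially no complete cases at 45 analytes. With the panel-correlated
admixture the full-scale preset keeps a ~4% complete-case minority
(roughly 400 of 9037), the order observed in real stroke cohorts, and
~13–15% at the reduced 12-analyte scale. MCAR masks cells independently;
MAR thresholds a score built from the observed comorbidity count instead
of the latent burden.

Presets: `gnsis-like` (45 analytes / 9037 patients, pre-block rates
36–74%, post clearly lower) and `hf-like` (38 analytes / 5192 patients,
both blocks 58–74.5%, pre ≈ post). Analyte means/SDs are a smooth sweep of
magnitudes (SD ≈ 15% of mean) — the benchmark metrics are scale-normalized,
so only the correlation structure matters.

**What the generator does not emulate.** Real lab panels have heavy-tailed,
bounded, unit-heterogeneous distributions; the generator is Gaussian, so
PMM's semi-parametric advantage on skewed data is not exercised. The
comorbidity matrix has a single latent factor, so five PCs explain ~34% of
its variance rather than the >60% typical of real ICD code matrices, and
the auxiliary-variable gain in the case study is correspondingly modest
(directionally positive, about +0.02 average R over replicates).
Repeated measurements within a block exist only as decoy records for the
extraction step. Passing tests therefore demonstrate correctness of the
machinery and the direction of the methodological contrasts under a known
mechanism — not effect sizes transferable to any particular health system.

## Benchmark study sizes

The benchmark grid runs at a desk scale chosen once: 2000 patients ×
12 analytes per replicate cohort, 20 replicate seeds with m = 20 sets for
the test-suite grid (6 seeds × m = 10 in the acceptance script), 20 HV
holdouts per analyte and 20 HC complete cases (the two policies are kept
at equal per-analyte cell counts because the "HC inflates the SE of
nRMSE" comparison is an averaging artifact if the counts differ), FCS at
5 sweeps and 20 Gibbs sweeps per multilevel visit. The univariate
case-study arm uses m = 10–20 with 100 Gibbs sweeps and 50 holdouts of the
highest-missingness analyte. At these sizes the full suite runs in ~6
minutes and the acceptance script in ~1 minute on one CPU.

## Known limitations

- The monotone procedure assumes the pattern is close to nested; on
  strongly arbitrary patterns its early targets are fit on imputed
  predictors, which is exactly the regime where FCS wins in the benchmark.
- The Gibbs imputer draws from the final sweep's state; for very short
  chains consecutive sets are nearly independent only because every set
  restarts from its own child stream.
- The heterogeneous within-patient-variance variant of the two-level model
  is out of scope; so are joint-model and EM-based MI.
- Figure rendering is out of scope; every diagnostic emits the table
  behind the plot instead.
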