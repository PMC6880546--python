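# Methods

## The score

A DNAm alcohol score is a pure weighted sum over a fixed CpG set,

    score_s = Σᵢ βᵢ · meth[s, CpGᵢ],

with no intercept or rescaling: every downstream statistic used here
(R², adjusted R², AUC, regression p-values) is invariant to the score's
location, and AUC also to any strictly monotone transform. Users comparing
against other score calculators should note some add an intercept; this one
deliberately does not. Coefficient sets come in nested families — each
smaller set's CpGs are a subset of every larger set's — and the loader
enforces that nesting, duplicate-free sets, and finite non-zero weights.

Probe attrition (e.g. scoring EPIC-array data with 450K-derived
coefficients) is handled by `missing_policy`: `error` (default, refuses
below a 0.95 coverage floor), `drop` (omit missing CpGs, record coverage),
and `impute-zero`, which is accepted only on residualized input, where 0 is
the covariate-predicted mean and therefore the only defensible imputation.

## Residualization

Each CpG column is replaced by its residual from OLS on an intercept plus a
named adjustment set, fitted within each time point separately on the
complete-case sample (listwise deletion, logged). Standard sets: age, sex,
BMI and white-blood-cell proportions for adult/adolescent/childhood waves;
the pregnancy set omits sex (all-female collection); the birth set uses
gestational age (weeks), sex, birthweight (g) and cord cell proportions.
"+smoking" variants add a binary smoking indicator for sensitivity reruns.

Two rank-preserving rules are applied automatically with logged warnings:
if the cell-proportion block sums to 1 the last cell column is dropped
(residuals remain orthogonal to all of them, since the dropped column is a
linear combination of the intercept and the rest), and constant columns
(sex in an all-female wave, a constant smoking indicator) are dropped.
Any remaining rank deficiency is a hard error naming the collinear columns.

Because both operations are linear, scoring a residualized matrix equals
residualizing the raw scores on the same covariates; the test suite asserts
this commutation as a cross-check.

## Phenotypes

Intake in grammes of ethanol per day is `occasions/week × units/occasion ×
8 / 7` (one UK unit = 8 g ethanol). Questionnaire frequency categories map
to occasions/week through a declared midpoint convention — never = 0,
monthly or less = 0.25, 2–4/month = 0.75, 2–4/week = 3, 4+/week = 5 —
which is configurable; surveys do not publish their exact mapping, so this
is a convention, not a reconstruction. "Never" yields 0 regardless of
reported quantity. The continuous analysis variable is the natural log
`ln(g/day + 1)` ("log" is taken as natural, the default of the usual
analysis environments; configurable).

Drinker categories are sex-specific: non-drinkers report exactly 0 g/day;
women — light (0, 14], at-risk (14, 28), heavy ≥ 28; men — light (0, 28],
at-risk (28, 42), heavy ≥ 42. The heavy thresholds are the unambiguous
anchors and take precedence at the boundaries; the interior boundaries
close on the light side. AUDIT totals lie in [0, 40], self-reported
non-drinkers score 0, and the high-risk dichotomy is strictly > 15.

## Evaluation

OLS fits go through statsmodels; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1)
and may be negative (reported as-is). p-values are nominal two-sided
t-tests; no multiple-testing correction is applied anywhere. Report tables
carry fractions ×100 rounded to 2 decimals at presentation only.

AUC is computed from the tie-grouped ROC curve by the trapezoidal rule,
which equals the Mann–Whitney probability that a random positive outscores
a random negative with half credit for ties; the test suite verifies exact
agreement with an O(n²) pairwise enumeration.

The **refit comparison** re-estimates coefficients for a set's CpGs in the
evaluation sample itself (alongside age/sex/BMI) and contrasts the fit with
the fixed-coefficient score on identical data. Because the fixed score is a
linear combination of the refit design's columns, the refit's unadjusted
in-sample R² can never be smaller — an exact span property — and on pure
noise the gap between its in-sample and out-of-fold R² is the overfitting
inflation the comparison exists to expose. Designs with parameter count ≥ n
are refused, never regularized.

## The longitudinal confounding test

If a methylation score were driven mainly by stable genetic or early
environmental factors, a score from blood drawn years earlier would predict
later AUDIT about as well as a concurrent score. The design fits three OLS
models on the complete-case paired subsample (early alone, concurrent
alone, both jointly). Scores are standardized to unit variance within the
paired subsample by default so coefficients are per-SD and comparable
across simulations; a raw-scale option exists. Identical early/concurrent
vectors raise a collinearity error; pairings of ≤ 10 samples are refused.
The mother–child extension adds the maternal pregnancy score alongside the
offspring birth and adolescent scores (pairing by family in the simulated
cohorts).

## Synthetic cohort generator

The generator emulates the cohort structure the pipeline needs — a
two-generation longitudinal study with repeated methylation — with all
latent drivers jointly Gaussian:

* stable per-person component `g` (abstract genotype/fixed environment),
  mother–child correlation 0.5;
* long-run drinking propensity `u`; occasion-level draws
  `z = ρ·u + √(1−ρ²)·ε` with ρ = 0.5, one per unit of drinking history;
* intake: the most recent draw is quantile-mapped onto a zero-inflated
  log-normal. The log-normal (μ, σ) is solved (sex-averaged, via the
  sex-specific g/day thresholds) so the drinker-category mixture matches
  the configured fractions — default 5% non, 71% light, 22.5% at-risk,
  1.5% heavy, the approximate composition of a general-population midlife
  cohort;
* AUDIT: for current drinkers, `round(clip(8.5 + 4·(θ·M + √(1−θ²)·e), 0, 40))`
  with driver `M ∝ 0.8·u + 0.2·z` (alcohol-use disorder reflects mostly
  sustained behaviour); current non-drinkers score exactly 0.

Methylation is simulated on the logit scale and inverse-transformed (no
boundary pile-up; clipping fraction is 0 by construction):

    logit(beta_ij) = logit(μⱼ) + λ·wⱼ·D_i(t) + covariate terms + noise,

with per-CpG baselines μⱼ ~ U(0.2, 0.8), logit-scale noise sd ~ U(0.15,
0.35), small random covariate loadings (age, sex, BMI, Dirichlet cell
proportions, smoking, and gestational age/birthweight at birth), and wⱼ the
largest set's weight for CpG j. The driver D depends on the effect mode:
concurrent standardized log intake (`exposure_concurrent`), the
standardized (optionally decay-weighted) mean over the drinking history
(`exposure_cumulative`), the stable component g at every wave
(`genetic_stable` — the confounded scenario, where u also loads on g),
nothing (`null`), or concurrent intake plus a drinking-correlated smoking
term (`smoking_confounded`). Waves flagged as non-drinking (pregnancy,
birth, childhood) carry zero alcohol signal in the exposure modes but still
carry g in the genetic mode — exactly the discriminating fact the
longitudinal test must detect.

### Calibration

Effect sizes are specified as target R² values and solved internally.
Writing dⱼ = μⱼ(1−μⱼ) for the local slope of the inverse logit, the
score's signal coefficient is c = λ·Σwⱼ²dⱼ and its noise variance
v = Σwⱼ²σⱼ²dⱼ², so λ = √(ψ·v/(1−ψ))/Σwⱼ²dⱼ delivers signal fraction ψ.
In concurrent mode ψ is the target score–intake R² (the driver *is*
standardized log intake, so the in-sample target is exact up to sampling
noise and second-order logit curvature, both verified small); in cumulative
mode ψ is the score–driver signal fraction; in genetic mode ψ is the score
reliability across waves (default 0.85, which makes an individual's scores
correlate > 0.8 across time by construction).

The AUDIT noise parameter θ is solved from
`target = ψ · corr(D, M)² · θ²`, with corr(D, M) computed analytically —
Gauss–Hermite quadrature through the nonlinear z → log(intake+1) map in the
concurrent modes, closed form otherwise — so the feasibility bound
ψ·corr(D, M)² is deterministic given the config, and infeasible targets
fail fast with that bound reported. The bound has a scientific reading: a
score driven by concurrent intake cannot explain AUDIT (a long-run
behaviour) better than intake itself does. The default AUDIT target
(0.025) therefore sits below the concurrent-mode bound (≈ 0.032 at intake
target 0.08); the pattern of AUDIT being explained *better* than intake
emerges only in cumulative mode, where the methylation driver is closer to
the long-run propensity than any single intake report.

Two realized-versus-latent caveats, both deliberate: forcing AUDIT = 0 for
non-drinkers adds real signal beyond the latent θ-path (realized AUDIT R²
runs above its latent target), and integer rounding/clipping attenuates
slightly. Ground truth (latents, solved constants, implied latent R²
values, achieved category mixture) is stored on the cohort and in the
written sidecars; identical config + seed reproduces byte-identical output
files.

### What the generator does not emulate

No array batch/dye artifacts, no bimodal probe-type structure, no
genotype at base-pair resolution (g is an abstract stable component), no
missing-data patterns, and covariates are independent of drinking by
default. The temporal decay of alcohol-related methylation is unknown; a
decay half-life parameter exists but the defaults make no claim about its
value. Passing tests therefore demonstrate the *statistical machinery* —
calibration, estimation, error rates — not fidelity to any real cohort's
noise structure.

## Experiment design and problem sizes

The packaged experiments run at the cohort sizes the pipeline is validated
against: 1018 mother–child pairs for full-cohort runs, n = 1049 for
parameter recovery (200 seeds), n = 518 pairs for the longitudinal
operating characteristics (2000 null simulations; 300 power simulations,
power ≈ 0.98 at the default genetic-mode effect), 200 replicates of the
overfitting experiment at n = 500 with 144 noise CpGs, and 200 seeds of the
cumulative contrast. The cumulative contrast compares a 30-year history
generation against a 1-year (recent-onset) generation with identical
concurrent intake distributions; its effect sizes (signal fraction 0.20,
AUDIT target 0.15) were chosen so the two generations' latent R² differ by
about three per-seed standard errors, giving the directional comparison
honest per-seed reliability after discretization losses.

One sampling-theory fact worth stating: a single cohort's estimated
adjusted R² at n ≈ 1000 and true R² = 0.08 has a standard deviation of
about 0.016 (≈ 2ρ(1−ρ²)/√n). Multi-seed means recover the target to ±0.01
easily, but individual seeds routinely land 0.03–0.05 away; tests and
users should judge calibration on means, not single draws.

## Known limitations

* The parent generation is simulated as mothers only; the midlife
  adjustment set's sex column is dropped by the constant-column rule.
  Mixed-sex parental cohorts would need an explicit father component.
* The maternal extension's mother–child pairing uses the simulated family
  ids; file-based inputs must supply maternal scores already keyed by
  offspring id.
* Latent AUDIT targets are calibrated on the pre-rounding scale; realized
  values differ for the two reasons above.
* Coefficient weights are treated as exact; uncertainty in the published
  coefficients is out of scope, as is re-estimating them.
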