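# methalc

Validation pipeline for **DNA methylation alcohol scores** (DNAm-Alc):
weighted sums of blood methylation beta values at fixed CpG sites, used as
biomarkers of alcohol intake and alcohol-use disorder.

The package is aimed at epigenetic epidemiologists who want to evaluate a
published CpG coefficient set on their own cohort — or on a simulated one —
rather than re-derive it. It implements the full evaluation pattern:

1. **Scoring** — `score_s = Σᵢ βᵢ · CpGᵢ,ₛ` over a nested family of
   coefficient sets (5/23/78/144 CpGs); no intercept, so only score
   variation matters downstream.
2. **Residualization** — each CpG is replaced by its OLS residual on
   age, sex, BMI and white-blood-cell proportions (time-point-specific
   adjustment sets; smoking as a sensitivity variant) before scoring.
3. **Phenotypes** — intake in grammes ethanol/day from frequency × quantity
   (1 UK unit = 8 g), `log(g/day + 1)`, sex-specific drinker categories
   (heavy ≥ 28 g/day women / ≥ 42 men), AUDIT (0–40) dichotomized at > 15.
4. **Evaluation** — variance explained (R², adjusted R²) by OLS; ROC/AUC
   (Mann–Whitney with half-credit ties) for binary contrasts; an in-sample
   *refit comparison* that quantifies how much re-estimating CpG
   coefficients in the evaluation sample inflates apparent performance.
5. **Longitudinal confounding test** — regress AUDIT on the score from an
   earlier blood draw, the concurrent draw, and both jointly. A null early
   coefficient with a strong concurrent one argues the score tracks alcohol
   exposure itself rather than stable genetic/environmental confounders.
6. **Synthetic cohorts** — a two-generation longitudinal generator
   (mothers at pregnancy + midlife; children at birth, childhood,
   adolescence) with known ground truth: stable per-person components,
   zero-inflated log-normal intake, AUDIT as a noisy monotone function of
   long-run drinking, and effect modes (`exposure_concurrent`,
   `exposure_cumulative`, `genetic_stable`, `smoking_confounded`, `null`)
   whose effect sizes are solved internally from target R² values.

Real published coefficients are **inputs** (TSV with columns
`cpg`/`weight`/`set`); the bundled family in
`src/methalc/data/dnamalc_synthetic_coefs.tsv` is synthetic, with the same
nested 5/23/78/144 structure.

## Worked example

A one-shot validation run on a simulated 1018-pair cohort in
concurrent-exposure mode (target score–intake R² = 0.08):

```yaml
# run.yaml
out_dir: demo_out
seed: 7
simulate: {n_pairs: 1018, mode: exposure_concurrent}
```

```bash
methalc run --config run.yaml
```

`demo_out/r2.tsv` (intake rows shown) reports variance explained per
coefficient set — rising with set size and landing near the simulated 8%
for the full 144-CpG score:

```
 time_point    outcome         set  n_cpgs    n  r2_pct  adj_r2_pct
    midlife log_intake   dnamalc.5       5 1018    0.00       -0.10
    midlife log_intake  dnamalc.23      23 1018    2.19        2.10
    midlife log_intake  dnamalc.78      78 1018    4.60        4.50
    midlife log_intake dnamalc.144     144 1018    8.05        7.96
```

`demo_out/longitudinal.tsv` shows the earlier-vs-concurrent test for the
mothers: the pregnancy-era score (drawn ~21 years before the outcome, when
the generator assigns no drinking) predicts nothing, while the concurrent
midlife score is strongly associated — the signature of a score driven by
exposure rather than by stable confounding:

```
Dependent variable Independent variable(s)    N             beta             SE           p value  Adjusted R2
  AUDIT at midlife               pregnancy 1018         -0.08391         0.1317            0.5243        -0.06
  AUDIT at midlife                 midlife 1018           0.9309         0.1285         8.499e-13         4.82
  AUDIT at midlife     pregnancy + midlife 1018 -0.05092, 0.9291 0.1286, 0.1286 0.6922, 9.896e-13         4.74
```

(β is per SD of score; adjusted R² in percent.) The bundle also contains
the AUC table, the refit/overfitting comparison, sensitivity variants
(non-drinkers excluded; smoking-adjusted residualization), the mother–child
extension and a run manifest. Individual stages are available as
`methalc simulate|residualize|score|evaluate|longitudinal`, and as library
functions (`methalc.compute_score`, `methalc.residualize_matrix`, ...).

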