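# Methods note

This note documents the statistical models implemented in `pubertwin`, the
reasoning behind parameter defaults, what the synthetic generator does and
does not emulate, and the package's known limitations.

## 1. Synthetic cohort generator

**Model.** Methylation at each CpG is generated directly on the beta-value
scale as

```
m = baseline + total_sd · (√a2·G + √c2·C + √d2·D + √e2·E) + linkage + covariate terms
```

with the latent standard-normal factors shared within a pair at correlation
1/0.5 (G, by zygosity), 1/1 (C), 1/0.25 (D) and 0 (E), then clamped to
[0.001, 0.999]. Gaussian-on-beta generation preserves the exact twin
correlation algebra `r_MZ = a2 + c2 + d2`, `r_DZ = a2/2 + c2 + d2/4` that the
variance-decomposition tests rely on; a logistic latent would distort it.
Clamping is monitored and a warning is raised if it touches more than 1% of
the values of any CpG; the `total_sd ≤ 0.2` cap keeps it negligible in
practice.

**Linkage modes** tie methylation to the latent pubertal-timing phenotype in
three distinct ways — `causal_individual` (each twin's own phenotype),
`family_confounded` (the pair's shared-environment factor) and
`genetic_confounded` (the pair's genetic factor) — so that the
discordant-pair module has scenarios it should and should not flag.

**Phenotypes.** A standardized pubertal-timing liability with ACE structure
(defaults a2 = 0.5, c2 = 0.2) underlies the questionnaires. Ordinal puberty
items are threshold cuts of a noisy copy of that liability (items run 1–3 at
the age-12 wave and 1–4 at the age-14 wave; menarche is coded {1, 4} and
facial hair 1–3 at both waves). Pubertal-age reports are right-censored at
the reporting age; females mature earlier on average via a mean shift.

**Cohort composition defaults** (`CohortConfig`): 400 families, 1/3 MZ, half
of DZ pairs opposite-sex, 54.6% female, 5% singleton families, two birth
cohorts with different sampling-age distributions, two platforms at a 60/40
split, six chip dates, eight array rows, smoking (never/current/former =
0.55/0.30/0.15), gamma-distributed alcohol intake, and Dirichlet cell-type
proportions around a whole-blood composition. The MZ:DZ ratio and
opposite-sex share are exposed parameters because no single canonical value
exists for a volunteer twin sample.

**meQTL tables.** Genotypes respect twin sharing (MZ cotwins identical, DZ
cotwins drawn by independent parental transmission); associations are tested
in one twin per family to avoid familial pseudo-replication.

**Seeding.** Every generator takes an explicit seed; per-CpG streams are
spawned from a single `SeedSequence`, so extending a spec list never perturbs
values already generated for earlier CpGs.

## 2. Phenotype scoring

The pubertal development scale is the mean of five ordinal items (sum / 5).
Records with any missing item are excluded (a counted exclusion, not an
error); out-of-range codes are input errors that name the offending item.
Pubertal age passes observed event ages through, codes "not yet happened" as
age 17, and excludes missing or internally inconsistent reports (event age
after the reporting age).

Covariate preparation expands smoking to current/former indicators (never =
reference), drops one cell-type column (the six proportions sum to one), and
codes chip date and array row as indicators against their first level.
Constant columns are dropped with a warning so designs stay full rank in
small or homogeneous subsets.

## 3. Family-clustered EWAS

Each CpG is regressed on an exposure plus covariates. Cotwin residual
dependence is handled in two steps:

1. **Consensus correlation.** Per CpG, OLS residual cotwin correlations over
   complete pairs are Fisher-z transformed, pooled by a 10% trimmed mean
   across CpGs, and back-transformed. A single pooled value is stable where
   per-CpG estimates are noisy, and the trimming guards against outlier CpGs.
2. **GLS.** The pooled correlation enters a block-diagonal residual
   correlation matrix (2×2 blocks for complete pairs, 1 for singletons),
   implemented by per-block Cholesky whitening. At rho = 0 this reduces
   exactly to OLS (a tested identity).

**Moderated statistics.** Residual variances across CpGs are shrunk toward a
scaled inverse-chi-square prior fitted by moment matching on the
log-variance scale (digamma/trigamma identities; the trigamma inverse by
Newton iteration). The moderated t uses the posterior variance on `d0 + d`
degrees of freedom; `d0 → 0` reproduces the ordinary t and `d0 → ∞` the
common-variance z test (both tested limits). When the observed log-variance
spread does not exceed the sampling spread, `d0 = ∞` is returned.

**QC.** Test-statistic bias and inflation are summarized as the median and
the normal-consistent MAD (1.4826·MAD) of the z-scores — robust location and
scale estimates that ignore a moderate fraction of true signals.

**Covariate-set choice** among candidate designs is by per-CpG AIC votes,
with exact ties resolved toward fewer columns.

## 4. Meta-analysis

Per-platform t statistics are converted to partial correlations
`r = t/√(t² + df)` with sampling variance `(1 − r²)²/df` — an effect size
comparable across platforms with different sample sizes and covariate
counts. Only CpGs present on both platform panels are analysed.

Fixed-effect inverse-variance estimates are the default. Cochran's Q is
computed per CpG; Q p-values are Benjamini–Hochberg adjusted across all
analysed CpGs, and CpGs with adjusted Q p < 0.01 are re-estimated with
DerSimonian–Laird random effects. Significance tiers: strict at
p ≤ 2.4×10⁻⁷ (array-wide threshold), suggestive at p ≤ 1×10⁻⁵; a separate
flag marks |r| > 0.13. The BH step-up is implemented directly (and
cross-checked against `statsmodels.stats.multitest` in the tests).

## 5. Twin variance decomposition

Per pair, methylation is bivariate normal with common mean structure
(intercept plus optional age and sex regressors) and covariance determined
by nonnegative path coefficients: `var = a² + c² + d² + e²`,
`cov_MZ = a² + c² + d²`, `cov_DZ = a²/2 + c² + d²/4`. C and D are never
fitted together (the classical design identifies at most one). Incomplete
pairs contribute univariate likelihood terms. Optimization is multi-start
L-BFGS-B on the path coefficients; the path parameterization enforces
nonnegative variance components by construction.

**Model selection** fits ACE, ADE, AE, CE, DE and E. Within each family
(ACE: {ACE, AE, CE, E}; ADE: {ADE, AE, DE, E}) a reduction is accepted when
its likelihood-ratio test against the family's full model is non-significant
at α = 0.05, and the most parsimonious accepted model wins; the two family
winners are arbitrated by AIC (ties → fewer parameters → the ACE family).

**Confidence intervals** are profile-likelihood (χ²₁ at 0.95), reported on
the standardized scale; bounds that cannot be bracketed because a parameter
sits on its boundary are reported as undefined rather than forced.

**Candidate eligibility** before modelling: a minimum methylation SD
(default 0.05) and four likelihood-ratio assumption checks against a
saturated pair model (means and variances equal across twin order and
zygosity) at α = 0.01.

**Twin correlations** are double-entry intraclass correlations after OLS
residualization on the available mean regressors.

## 6. Sex differences

Mean methylation differences use a two-sample rank test (normal
approximation with tie and continuity correction), Bonferroni-corrected over
the tested CpGs, significant at adjusted p < 0.01.

The five-group sex-limitation model (MZ male, MZ female, DZ male, DZ female,
DZ opposite-sex) gives every parameter a sex index; the opposite-sex DZ
covariance is `rg·a_m·a_f + c_m·c_f` with the genetic cross-correlation rg
bounded in [0, 0.5] (0.5 means the same genes act in both sexes; the
shared-environment cross-correlation is fixed at 1 by convention).
Quantitative differences are tested by likelihood-ratio tests equating
parameters across sexes (omnibus first, then one parameter at a time:
mean structure, unstandardized A, unstandardized E, total variance);
the qualitative difference by fixing rg = 0.5. Equality constraints are
imposed directly in the SLSQP fit, so constrained models are exactly nested.
Per-parameter tests are Bonferroni-corrected, significant at adjusted
p < 0.01.

## 7. Discordant-pair analysis

Exposures decompose into `between = (x1 + x2)/2` per pair and
`within = x_self − x_cotwin` per twin (antisymmetric; concordant pairs have
within = 0 but still inform the between effect; incomplete pairs are excluded
with a reported count). The mixed model

```
y = β0 + βB·between + βW·(within/2) + γ·covariates + u_family + ε
```

is fitted by REML with a family random intercept. The within regressor is
half the cotwin difference — each twin's deviation from the pair mean — so a
purely individual-level exposure effect yields βW = βB while purely familial
confounding yields βW = 0; this scale makes the two coefficients directly
comparable. A CpG is classified as showing a within-pair difference when the
pooled (MZ + DZ) within effect has p < 0.05 and the MZ-only within effect has
p < 0.10 with the same sign.

## 8. meQTL integration

Per-CpG counts of associations with p strictly below 5×10⁻⁸, with a
cis/trans breakdown when available; duplicate (SNP, CpG) rows are input
errors reported by name, and CpGs absent from the table count zero. Counts
are correlated with heritability estimates by Spearman rank correlation
(midrank ties); constant inputs leave the correlation undefined (NaN) rather
than raising.

## 9. Pipeline and reproducibility

`run_full_analysis` chains simulate → phenotype scoring → per-model,
per-platform EWAS (with moderation when ≥ 10 CpGs) → meta-analysis →
candidate selection (any suggestive-tier hit; best model per CpG) →
twin modelling, sex-difference testing, discordant-pair analysis and meQTL
correlation of the candidates. Stage failures raise `StageError` naming the
stage; an empty candidate set short-circuits gracefully. Every output TSV
embeds the SHA-256 configuration hash (first 16 hex digits) and seed in a
header comment, and reruns are byte-identical. Seven analysis models are
configured by default: the age-12 development score in everyone and per sex,
the age-14 score per sex, and pubertal age per sex.

## 10. Build-versus-buy choices

Standard numerics are delegated to established libraries: the mixed model to
`statsmodels.MixedLM`, distributions and rank statistics to `scipy.stats`,
optimization to `scipy.optimize`. Hand-rolled, with oracle tests, are the
pieces whose exact behaviour is the point: the FIML twin likelihoods, the
GLS whitening, the variance-prior moment matching, the partial-r conversion,
the meta-analysis estimators and the BH step-up (cross-checked against
`statsmodels`).

## 11. What the generator does not emulate

- Probe-level artefacts (type I/II probe chemistry, cross-reactive probes,
  detection p-values) — methylation is clean Gaussian-on-beta.
- Genomic context: CpG positions, chromosomes and cis/trans labels are
  synthetic bookkeeping, not a genome map.
- Longitudinal methylation: arrays are sampled once; the two questionnaire
  waves share a single liability rather than modelling developmental change.
- Population structure and assortative mating; parental genotypes are drawn
  under Hardy–Weinberg equilibrium.
- Missingness mechanisms beyond simple singleton families and questionnaire
  exclusions.

## 12. Limitations

- The DerSimonian–Laird heterogeneity step with two platforms estimates tau²
  from a single degree of freedom; it is triaged (BH over Q) to keep it
  rare, but per-CpG random-effects estimates are noisy by construction.
- The consensus residual correlation is a single pooled value; CpGs with
  genuinely atypical familiality are mildly mis-whitened (type-I error for
  these remains controlled in the tested regimes).
- Profile CIs refit the likelihood along one path coefficient; with
  components at the boundary the interval ends are undefined by design.
- AE fits at correlation patterns far from AE structure (e.g. r_DZ well
  below half of r_MZ) converge to a maximum-likelihood compromise that
  weights the larger MZ information; recovered heritabilities can sit
  slightly below the r_MZ value, which is expected behaviour, not a bug.
- The sex-limitation model fixes the shared-environment cross-sex
  correlation at 1 and bounds rg in [0, 0.5]; likelihood surfaces near those
  bounds make the qualitative test conservative.
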