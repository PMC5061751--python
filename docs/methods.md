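# Methods

This note documents the statistical models implemented in `pleioscan`,
the synthetic data that exercises them, the numerical choices, and the
known limitations. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Univariate association models

All models use additive minor-allele coding (dosage 0/1/2).

**Longitudinal quantitative traits.** Linear mixed model
`value ~ dosage + age + sex + C(center)` with random intercepts for
individual nested in family, fitted by REML (statsmodels `MixedLM`).
The random structure degrades gracefully with the design: the family
intercept is dropped when every family is a singleton, the individual
intercept when every subject has one visit, and the model collapses to
OLS when both hold (verified exactly in tests). Wald inference on the
dosage coefficient. Skewed positive traits can be transformed with
`assoc.log_transform` (100·ln x) before fitting.

**Cross-sectional binary traits.** Logistic regression; the
coefficient is a log-odds ratio (prevalence data), not a log-hazard.

**Time-to-event traits.** Marginal Cox proportional-hazards model via
lifelines, Efron tie handling, sandwich variance clustered on family id.
The default time scale is **age with left truncation at study entry**,
matching age-at-onset outcomes and the age-dependence analyses; a
follow-up-time mode (entry age as covariate) is provided. Age is
therefore never a covariate in the event models.

**Fast scan engine.** Calibration and power studies need 10³–10⁴
per-SNP statistics against *fixed* phenotype data. The
`_fastscan`/`_fastcox` engines fit each phenotype's null model once and
derive per-SNP statistics as (a) exact GLS Wald statistics after
whitening by the REML-estimated random-effect covariance (the standard
two-stage device used by fast mixed-model GWAS methods), (b) Rao
efficient scores from the null GLM, and (c) efficient score statistics
from the null Cox model with the nuisance-information correction
I_gg − I_gx I_xx⁻¹ I_xg. Breslow ties are used internally (simulated
ages are continuous). Tests pin the fast engines to the exact refits
(GLS = OLS/MixedLM; score z within 0.1 + 10% of Wald z near the null;
weighted Cox vs lifelines to 1e−3) and the null-z standard deviations
to ≈ 1.

## 2. Omnibus test and meta-analysis

T = z′Σ⁻¹z with z the per-phenotype z-scores of one SNP in one cohort
and Σ the null z-score correlation. Under H₀, T ~ χ²_K.

* **Σ estimation.** z-scores of SNPs simulated under HWE (default 1000;
  fewer than 50 is refused) scanned against the cohort's actual
  phenotype data — only genotypes are regenerated, so the cross-trait
  correlation (including the O(1/√n) component conditional on the
  realized phenotypes) is preserved. Pearson correlation matrix; if the
  smallest eigenvalue falls below 1e−8 a ridge of 1e−6 is added and the
  diagonal renormalized; the condition number is recorded. MAFs for the
  simulated SNPs resample the candidates' observed MAFs, with a
  uniform(0.02, 0.5) fallback.
* **Normality check.** Henze–Zirkler test with the standard bandwidth
  b = 2^{−1/2}[(2p+1)n/4]^{1/(p+4)} and the lognormal null
  approximation, implemented for any dimension p ≥ 1 (the installed
  reference implementation requires p ≥ 2 and is used as the oracle for
  p ≥ 2 in tests, agreement to 1e−10).
* **Phenotype-subset selection.** Greedy: while any |Σ_kl| ≥ 0.7, drop
  the lower-priority member of the worst pair; the drops are returned as
  an audit trail. Priority is a caller-supplied order (convention:
  diseases before endophenotypes, then alphabetical).
* **Solving.** Σ⁻¹z via a symmetric positive-definite Cholesky solve,
  never an explicit inverse; a ridge retry guards indefinite subsets.
* **Fisher combination.** −2Σ ln p ~ χ²_{2m}; p-values are floored at
  1e−300 with a warning before the log. Used both for the uncorrected
  pre-selection screen across phenotypes (candidate rule: MAF > 0.02 and
  combined p < 5e−8) and across cohorts on the omnibus p_j. Cohorts in
  which a SNP is missing or failed QC drop out and the df adjusts to
  2 × (contributing cohorts). Σ is estimated once per cohort over all
  phenotypes and subset per analysis group
  (endophenotypes / diseases / both).

## 3. QC

Subjects with overall missing rate > 5% are removed first; then per
SNP: HWE 1-df chi-square against expected counts from the allele
frequency (exclusion at p < 1e−5; a Wigginton-style exact test is
available behind `hwe_method="exact"`), missing rate > 5%, imputation
info score < 0.8. The MAF > 2% rule belongs to pre-selection and is off
by default. HWE is tested in all subjects (founder status is not
modelled). Monomorphic SNPs report p = 1 with a flag rather than
raising. Filters commute: the surviving SNP set is order-independent
(tested over all filter permutations).

## 4. LD grouping

r² is the squared Pearson correlation of dosages over pairwise-complete
subjects (≥ 20 required), intra-chromosome only. Sequential "merge into
a group if r² > 0.5 with any member" is order-dependent as stated, so
groups are defined as the **connected components** of the r² > 0.5
graph — its order-independent closure (tested against a networkx
brute-force oracle on random matrices). Proxy = member with smallest
meta p, ties broken by smaller genomic position (a convention; ties are
not otherwise resolved). A loader for precomputed pairwise r² lets
reference-panel values replace in-sample estimates. The haplotype-
copying LD-block generator (latent Gaussian AR(1) thresholded at the
MAF quantile) exists for fixtures and tests only.

## 5. Age-dependent effects

**Diagnostic.** Grambsch–Therneau score test: scaled Schoenfeld
residuals r\* = β̂ + d·I⁻¹s regressed on a transform g(t) of event
time; statistic [Σ(g−ḡ)r\*]² / ((I⁻¹)_jj · Σ(g−ḡ)²) ~ χ²₁; violation at
p < 0.05. Residuals are computed in-house because the risk sets carry
delayed entry, which the packaged residual routines do not support; the
default transform is the (left-truncation-aware) Kaplan–Meier
transform, with identity/rank/log selectable. Only the SNP term is
tested; other covariates are treated as constant-effect. Fewer than 10
events is refused. `ph_test_quick` provides the same test from a
direct Newton fit for simulation loops (equal to the lifelines-backed
route to ~1e−3 in tests).

**Stratified fits.** Half-open age windows [lo, hi): subjects enter at
max(entry, lo), exit at min(exit, hi), count as events only inside the
window; each window is a marginal Cox fit with family-robust variance.
Window boundaries are inputs (the choice of breakpoints is not
algorithmic). A single all-covering window reproduces the unstratified
fit exactly; per-window event counts sum to the total.

**Cumulative effect curve.** Piecewise-constant: cumulative sum of
(bin log-HR × bin width) from the counting-process start age (default
40), with pointwise percentile bands from a family-cluster bootstrap.
This is an explicitly simplified summary of the cumulative regression
coefficient — it is not a resampling-based functional estimator, and
its output is labelled accordingly (bins without events contribute
flagged flat segments).

**Kaplan–Meier by genotype.** lifelines product-limit estimator with
delayed entry per dosage group, Greenwood standard errors; matches an
independent longhand product-limit oracle to 1e−12 in tests.

## 6. Mediation (natural direct and indirect effects)

Weighted MSM approach for a survival outcome: each subject is
duplicated once per auxiliary exposure level a\* ∈ {0, 1, 2} with weight
f(M | a\*, C)/f(M | a_obs, C) from a Gaussian linear mediator model
(M ~ dosage + baseline age + sex), then a weighted Cox model with
linear predictor γ₁·A + γ₂·A\* (+ covariates) is fitted on the age time
scale with entry at the mediator measurement; NDE = γ₁, NIE = γ₂
(log-HR per allele). Only the **baseline** (earliest-visit) mediator
value is used and subjects with onset before it are excluded, enforcing
mediator-before-outcome ordering. Weights are truncated at their
1st/99th percentiles by default (recorded; toggleable). The proportion
mediated is NIE/(NDE+NIE) on the log-HR scale and is reported only when
|NDE+NIE| > 0.01. Uncertainty comes from a family-cluster
non-parametric bootstrap (default 500 replicates; plain Cox inside
replicates, so all uncertainty is bootstrap-borne); > 10% failed
replicates flags the result unreliable. No exposure–mediator
interaction, single mediator, and no unmeasured-confounding sensitivity
analysis — the no-confounding assumption is asserted, not tested.

**Known property.** Under the *complete* null (α = γ_M = direct = 0)
the NIE is a product-type, non-regular functional; its bootstrap
distribution over-disperses (measured ≈ 2× the sampling SD at n = 600),
so 95% NIE intervals over-cover there (towards 100%) — conservative,
never anti-conservative. NDE intervals are nominal (measured coverage
0.965 over 200 null repetitions).

## 7. Synthetic data generator

The generator emulates a six-cohort pooled study design: heterogeneous
phenotype panels per cohort, family clustering, longitudinal visits,
age-at-onset outcomes, one optionally binary/cross-sectional cohort,
and platform-specific SNP missingness. Specifics:

* Genotypes: dosage ~ Binomial(2, MAF) under HWE, independent across
  SNPs and subjects (family members' genotypes are independent — the
  family correction targets phenotypes and outcomes; no
  linkage/recombination maps). MAF outside (0, 0.5] is rejected naming
  the SNP.
* Quantitative traits: intercept + β·g + age-slope·age + sex-effect·sex
  + b_family + b_subject + ε, with a single trait-correlation matrix R
  applied to the family, subject and residual draws so the total
  cross-trait correlation equals R regardless of the variance split.
* Binary traits: logistic in dosage, entry age and sex (prevalence
  format), one observation at entry.
* Events: piecewise-constant baseline hazard over age; subject hazard
  λ₀(a)·exp(β(a)·g + γ_M·M_baseline,centered + sex term); event ages by
  exact inversion of the cumulative hazard from entry (so left
  truncation is respected by construction); censoring = administrative
  age (default 90) plus exponential dropout (default 0.02/yr) — the
  censoring model is a convention, real cohorts' dropout processes are
  not reconstructed. Sex ~ Bernoulli(0.5), centers categorical with 2–4
  levels, entry ages uniform on a cohort-specific range.
* All draws descend from one integer seed through named substreams
  (`substream(seed, purpose, cohort)`), so any single table is
  reproducible in isolation; the truth record (flat key–value text)
  lists every nonzero effect, age breakpoint and mediation path.

What the generator does **not** emulate: genotype transmission within
families (an optional sibling-transmission mode is out of scope of the
defaults), LD between causal and typed SNPs, population stratification,
measurement-error or batch structure, informative censoring, and
cohort-specific trait distributions beyond location/scale. Passing
tests therefore demonstrate statistical correctness of the machinery
under a clean data-generating process, not robustness to those
real-data features.

## 8. Study sizes used by tests and the acceptance script

Chosen so the full suite runs in minutes on one CPU while leaving the
assertion bands meaningful:

* Null calibration: 3 cohorts × 400 subjects × 2 visits, 8 traits with
  cross-trait correlation up to 0.5; Σ from 1000 simulated SNPs; 2000
  test SNPs per cohort (omnibus rates pooled over cohorts; meta rates
  over 2000 SNP labels).
* Power ordering: 500 replicate SNPs (MAF 0.3) affecting traits 0/3/6
  with signs (+, −, +); per-trait effect sized from the design for
  power 0.3 at the two-sided α = 1e−4 test level (ncp ≈ 3.37);
  comparison at matched α against min-p Bonferroni over 8 traits.
* PH diagnostics: size from 200 constant-effect cohorts (n = 800);
  power from 60 piecewise cohorts (n = 5000, log 2 → 0 at age 70);
  windows [40, 70) and [70, 90) for HR recovery.
* Mediation: 27-point grid (α, γ_M, direct ∈ {0, 0.3, 0.6}) at
  n = 4000, one replicate per point (grid-mean bias averages the Monte
  Carlo noise down to ~0.01); null coverage from 200 repetitions at
  n = 600 with 200 bootstrap replicates each.
* LD oracle agreement: 200 random matrices of ≤ 30 SNPs.

## 9. Numerical conventions

* p-values floored at 1e−300 before logs; omnibus p floored likewise.
* Ridge 1e−6 on Σ when the smallest eigenvalue < 1e−8 (renormalized to
  unit diagonal).
* Newton Cox solver: Breslow ties, step-halving on likelihood
  decrease, convergence on relative log-likelihood change < 1e−9 and
  small gradient.
* Missing dosages: exact fits drop the subject; the fast scan engine
  mean-imputes (score statistics stay well defined); the generator
  substitutes the expected dosage 2·MAF in effect terms so platform-
  missing SNPs carry no signal.
* Proxy ties broken by genomic position; phenotype-subset drops by
  caller priority then alphabetically.
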