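# pleioscan

Pleiotropic meta-analysis of genetic variants across heterogeneous
phenotypes — longitudinal quantitative endophenotypes (BMI, blood
glucose, lipids, ...), cross-sectional binary outcomes, and age-at-onset
diseases (CHD, stroke, diabetes, ...) — observed in several family
cohorts with different phenotype panels and genotyping platforms.

It is written for statistical geneticists and epidemiologists who want
to ask, from per-cohort univariate summary statistics alone: *is this
SNP associated with anything, anywhere* — and then characterize how:
through which intermediate trait (mediation), and whether the effect on
disease hazard changes with age.

## The method

For SNP *s* in cohort *j*, univariate scans produce per-phenotype effect
estimates β̂<sub>ij</sub> with standard errors σ̂<sub>ij</sub> (linear
mixed models with family- and individual-level random intercepts for
longitudinal traits; logistic regression for binary traits; marginal Cox
proportional-hazards models on the age time scale with family-clustered
robust variance for time-to-event traits). With
**z**<sub>j</sub> = β̂<sub>j</sub>/σ̂<sub>j</sub>, the cohort-level
omnibus statistic is

> T<sub>j</sub> = **z**<sub>j</sub>′ Σ<sub>j</sub><sup>−1</sup> **z**<sub>j</sub> ~ χ²<sub>K<sub>j</sub></sub> under H₀,

where Σ<sub>j</sub> is the correlation matrix of the z-scores induced by
phenotypic correlation, estimated by scanning independent SNPs simulated
under Hardy–Weinberg equilibrium against the cohort's *actual* phenotype
data (1000 by default; multivariate normality is checkable with the
Henze–Zirkler test, and phenotypes are greedily pruned so every pairwise
|correlation| stays below 0.7). Cohort p-values p<sub>j</sub> are then
combined across J cohorts with Fisher's method,
−2 Σ ln p<sub>j</sub> ~ χ²<sub>2J</sub> (df = 12 for six cohorts), for
three analysis groups: endophenotypes, diseases, and both.

Around the core test the package provides the full pipeline: SNP-level
QC (HWE p < 1e−5, missing rate > 5%, imputation info < 0.8), the
uncorrected Fisher pre-selection screen (MAF > 2%, p < 5e−8), LD
grouping of significant SNPs (connected components at r² > 0.5, proxy =
most significant member) with r² > 0.8 partner listing, Schoenfeld-
residual diagnostics and age-window-stratified Cox fits for
age-dependent effects (counting process from age 40), and natural
direct/indirect effects through a baseline endophenotype via weighted
marginal structural models with family-cluster bootstrap CIs.

A fully synthetic multi-cohort generator (`pleioscan.synth`) with a
machine-readable truth record drives every test; no external or
controlled-access data are needed anywhere.

## Worked example

```python
import numpy as np
from pleioscan import synth, meta, assoc
from pleioscan.datatypes import CohortSpec, PhenotypeDef, SNPDef, EffectSpec, CohortData
from pleioscan._fastscan import FastCohortScanner

panel = [PhenotypeDef("BMI"), PhenotypeDef("BG"), PhenotypeDef("CHD", "time-to-event")]
spec = CohortSpec("C1", 400, 200, panel, n_visits=2)
geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=1)
vcs = {"BMI": synth.VarianceComponents(25, 1, 2, 1, 0.02, 0.5),
       "BG": synth.VarianceComponents(5, 0.5, 1, 1)}
effects = [EffectSpec("rs0", {"BMI": 0.3, "CHD": 0.4})]
pheno = synth.simulate_phenotypes(geno, spec, effects, vcs, seed=1)
events = synth.simulate_events(geno, spec, effects,
                               synth.PiecewiseHazard((60, 80), (0.005, 0.02, 0.05)), seed=1)
cohort = CohortData(spec, geno, pheno, events)

stats = assoc.scan(cohort, ["rs0"])                    # exact per-SNP fits
sigma = meta.estimate_sigma(meta.simulate_null_z(cohort, n_snps=300, seed=2), "C1")
z = stats.set_index("phenotype")["z"]
res = meta.omnibus(z, sigma, snp_id="rs0")
print(stats[["phenotype", "beta", "se", "p"]].round(4).to_string(index=False))
print(f"omnibus T = {res.statistic:.2f}, df = {res.df}, p = {res.p:.3g}")
```

prints

```
phenotype    beta     se      p
       BG -0.0089 0.1056 0.9329
      BMI  0.2250 0.1419 0.1129
      CHD  0.4263 0.1073 0.0001
```

followed by `omnibus T = 19.44, df = 3, p = 0.000222`: the BMI and CHD
effects (true values 0.3 trait units and 0.4 log-hazard per minor
allele) are recovered within one standard error each, the unaffected
trait BG is null, and the joint statistic combines evidence from all
three traits — a single pleiotropy test at n = 400 rather than three
separate ones. The full candidate workflow (QC → pre-selection →
per-cohort omnibus → cross-cohort Fisher → LD pruning) composes these
same calls; see `pleioscan.meta.meta_analyze`.

The same steps are available from the shell:

```bash
pleioscan qc      --dosages dos.tsv --out report.tsv
pleioscan assoc   --dosages dos.tsv --phenotypes ph.tsv --events ev.tsv --out stats.tsv
pleioscan meta    --stats stats.tsv --dosages dos.tsv --phenotypes ph.tsv --out meta.tsv
pleioscan prune   --meta meta.tsv --dosages dos.tsv --r2 0.5 --out groups.tsv
pleioscan mediate --dosages dos.tsv --phenotypes ph.tsv --events ev.tsv \
                  --snp rs0 --mediator BMI --disease CHD --n-boot 500 --seed 1 --out med.json
```

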