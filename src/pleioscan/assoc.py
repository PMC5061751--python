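"""Per-cohort univariate association fits: LMM, logistic, marginal Cox.

Each fit produces one :class:`SummaryStat` — effect per minor allele with
its standard error, Wald z and two-sided p — which is all the downstream
meta-analysis consumes.  Model choices follow common cohort-study
practice:

* longitudinal quantitative traits: linear mixed model with family- and
  individual-level random intercepts (REML); the individual intercept is
  dropped with a single visit per subject and the family intercept when
  every family is a singleton, in which case the fit collapses to OLS;
* cross-sectional binary traits: logistic regression (log-odds per
  allele);
* age-at-onset diseases: marginal Cox proportional-hazards model with
  Efron tie handling and a family-clustered robust (sandwich) variance;
  the default time scale is age with left truncation at entry, a
  follow-up-time mode with entry age as covariate is available.

Degenerate inputs (phenotype not measured, SNP not genotyped,
monomorphic SNP, zero events, non-convergence, complete separation)
return flagged results instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps

from .datatypes import (
    BINARY,
    EVENT,
    QUANTITATIVE,
    CohortData,
    GenotypeMatrix,
    SummaryStat,
    stats_frame,
)
from ._fastscan import FastCohortScanner, _null_formula, fit_mixedlm

__all__ = ["CoxFit", "log_transform", "fit_lmm", "fit_logistic", "fit_cox", "scan"]


@dataclass
class CoxFit:
    """A fitted marginal Cox model retained for PH diagnostics.

    Besides the lifelines fitter, carries the numeric design matrix and
    the (entry, stop, event) arrays so Schoenfeld residuals can be
    computed under delayed entry.
    """

    fitter: CoxPHFitter
    data: pd.DataFrame
    snp_id: str
    disease: str
    timescale: str
    n_events: int
    design: np.ndarray = None
    columns: list[str] = None


def log_transform(values):
    """Skewness correction used for positive traits: 100 * ln(value)."""
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0))[0]
    if bad.size:
        idx = values.index[bad[0]] if isinstance(values, pd.Series) else bad[0]
        raise ValueError(f"non-positive value at {idx!r}; cannot log-transform")
    out = 100.0 * np.log(arr)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def _assemble(
    geno: GenotypeMatrix, snp_id: str, rows: pd.DataFrame
) -> tuple[pd.DataFrame, str]:
    """Merge dosage + subject covariates onto phenotype/event rows."""
    if snp_id not in geno.dosages.columns:
        return rows.iloc[0:0], "not-genotyped"
    df = rows.merge(
        geno.subjects[["sex", "center"]], left_on="subject_id", right_index=True, how="left"
    )
    df["dosage"] = geno.dosages[snp_id].reindex(df["subject_id"]).to_numpy()
    df = df.dropna(subset=["dosage"])
    if df.empty or df["dosage"].nunique() < 2:
        return df, "not-genotyped" if df.empty else "monomorphic"
    return df.reset_index(drop=True), ""


def _flagged(snp_id, phenotype, cohort_id, model, flag) -> SummaryStat:
    return SummaryStat(snp_id, phenotype, cohort_id, model, flag=flag)


def fit_lmm(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    phenotype: str,
    snp_id: str,
    covariates=("age", "sex", "center"),
) -> SummaryStat:
    """Linear mixed model of a quantitative trait on dosage + covariates.

    Random intercepts: individual nested in family where the design
    identifies them (see module docstring).  REML estimation, Wald
    inference on the dosage coefficient.
    """
    cohort_id = geno.cohort_id
    rows = pheno[pheno["phenotype"] == phenotype]
    if rows.empty:
        return _flagged(snp_id, phenotype, cohort_id, "lmm", "not-measured")
    df, flag = _assemble(geno, snp_id, rows)
    if flag:
        return _flagged(snp_id, phenotype, cohort_id, "lmm", flag)

    formula = _null_formula(covariates, df).replace("value ~", "value ~ dosage +")
    sub = pd.factorize(df["subject_id"])[0]
    repeated = len(df) > sub.max() + 1
    clustered = (
        pd.Series(sub).groupby(pd.factorize(df["family_id"])[0]).nunique().max() > 1
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if clustered and repeated:
                md = sm.MixedLM.from_formula(
                    formula,
                    groups="family_id",
                    re_formula="1",
                    vc_formula={"subject": "0 + C(subject_id)"},
                    data=df,
                )
                res = fit_mixedlm(md)
            elif clustered or repeated:
                md = sm.MixedLM.from_formula(
                    formula,
                    groups="family_id" if clustered else "subject_id",
                    re_formula="1",
                    data=df,
                )
                res = fit_mixedlm(md)
            else:
                res = sm.OLS.from_formula(formula, data=df).fit()
    except Exception:
        return _flagged(snp_id, phenotype, cohort_id, "lmm", "fit-failed")

    converged = bool(getattr(res, "converged", True))
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    z = beta / se
    return SummaryStat(
        snp_id,
        phenotype,
        cohort_id,
        "lmm",
        beta,
        se,
        z,
        float(2 * sps.norm.sf(abs(z))),
        len(df),
        df["subject_id"].nunique(),
        "" if converged and np.isfinite(z) else "non-converged",
    )


def fit_logistic(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    phenotype: str,
    snp_id: str,
    covariates=("age", "sex", "center"),
) -> SummaryStat:
    """Logistic regression of a cross-sectional binary trait on dosage.

    The coefficient is the log-odds per minor allele; because the binary
    outcomes are prevalence-format, exp(beta) is an odds ratio, not a
    hazard ratio.
    """
    cohort_id = geno.cohort_id
    rows = pheno[pheno["phenotype"] == phenotype]
    if rows.empty:
        return _flagged(snp_id, phenotype, cohort_id, "logistic", "not-measured")
    df, flag = _assemble(geno, snp_id, rows)
    if flag:
        return _flagged(snp_id, phenotype, cohort_id, "logistic", flag)
    if df["value"].nunique() < 2:
        return _flagged(snp_id, phenotype, cohort_id, "logistic", "constant-outcome")

    formula = _null_formula(covariates, df).replace("value ~", "value ~ dosage +")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM.from_formula(
                formula, data=df, family=sm.families.Binomial()
            ).fit()
    except Exception:
        return _flagged(snp_id, phenotype, cohort_id, "logistic", "fit-failed")
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        return _flagged(snp_id, phenotype, cohort_id, "logistic", "separation")
    z = beta / se
    return SummaryStat(
        snp_id,
        phenotype,
        cohort_id,
        "logistic",
        beta,
        se,
        z,
        float(2 * sps.norm.sf(abs(z))),
        len(df),
        df["subject_id"].nunique(),
        "",
    )


def fit_cox(
    events: pd.DataFrame,
    geno: GenotypeMatrix,
    disease: str,
    snp_id: str,
    covariates=("sex", "center"),
    timescale: str = "age",
) -> tuple[SummaryStat, CoxFit | None]:
    """Marginal Cox PH fit with family-clustered robust variance.

    timescale='age' (default): age is the event time with left
    truncation at entry.  timescale='followup': time since entry, with
    entry age added as a fixed covariate.
    """
    cohort_id = geno.cohort_id
    rows = events[events["disease"] == disease]
    if rows.empty:
        return _flagged(snp_id, disease, cohort_id, "cox", "not-measured"), None
    df, flag = _assemble(geno, snp_id, rows)
    if flag:
        return _flagged(snp_id, disease, cohort_id, "cox", flag), None
    if int(df["event"].sum()) == 0:
        return _flagged(snp_id, disease, cohort_id, "cox", "no-events"), None

    terms = ["dosage"]
    if "sex" in covariates:
        terms.append("sex")
    if "center" in covariates and df["center"].nunique() > 1:
        terms.append("C(center)")
    if timescale == "age":
        df["_entry"] = df["entry_age"]
        df["_stop"] = df["exit_age"]
    elif timescale == "followup":
        df["_entry"] = 0.0
        df["_stop"] = df["exit_age"] - df["entry_age"]
        terms.append("entry_age")
    else:
        raise ValueError("timescale must be 'age' or 'followup'")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="_stop",
                entry_col="_entry",
                event_col="event",
                cluster_col="family_id",
                formula=" + ".join(terms),
                robust=True,
            )
    except Exception:
        return _flagged(snp_id, disease, cohort_id, "cox", "fit-failed"), None

    beta = float(cph.params_["dosage"])
    se = float(cph.standard_errors_["dosage"])
    z = beta / se
    stat = SummaryStat(
        snp_id,
        disease,
        cohort_id,
        "cox",
        beta,
        se,
        z,
        float(2 * sps.norm.sf(abs(z))),
        len(df),
        df["subject_id"].nunique(),
        "",
    )
    design_cols = [("dosage", df["dosage"].to_numpy(dtype=float))]
    if "sex" in terms:
        design_cols.append(("sex", df["sex"].to_numpy(dtype=float)))
    if "C(center)" in terms:
        for lv in sorted(df["center"].unique())[1:]:
            design_cols.append((f"center_{lv}", (df["center"] == lv).to_numpy(dtype=float)))
    if "entry_age" in terms:
        design_cols.append(("entry_age", df["entry_age"].to_numpy(dtype=float)))
    fit = CoxFit(
        cph,
        df,
        snp_id,
        disease,
        timescale,
        int(df["event"].sum()),
        design=np.column_stack([c for _, c in design_cols]),
        columns=[n for n, _ in design_cols],
    )
    return stat, fit


def scan(
    cohort: CohortData,
    snp_ids: list[str] | None = None,
    covariates=("age", "sex", "center"),
    engine: str = "exact",
    timescale: str = "age",
) -> pd.DataFrame:
    """The per-cohort battery: one row per (SNP, phenotype) in canonical order.

    engine='exact' refits every model per SNP (the defensible default for
    a handful of candidate SNPs); engine='fast' uses the shared-null-model
    score/GLS scan, which is the right tool when thousands of SNPs are
    screened against the same phenotype data.
    """
    geno = cohort.genotypes
    snp_ids = list(snp_ids) if snp_ids is not None else geno.snp_ids

    if engine == "fast":
        scanner = FastCohortScanner(cohort, covariates=covariates)
        known = [s for s in snp_ids if s in geno.dosages.columns]
        res = scanner.zscan(geno.dosages[known])
        out = []
        for snp_id in snp_ids:
            for pdef in cohort.spec.phenotype_panel:
                model = {"quantitative-longitudinal": "lmm", "binary-cross-sectional": "logistic"}.get(
                    pdef.kind, "cox"
                )
                if snp_id not in res["z"].index or geno.dosages[snp_id].isna().all():
                    out.append(_flagged(snp_id, pdef.name, geno.cohort_id, model, "not-genotyped"))
                    continue
                beta = float(res["beta"].loc[snp_id, pdef.name])
                se = float(res["se"].loc[snp_id, pdef.name])
                z = beta / se
                out.append(
                    SummaryStat(
                        snp_id, pdef.name, geno.cohort_id, model,
                        beta, se, z, float(2 * sps.norm.sf(abs(z))),
                        n_obs=0, n_subjects=geno.n_subjects, flag="",
                    )
                )
        return stats_frame(out)

    if engine != "exact":
        raise ValueError("engine must be 'exact' or 'fast'")
    out = []
    for snp_id in snp_ids:
        for pdef in cohort.spec.phenotype_panel:
            if pdef.kind == QUANTITATIVE:
                out.append(fit_lmm(cohort.phenotypes, geno, pdef.name, snp_id, covariates))
            elif pdef.kind == BINARY:
                out.append(fit_logistic(cohort.phenotypes, geno, pdef.name, snp_id, covariates))
            elif pdef.kind == EVENT:
                stat, _ = fit_cox(
                    cohort.events, geno, pdef.name, snp_id,
                    covariates=tuple(c for c in covariates if c != "age"),
                    timescale=timescale,
                )
                out.append(stat)
    return stats_frame(out)
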