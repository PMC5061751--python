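"""SNP-level quality control: Hardy-Weinberg, missingness, imputation info.

Filters mirror standard GWAS practice: subjects with overall missing rate
above 5% are dropped first, then each SNP is tested for Hardy-Weinberg
equilibrium (default 1-df chi-square goodness of fit, exact test behind a
flag), call-rate and imputation information score.  The minor-allele
frequency filter (MAF > 2%) belongs to the candidate pre-selection stage
and is off by default here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix

__all__ = ["HWEResult", "QCThresholds", "hwe_test", "hwe_exact_test", "apply_filters"]


@dataclass(frozen=True)
class HWEResult:
    statistic: float
    p: float
    monomorphic: bool = False


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion rules: HWE p < hwe_p, missing rate > max_missing,
    info score < min_info, and (optionally) MAF <= min_maf."""

    hwe_p: float = 1e-5
    max_missing: float = 0.05
    min_info: float = 0.8
    min_maf: float | None = None
    subject_max_missing: float = 0.05
    hwe_method: str = "chisq"  # or "exact"


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "chisq") -> HWEResult:
    """Hardy-Weinberg goodness-of-fit test from genotype counts.

    AA is the major homozygote, aa the minor.  A monomorphic SNP (one
    allele absent) returns p = 1 with the ``monomorphic`` flag rather
    than raising.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("genotype counts sum to zero")
    q = (2 * n_aa + n_Aa) / (2 * n)  # minor allele frequency
    if q <= 0.0 or q >= 1.0:
        return HWEResult(0.0, 1.0, monomorphic=True)
    if method == "exact":
        return hwe_exact_test(n_AA, n_Aa, n_aa)
    if method != "chisq":
        raise ValueError(f"unknown HWE method {method!r}")
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return HWEResult(statistic, p)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Exact Hardy-Weinberg test (sum of probabilities <= observed).

    Enumerates the conditional distribution of the heterozygote count
    given the allele counts via the standard recurrence; the p-value sums
    the probabilities of all heterozygote counts no more likely than the
    observed one.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("genotype counts sum to zero")
    n_minor = 2 * n_aa + n_Aa
    n_minor = min(n_minor, 2 * n - n_minor)
    if n_minor == 0:
        return HWEResult(0.0, 1.0, monomorphic=True)
    het_obs = n_Aa

    # heterozygote count must have the parity of the minor-allele count
    het_lo = n_minor % 2
    hets = np.arange(het_lo, n_minor + 1, 2)
    probs = np.zeros(len(hets))
    mid = len(hets) // 2
    probs[mid] = 1.0
    # recurrence upward and downward from the mode region
    for i in range(mid, len(hets) - 1):
        het = hets[i]
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        probs[i + 1] = probs[i] * 4.0 * hom_min * hom_maj / ((het + 2.0) * (het + 1.0))
    for i in range(mid, 0, -1):
        het = hets[i]
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        probs[i - 1] = probs[i] * het * (het - 1.0) / (
            4.0 * (hom_min + 1.0) * (hom_maj + 1.0)
        )
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het_obs)]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return HWEResult(float(p_obs), min(p, 1.0))


def apply_filters(
    geno: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply subject- then SNP-level QC; return the filtered matrix and a report.

    The report has one row per input SNP (including excluded ones) with
    genotype counts, missing rate, MAF recomputed from calls, HWE
    statistic/p, the pass flag and semicolon-joined failure reasons.
    Column order of surviving SNPs is preserved.
    """
    thr = thresholds or QCThresholds()
    if geno.dosages.shape[1] == 0 or geno.n_subjects == 0:
        raise ValueError("empty genotype matrix")

    dos = geno.dosages
    # subject-level call-rate filter runs first
    subj_missing = dos.isna().mean(axis=1)
    keep_subjects = subj_missing <= thr.subject_max_missing
    dos = dos.loc[keep_subjects]

    rows = []
    passing = []
    n_total = len(dos)
    for snp_id in dos.columns:
        col = dos[snp_id].to_numpy(dtype=float)
        called = col[~np.isnan(col)]
        n_called = len(called)
        n_aa = int((called == 2).sum())
        n_Aa = int((called == 1).sum())
        n_AA = int((called == 0).sum())
        missing_rate = 1.0 - n_called / n_total if n_total else 1.0
        maf = (2 * n_aa + n_Aa) / (2 * n_called) if n_called else np.nan
        if np.isfinite(maf) and maf > 0.5:
            maf = 1.0 - maf
        info = float(geno.snps.loc[snp_id, "info_score"]) if "info_score" in geno.snps else 1.0

        reasons = []
        if n_called == 0:
            hwe = HWEResult(np.nan, np.nan, monomorphic=True)
            reasons.append("missing_rate")
        else:
            hwe = hwe_test(n_AA, n_Aa, n_aa, method=thr.hwe_method)
            if missing_rate > thr.max_missing:
                reasons.append("missing_rate")
            if not hwe.monomorphic and hwe.p < thr.hwe_p:
                reasons.append("hwe")
        if info < thr.min_info:
            reasons.append("info")
        if thr.min_maf is not None and not (np.isfinite(maf) and maf > thr.min_maf):
            reasons.append("maf")

        ok = not reasons
        passing.append(ok)
        rows.append(
            {
                "snp_id": snp_id,
                "n_AA": n_AA,
                "n_Aa": n_Aa,
                "n_aa": n_aa,
                "n_missing": n_total - n_called,
                "missing_rate": missing_rate,
                "maf": maf,
                "hwe_stat": hwe.statistic,
                "hwe_p": hwe.p,
                "monomorphic": hwe.monomorphic,
                "info": info,
                "pass": ok,
                "reasons": ";".join(reasons),
            }
        )

    report = pd.DataFrame(rows)
    kept = [s for s, ok in zip(dos.columns, passing) if ok]
    filtered = GenotypeMatrix(
        dos[kept].copy(), geno.subjects.loc[keep_subjects], geno.snps.loc[kept].copy()
    )
    return filtered, report
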