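"""Readers and writers for the plain-text interchange formats.

Dosage TSV: header ``subject_id family_id cohort_id [sex center
entry_age] <snp1> <snp2> ...``, missing coded ``NA``.  A sidecar SNP
table (``snp_id maf chrom pos info_score``) can accompany it; without
one, MAF is recomputed from the dosages.  Phenotype and event tables are
long-format TSV, the truth record a flat ``key<TAB>value`` file, and
pairwise LD a three-column ``snp_a snp_b r2`` TSV.  An optional VCF
reader maps diploid GT calls to minor-allele dosage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    validate_event_table,
    validate_phenotype_table,
)

_META_COLS = ["subject_id", "family_id", "cohort_id", "sex", "center", "entry_age"]


def write_dosage_tsv(geno: GenotypeMatrix, path, snp_table_path=None) -> None:
    df = geno.subjects.reset_index()[
        [c for c in _META_COLS if c in list(geno.subjects.columns) + ["subject_id"]]
    ]
    df = pd.concat([df, geno.dosages.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    if snp_table_path is not None:
        geno.snps.reset_index().to_csv(snp_table_path, sep="\t", index=False)


def read_dosage_tsv(path, snp_table_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta_cols = [c for c in _META_COLS if c in df.columns]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    subjects = df[meta_cols].set_index("subject_id")
    for col, default in (("sex", 0), ("center", 0), ("entry_age", np.nan)):
        if col not in subjects.columns:
            subjects[col] = default
    dosages = df[snp_cols].astype(float)
    dosages.index = subjects.index
    if snp_table_path is not None:
        snps = pd.read_csv(snp_table_path, sep="\t").set_index("snp_id").loc[snp_cols]
    else:
        maf = dosages.mean() / 2.0
        maf = np.minimum(maf, 1 - maf)
        snps = pd.DataFrame(
            {"maf": maf, "chrom": "1", "pos": 0, "info_score": 1.0}, index=dosages.columns
        )
        snps.index.name = "snp_id"
    return GenotypeMatrix(dosages, subjects, snps)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    validate_phenotype_table(df)
    return df


def read_event_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    validate_event_table(df)
    return df


def write_truth(truth: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for k in sorted(truth):
            fh.write(f"{k}\t{truth[k]}\n")


def read_truth(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            k, _, v = line.partition("\t")
            out[k] = v
    return out


def write_r2_tsv(ld, path) -> None:
    rows = []
    snps = list(ld.r2.index)
    for i, a in enumerate(snps):
        for b in snps[i + 1 :]:
            v = ld.r2.loc[a, b]
            if np.isfinite(v):
                rows.append({"snp_a": a, "snp_b": b, "r2": v})
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_r2_tsv(path, snp_positions: pd.DataFrame | None = None):
    """Load precomputed pairwise r2 (e.g. reference-panel values)."""
    from .ld import LDMatrix

    df = pd.read_csv(path, sep="\t")
    snps = sorted(set(df["snp_a"]) | set(df["snp_b"]))
    r2 = pd.DataFrame(np.nan, index=snps, columns=snps)
    np.fill_diagonal(r2.values, 1.0)
    for _, row in df.iterrows():
        r2.loc[row["snp_a"], row["snp_b"]] = row["r2"]
        r2.loc[row["snp_b"], row["snp_a"]] = row["r2"]
    if snp_positions is None:
        snp_positions = pd.DataFrame({"chrom": "1", "pos": 0}, index=pd.Index(snps, name="snp_id"))
    return LDMatrix(r2, snp_positions.loc[snps])


def read_vcf(path, subjects_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF into minor-allele dosages.

    Phased or unphased calls are accepted; half-calls and missing
    genotypes become NaN.  The counted allele is whichever of REF/ALT is
    minor in the sample; ``subjects_meta`` (indexed by sample name) may
    supply family/cohort/sex/center/entry_age columns.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        gts = np.array([g[:2] for g in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        alt_dose = np.where(np.isnan(gts).any(axis=1), np.nan, np.nansum(gts, axis=1))
        af = np.nanmean(alt_dose) / 2.0 if np.isfinite(alt_dose).any() else np.nan
        dose = alt_dose if not (af > 0.5) else 2.0 - alt_dose
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        rows.append(dose)
    dosages = pd.DataFrame(
        np.array(rows).T, index=pd.Index(samples, name="subject_id"), columns=snp_ids
    )
    if subjects_meta is not None:
        subjects = subjects_meta.loc[samples].copy()
    else:
        subjects = pd.DataFrame(
            {
                "family_id": samples,
                "cohort_id": "VCF",
                "sex": 0,
                "center": 0,
                "entry_age": np.nan,
            },
            index=dosages.index,
        )
    maf = dosages.mean() / 2.0
    maf = np.minimum(maf, 1 - maf)
    snps = pd.DataFrame(
        {"maf": maf, "chrom": chroms, "pos": poss, "info_score": 1.0},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(dosages, subjects, snps)
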