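"""Linkage-disequilibrium computation, SNP grouping, and proxy selection.

Significant SNPs on the same chromosome are merged into groups whenever
r^2 (squared Pearson correlation of dosages over pairwise-complete
subjects) exceeds a threshold with *any* member — i.e. groups are the
connected components of the r^2 > threshold graph, the order-independent
closure of the sequential merge rule.  Each group is represented by its
proxy: the member with the smallest meta-analysis p-value, ties broken
by smaller genomic position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import GenotypeMatrix
from .synth import substream

__all__ = [
    "LDMatrix",
    "LDGroup",
    "compute_r2",
    "group_by_ld",
    "high_ld_partners",
    "simulate_ld_block",
]


@dataclass
class LDMatrix:
    """Pairwise r^2 values with SNP positions.

    r2: symmetric DataFrame (diagonal 1); only intra-chromosome pairs
    are populated, the rest are NaN.
    """

    r2: pd.DataFrame
    snps: pd.DataFrame  # index snp_id, columns chrom, pos

    def value(self, a: str, b: str) -> float:
        if a not in self.r2.index or b not in self.r2.index:
            return np.nan
        return float(self.r2.loc[a, b])


@dataclass
class LDGroup:
    group_id: int
    chrom: str
    members: list[str]
    proxy: str
    proxy_p: float


def compute_r2(geno: GenotypeMatrix, snp_ids=None, min_n: int = 20) -> LDMatrix:
    """Squared Pearson correlation of dosages over pairwise-complete subjects.

    Pairs with fewer than ``min_n`` complete subjects, with a monomorphic
    SNP in the complete subset, or on different chromosomes come out NaN.
    """
    snp_ids = list(snp_ids) if snp_ids is not None else geno.snp_ids
    D = geno.dosages[snp_ids].to_numpy(dtype=float)
    chrom = geno.snps.loc[snp_ids, "chrom"].to_numpy()
    m = len(snp_ids)
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            if chrom[i] != chrom[j]:
                continue
            mask = ~np.isnan(D[:, i]) & ~np.isnan(D[:, j])
            if mask.sum() < min_n:
                continue
            x, y = D[mask, i], D[mask, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[i, j] = out[j, i] = r * r
    r2 = pd.DataFrame(out, index=snp_ids, columns=snp_ids)
    return LDMatrix(r2, geno.snps.loc[snp_ids, ["chrom", "pos"]].copy())


def group_by_ld(
    significant: pd.DataFrame, ld: LDMatrix, threshold: float = 0.5
) -> list[LDGroup]:
    """Partition significant SNPs into LD groups and pick proxies.

    ``significant`` needs columns ``snp_id`` and ``p`` (the meta
    p-value); chromosome and position come from the LD matrix, falling
    back to singleton groups (with a warning flag via chrom='?') for
    SNPs absent from it.
    """
    import warnings

    snp_ids = list(significant["snp_id"])
    pvals = dict(zip(significant["snp_id"], significant["p"]))
    known = [s for s in snp_ids if s in ld.r2.index]
    orphans = [s for s in snp_ids if s not in ld.r2.index]
    if orphans:
        warnings.warn(f"SNPs missing from LD matrix, kept as singletons: {orphans}")

    groups: list[LDGroup] = []
    gid = 0
    for chrom in sorted(set(ld.snps.loc[known, "chrom"].astype(str))):
        members = [s for s in known if str(ld.snps.loc[s, "chrom"]) == chrom]
        if not members:
            continue
        sub = ld.r2.loc[members, members].to_numpy(dtype=float)
        adj = np.nan_to_num(sub, nan=0.0) > threshold
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(n_comp):
            comp_members = [m for m, l in zip(members, labels) if l == comp]
            proxy = min(
                comp_members,
                key=lambda s: (pvals.get(s, np.inf), int(ld.snps.loc[s, "pos"])),
            )
            groups.append(
                LDGroup(gid, chrom, comp_members, proxy, float(pvals.get(proxy, np.nan)))
            )
            gid += 1
    for s in orphans:
        groups.append(LDGroup(gid, "?", [s], s, float(pvals.get(s, np.nan))))
        gid += 1
    return groups


def high_ld_partners(snp_id: str, ld: LDMatrix, threshold: float = 0.8) -> list[str]:
    """SNPs with r^2 above ``threshold`` to the query, descending r^2.

    The export feeds external regulatory-annotation lookups.
    """
    if snp_id not in ld.r2.index:
        return []
    row = ld.r2.loc[snp_id].drop(snp_id)
    hits = row[row > threshold].sort_values(ascending=False)
    return list(hits.index)


def simulate_ld_block(
    n_subjects: int,
    n_snps: int,
    rho: float = 0.9,
    maf: float = 0.3,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
) -> GenotypeMatrix:
    """Synthetic LD block for tests: a haplotype-copying style generator.

    Latent per-haplotype Gaussian AR(1) processes with lag-one
    correlation ``rho`` are thresholded at the MAF quantile to produce
    alleles, so adjacent SNPs are in high LD with geometric decay.
    """
    from scipy.stats import norm

    rng = substream(seed, "ldblock")
    thresh = norm.ppf(maf)
    haps = np.zeros((2 * n_subjects, n_snps))
    z = rng.standard_normal(2 * n_subjects)
    for j in range(n_snps):
        haps[:, j] = z
        z = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(2 * n_subjects)
    alleles = (haps < thresh).astype(float)
    dos = alleles[0::2] + alleles[1::2]

    subject_ids = [f"LD_S{i:05d}" for i in range(n_subjects)]
    snp_ids = [f"ld{j:03d}" for j in range(n_snps)]
    dosages = pd.DataFrame(
        dos, index=pd.Index(subject_ids, name="subject_id"), columns=snp_ids
    )
    subjects = pd.DataFrame(
        {
            "family_id": subject_ids,
            "cohort_id": "LD",
            "sex": rng.integers(0, 2, size=n_subjects),
            "center": 0,
            "entry_age": 50.0,
        },
        index=dosages.index,
    )
    snps = pd.DataFrame(
        {
            "maf": maf,
            "chrom": chrom,
            "pos": start_pos + 1000 * np.arange(n_snps),
            "info_score": 1.0,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(dosages, subjects, snps)
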