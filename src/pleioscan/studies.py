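"""Reusable simulation studies: calibration, power, and recovery checks.

Each function builds its own synthetic data from a single seed, runs the
relevant slice of the pipeline, and returns plain numbers.  They back
both the acceptance test suite and ``scripts/acceptance.py``; problem
sizes default to what one CPU handles in minutes (the methods note lists
them).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import agedep, assoc, ld, mediation, meta, qc, synth
from ._fastscan import FastCohortScanner
from .datatypes import (
    AgeVaryingEffect,
    CohortData,
    CohortSpec,
    EffectSpec,
    MediationPath,
    PhenotypeDef,
    SNPDef,
)

__all__ = [
    "calibration_trait_correlation",
    "make_calibration_cohort",
    "null_calibration_study",
    "power_ordering_study",
    "fisher_null_study",
    "ld_grouping_agreement_study",
    "ph_diagnostics_study",
    "mediation_grid_study",
    "mediation_null_coverage_study",
]

_EMPTY_EVENTS = pd.DataFrame(
    columns=["subject_id", "family_id", "cohort_id", "entry_age", "exit_age", "event", "disease"]
)


def calibration_trait_correlation(n_traits: int = 8) -> np.ndarray:
    """Banded cross-trait correlation with entries up to 0.5.

    Neighbouring traits correlate at 0.5, next-neighbours at 0.25, the
    rest at 0.1 — mimicking clusters of related endophenotypes (e.g.
    blood pressures, lipids)."""
    R = np.full((n_traits, n_traits), 0.1)
    for i in range(n_traits):
        R[i, i] = 1.0
        for j in range(n_traits):
            if abs(i - j) == 1:
                R[i, j] = 0.5
            elif abs(i - j) == 2:
                R[i, j] = 0.25
    return R


def make_calibration_cohort(
    cohort_id: str,
    seed: int,
    n_subjects: int = 400,
    n_traits: int = 8,
    n_visits: int = 2,
    effects: list[EffectSpec] | None = None,
) -> CohortData:
    """One family cohort with correlated longitudinal traits, no diseases."""
    traits = [f"T{k}" for k in range(n_traits)]
    panel = [PhenotypeDef(t) for t in traits]
    vcs = {t: synth.VarianceComponents(0.0, 0.3, 0.4, 1.0, 0.01, 0.2) for t in traits}
    spec = CohortSpec(cohort_id, n_subjects, n_subjects // 2, panel, n_visits=n_visits)
    geno = synth.simulate_genotypes(spec, [SNPDef("rs_anchor", 0.3)], seed)
    pheno = synth.simulate_phenotypes(
        geno, spec, effects or [], vcs, seed,
        trait_corr=calibration_trait_correlation(n_traits),
    )
    return CohortData(spec, geno, pheno, _EMPTY_EVENTS.copy())


def _hwe_dosage_frame(rng, n_subjects, n_snps, index, maf_range=(0.05, 0.5)):
    mafs = rng.uniform(*maf_range, size=n_snps)
    dos = rng.binomial(2, mafs[None, :], size=(n_subjects, n_snps)).astype(float)
    return pd.DataFrame(dos, index=index, columns=[f"t{i:05d}" for i in range(n_snps)])


def null_calibration_study(
    seed: int,
    n_cohorts: int = 3,
    n_subjects: int = 400,
    n_traits: int = 8,
    n_sigma_snps: int = 1000,
    n_test_snps: int = 2000,
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> dict:
    """Type-I error of the omnibus test and the cross-cohort Fisher meta
    p under the global null with correlated phenotypes.

    Per cohort: Sigma is estimated from ``n_sigma_snps`` simulated null
    SNPs, then ``n_test_snps`` fresh null SNPs are scanned and tested.
    Omnibus rejection rates are pooled over cohorts (each cohort's test
    SNPs are independent draws); the meta rates combine the same SNP
    label across cohorts with Fisher's method.
    """
    ps = {}
    for ci in range(n_cohorts):
        cid = f"C{ci}"
        cohort = make_calibration_cohort(cid, seed * 7919 + ci, n_subjects, n_traits)
        scanner = FastCohortScanner(cohort)
        Z = meta.simulate_null_z(
            cohort, n_snps=n_sigma_snps, seed=seed * 31 + ci, scanner=scanner
        )
        sigma = meta.estimate_sigma(Z, cid)
        rng = synth.substream(seed, "test_snps", cid)
        D = _hwe_dosage_frame(
            rng, cohort.genotypes.n_subjects, n_test_snps,
            cohort.genotypes.subjects.index,
        )
        Ztest = scanner.zscan(D)["z"].to_numpy()
        T = np.einsum("ij,ij->i", Ztest, np.linalg.solve(sigma.matrix, Ztest.T).T)
        ps[cid] = stats.chi2.sf(T, n_traits)

    pooled = np.concatenate(list(ps.values()))
    fisher_stat = -2 * np.sum([np.log(np.maximum(p, 1e-300)) for p in ps.values()], axis=0)
    p_meta = stats.chi2.sf(fisher_stat, 2 * n_cohorts)

    out = {"n_test_snps": n_test_snps, "n_cohorts": n_cohorts}
    for a in alphas:
        key = f"{a:g}".replace("0.", "")
        out[f"omnibus_typeI_{key}"] = float((pooled < a).mean())
        out[f"meta_typeI_{key}"] = float((p_meta < a).mean())
        out[f"band3se_{key}_omnibus"] = 3 * float(
            np.sqrt(a * (1 - a) / len(pooled))
        )
        out[f"band3se_{key}_meta"] = 3 * float(np.sqrt(a * (1 - a) / n_test_snps))
    return out


def power_ordering_study(
    seed: int,
    n_reps: int = 500,
    alpha: float = 1e-4,
    per_trait_power: float = 0.3,
    n_subjects: int = 400,
    n_traits: int = 8,
    affected=(0, 3, 6),
    signs=(1.0, -1.0, 1.0),
    n_sigma_snps: int = 1000,
) -> dict:
    """Omnibus vs Bonferroni-best-univariate power for a sparse signal.

    A SNP affects 3 of ``n_traits`` correlated phenotypes with
    heterogeneous signs; the per-trait effect size is set from the design
    so each univariate test has the target power at ``alpha`` (two-sided
    normal power calculation).  For the quantitative GLS scan the
    signal adds exactly ``beta / se`` to the null z-score, so each
    replicate draws a fresh genotype, scans it against the fixed null
    phenotypes, and shifts the affected components.
    """
    cohort = make_calibration_cohort("P", seed * 6151 + 5, n_subjects, n_traits)
    scanner = FastCohortScanner(cohort)
    Z0 = meta.simulate_null_z(cohort, n_snps=n_sigma_snps, seed=seed * 97 + 3, scanner=scanner)
    sigma = meta.estimate_sigma(Z0, "P")

    rng = synth.substream(seed, "power_snps")
    dos = rng.binomial(2, 0.3, size=(cohort.genotypes.n_subjects, n_reps)).astype(float)
    D = pd.DataFrame(
        dos, index=cohort.genotypes.subjects.index,
        columns=[f"r{i:04d}" for i in range(n_reps)],
    )
    res = scanner.zscan(D)
    z_null, se = res["z"].to_numpy(), res["se"].to_numpy()

    zcrit = stats.norm.isf(alpha / 2)
    ncp = zcrit + stats.norm.ppf(per_trait_power)
    z_eff = z_null.copy()
    betas = {}
    for k, s in zip(affected, signs):
        beta = s * ncp * float(se[:, k].mean())
        betas[f"T{k}"] = beta
        z_eff[:, k] = z_null[:, k] + beta / se[:, k]

    T = np.einsum("ij,ij->i", z_eff, np.linalg.solve(sigma.matrix, z_eff.T).T)
    p_omni = stats.chi2.sf(T, n_traits)
    p_uni = 2 * stats.norm.sf(np.abs(z_eff))

    return {
        "alpha": alpha,
        "n_reps": n_reps,
        "target_ncp": float(ncp),
        "betas": betas,
        "omnibus_power": float((p_omni < alpha).mean()),
        "bonferroni_power": float((p_uni.min(axis=1) < alpha / n_traits).mean()),
    }


def fisher_null_study(seed: int, n_cohorts: int = 6, n_sim: int = 10_000) -> dict:
    """The Fisher statistic over six null cohort p-values vs chi^2_12.

    Analytic df from the combiner itself plus a KS comparison of 1e4
    simulated null statistics against the chi-square reference.
    """
    _, df, _ = meta.fisher_combine([0.5] * n_cohorts)
    rng = synth.substream(seed, "fisher_null")
    p = rng.uniform(size=(n_sim, n_cohorts))
    statistic = -2 * np.log(p).sum(axis=1)
    ks = stats.kstest(statistic, "chi2", args=(df,))
    return {"df": df, "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue), "n_sim": n_sim}


def ld_grouping_agreement_study(
    seed: int, n_matrices: int = 200, max_snps: int = 30
) -> dict:
    """Connected-component grouping vs an independent brute-force oracle.

    Random sparse LD matrices (<= ``max_snps`` SNPs over 1-2 chromosomes)
    are grouped with :func:`pleioscan.ld.group_by_ld` and with a
    networkx-based component search; proxies are re-derived by direct
    argmin with the positional tie-break.  Returns exact agreement
    fractions (both should be 1.0).
    """
    import networkx as nx

    rng = synth.substream(seed, "ld_matrices")
    group_ok = proxy_ok = 0
    for _ in range(n_matrices):
        m = int(rng.integers(2, max_snps + 1))
        names = [f"s{i}" for i in range(m)]
        mat = np.eye(m)
        iu = np.triu_indices(m, 1)
        vals = rng.uniform(0, 1, size=len(iu[0])) * (rng.random(len(iu[0])) < 0.25)
        mat[iu] = vals
        mat.T[iu] = vals
        chroms = [str(c) for c in rng.integers(1, 3, size=m)]
        r2 = pd.DataFrame(mat, index=names, columns=names)
        snps = pd.DataFrame(
            {"chrom": chroms, "pos": np.arange(m)}, index=pd.Index(names, name="snp_id")
        )
        ldm = ld.LDMatrix(r2, snps)
        pvals = rng.uniform(1e-12, 1e-6, size=m)
        sig = pd.DataFrame({"snp_id": names, "p": pvals})
        groups = ld.group_by_ld(sig, ldm, threshold=0.5)

        G = nx.Graph()
        G.add_nodes_from(names)
        for i in range(m):
            for j in range(i + 1, m):
                if chroms[i] == chroms[j] and mat[i, j] > 0.5:
                    G.add_edge(names[i], names[j])
        expected = {frozenset(c) for c in nx.connected_components(G)}
        got = {frozenset(g.members) for g in groups}
        group_ok += got == expected

        pmap = dict(zip(names, pvals))
        proxy_ok += all(
            g.proxy == min(g.members, key=lambda s: (pmap[s], int(s[1:])))
            for g in groups
        )
    return {
        "n_matrices": n_matrices,
        "grouping_agreement": group_ok / n_matrices,
        "proxy_agreement": proxy_ok / n_matrices,
    }


def _event_cohort(seed, n, effects, n_families=None):
    spec = CohortSpec(
        "E", n, n_families or n, [PhenotypeDef("CHD", "time-to-event")], n_visits=1
    )
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed)
    events = synth.simulate_events(
        geno, spec, effects, synth.PiecewiseHazard((60.0, 80.0), (0.01, 0.03, 0.06)), seed
    )
    return CohortData(spec, geno, pd.DataFrame(columns=["subject_id", "family_id", "cohort_id", "age", "phenotype", "value"]), events)


def ph_diagnostics_study(
    seed: int,
    n_null_reps: int = 200,
    n_power_reps: int = 60,
    null_n: int = 800,
    power_n: int = 5000,
    breakpoint: float = 70.0,
) -> dict:
    """Grambsch-Therneau diagnostic: size under a constant log-HR and
    power against log 2 -> 0 at the breakpoint age; plus age-window HR
    recovery from one large piecewise simulation."""
    const_eff = [EffectSpec("rs0", {"CHD": 0.3})]
    null_rej = 0
    for r in range(n_null_reps):
        cohort = _event_cohort(seed * 131 + r, null_n, const_eff)
        null_rej += agedep.ph_test_quick(cohort.events, cohort.genotypes, "CHD", "rs0").violation

    pw_eff = [EffectSpec("rs0", age_effects={
        "CHD": AgeVaryingEffect((breakpoint,), (np.log(2), 0.0))})]
    power_rej = 0
    strat = None
    for r in range(n_power_reps):
        cohort = _event_cohort(seed * 151 + 7000 + r, power_n, pw_eff, n_families=power_n // 2)
        power_rej += agedep.ph_test_quick(cohort.events, cohort.genotypes, "CHD", "rs0").violation
        if r == 0:
            # the lifelines-backed route for the headline window estimates
            strat = agedep.stratified_cox(
                cohort.events, cohort.genotypes, "CHD", "rs0",
                [(40.0, breakpoint), (breakpoint, 90.0)],
            ).table

    return {
        "null_rejection_rate": null_rej / n_null_reps,
        "n_null_reps": n_null_reps,
        "band3se_null": 3 * float(np.sqrt(0.05 * 0.95 / n_null_reps)),
        "power_rejection_rate": power_rej / n_power_reps,
        "n_power_reps": n_power_reps,
        "hr_below_breakpoint": float(np.exp(strat.loc[0, "log_hr"])),
        "loghr_below_se": float(strat.loc[0, "se"]),
        "hr_above_breakpoint": float(np.exp(strat.loc[1, "log_hr"])),
        "loghr_above_se": float(strat.loc[1, "se"]),
    }


def _mediation_cohort(seed, n, alpha, gamma_m, direct):
    eff = EffectSpec(
        "rs0", {"M": alpha, "CHD": direct},
        mediation=[MediationPath("M", "CHD", alpha, gamma_m)],
    )
    spec = CohortSpec(
        "M", n, n // 2,
        [PhenotypeDef("M"), PhenotypeDef("CHD", "time-to-event")], n_visits=2,
    )
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed)
    pheno = synth.simulate_phenotypes(
        geno, spec, [eff], {"M": synth.VarianceComponents(0.0, 0.2, 0.3, 0.5)}, seed
    )
    events = synth.simulate_events(
        geno, spec, [eff], synth.PiecewiseHazard((60.0, 80.0), (0.004, 0.012, 0.03)),
        seed, mediator_values=pheno,
    )
    return CohortData(spec, geno, pheno, events)


def mediation_grid_study(seed: int, n: int = 4000, levels=(0.0, 0.3, 0.6)) -> dict:
    """NDE/NIE point-estimate bias over the (alpha, gamma_m, direct) grid.

    Truth on the log-HR scale: NDE = direct, NIE = alpha * gamma_m (no
    exposure-mediator interaction in the generator)."""
    nde_err, nie_err, nie_alpha0 = [], [], []
    for i, (a, gm, d) in enumerate(itertools.product(levels, repeat=3)):
        cohort = _mediation_cohort(seed * 211 + i, n, a, gm, d)
        spec = mediation.MediationSpec("rs0", "M", "CHD")
        data = mediation.assemble_mediation_data(cohort, spec)
        nde, nie = mediation._MediationArrays(data, spec).estimates()
        nde_err.append(nde - d)
        nie_err.append(nie - a * gm)
        if a == 0.0:
            nie_alpha0.append(nie)
    return {
        "n": n,
        "grid_points": len(nde_err),
        "nde_mean_bias": float(np.mean(nde_err)),
        "nie_mean_bias": float(np.mean(nie_err)),
        "nie_abs_mean_alpha0": float(np.mean(np.abs(nie_alpha0))),
    }


def mediation_null_coverage_study(
    seed: int, n_reps: int = 200, n_boot: int = 200, n: int = 600
) -> dict:
    """Coverage of 95% cluster-bootstrap CIs for NDE and NIE under the
    global null (no SNP effects anywhere)."""
    nde_cover = nie_cover = 0
    for r in range(n_reps):
        cohort = _mediation_cohort(seed * 911 + r, n, 0.0, 0.0, 0.0)
        spec = mediation.MediationSpec("rs0", "M", "CHD")
        data = mediation.assemble_mediation_data(cohort, spec)
        res = mediation.bootstrap_ci(data, spec, n_boot=n_boot, seed=seed * 13 + r)
        nde_cover += res.nde_ci[0] <= 0.0 <= res.nde_ci[1]
        nie_cover += res.nie_ci[0] <= 0.0 <= res.nie_ci[1]
    return {
        "n_reps": n_reps,
        "n_boot": n_boot,
        "nde_coverage": nde_cover / n_reps,
        "nie_coverage": nie_cover / n_reps,
        "band3se": 3 * float(np.sqrt(0.95 * 0.05 / n_reps)),
    }
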