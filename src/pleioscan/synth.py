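"""Multi-cohort genotype / phenotype / event simulator with known truth.

The generator emulates the structure of pooled population cohorts: several
cohorts with distinct phenotype panels, family clustering, longitudinal
quantitative endophenotypes with family- and individual-level random
effects, age-at-onset diseases on the age time scale (left truncation at
study entry), one optional cross-sectional binary cohort, and
platform-specific SNP missingness.  Every nonzero effect is recorded in a
machine-readable truth record so downstream stages can be tested without
any external data.

All randomness flows from one integer seed; per-cohort and per-purpose
substreams are derived with :func:`substream` so any single table can be
regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    BINARY,
    EVENT,
    QUANTITATIVE,
    CohortData,
    CohortSpec,
    EffectSpec,
    GenotypeMatrix,
    SNPDef,
    validate_event_table,
    validate_phenotype_table,
)

__all__ = [
    "VarianceComponents",
    "PiecewiseHazard",
    "SuiteConfig",
    "SimulatedSuite",
    "substream",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_events",
    "simulate_suite",
    "truth_record",
]


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Derive a named, reproducible child generator from a master seed."""
    tokens = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(tokens))


@dataclass(frozen=True)
class VarianceComponents:
    """Generative parameters for one quantitative (or binary) phenotype.

    For quantitative traits the visit value is

        intercept + beta*dosage + age_slope*age + sex_effect*sex
        + b_family + b_subject + eps,

    with b_family ~ N(0, family_var) shared within family, b_subject ~
    N(0, subject_var) shared across a subject's visits, and eps ~
    N(0, resid_var) per visit.  For binary traits the same intercept /
    age_slope / sex_effect are used on the logit scale and the variance
    fields are ignored.
    """

    intercept: float = 0.0
    family_var: float = 0.0
    subject_var: float = 0.0
    resid_var: float = 1.0
    age_slope: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        for name in ("family_var", "subject_var", "resid_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant baseline hazard over age, from age 0 upward.

    ``breakpoints`` are interior cut ages; ``rates`` (per year) has one
    entry per segment.  The last segment extends to +inf, so any age range
    is covered; a zero rate in a needed segment is rejected at sampling
    time only if it would make the cumulative hazard non-increasing
    everywhere past entry.
    """

    breakpoints: tuple[float, ...] = ()
    rates: tuple[float, ...] = (0.02,)

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.breakpoints) + 1:
            raise ValueError("need one rate per age segment (len(breakpoints)+1)")
        if any(r < 0 for r in self.rates):
            raise ValueError("hazard rates must be non-negative")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be increasing")


def _family_assignment(spec: CohortSpec) -> np.ndarray:
    """Round-robin subjects into families (sizes differ by at most one)."""
    return np.arange(spec.n_subjects) % spec.n_families


def simulate_genotypes(
    spec: CohortSpec, snp_panel: list[SNPDef], seed: int, family_mode: str = "independent"
) -> GenotypeMatrix:
    """Draw HWE genotypes: dosage ~ Binomial(2, MAF) per subject per SNP.

    SNPs listed in ``spec.snp_missing_set`` come out all-missing for this
    cohort (platform missingness).  Family members share a family id but
    genotypes are drawn independently by default (``family_mode
    ="independent"``) — the family correction targets phenotypes and
    outcomes, and independence keeps null calibration simple.
    ``family_mode="sibling"`` instead draws two HWE parents per family
    and transmits one allele from each to every member, giving the
    Mendelian within-family dosage correlation of 1/2.
    """
    for snp in snp_panel:
        if not 0.0 < snp.maf <= 0.5:  # SNPDef validates too; belt and braces
            raise ValueError(f"SNP {snp.snp_id!r}: MAF must lie in (0, 0.5]")
    rng = substream(seed, "geno", spec.cohort_id)
    n = spec.n_subjects
    subject_ids = [f"{spec.cohort_id}_S{i:05d}" for i in range(n)]
    fam_idx = _family_assignment(spec)
    family_ids = [f"{spec.cohort_id}_F{i:05d}" for i in fam_idx]

    mafs = np.array([s.maf for s in snp_panel])
    if family_mode == "independent":
        dos = rng.binomial(2, mafs[None, :], size=(n, len(snp_panel))).astype(float)
    elif family_mode == "sibling":
        n_fam = spec.n_families
        m = len(snp_panel)
        # parental haplotypes per family: 2 parents x 2 alleles each
        par = rng.binomial(1, mafs[None, None, :], size=(n_fam, 4, m))
        pick_p = rng.integers(0, 2, size=(n, m))  # which paternal allele
        pick_m = rng.integers(0, 2, size=(n, m))  # which maternal allele
        fam_par = par[fam_idx]  # (n, 4, m)
        a1 = np.take_along_axis(fam_par[:, 0:2, :], pick_p[:, None, :], axis=1)[:, 0, :]
        a2 = np.take_along_axis(fam_par[:, 2:4, :], pick_m[:, None, :], axis=1)[:, 0, :]
        dos = (a1 + a2).astype(float)
    else:
        raise ValueError("family_mode must be 'independent' or 'sibling'")
    for j, s in enumerate(snp_panel):
        if s.snp_id in spec.snp_missing_set:
            dos[:, j] = np.nan

    dosages = pd.DataFrame(
        dos, index=pd.Index(subject_ids, name="subject_id"),
        columns=[s.snp_id for s in snp_panel],
    )
    subjects = pd.DataFrame(
        {
            "family_id": family_ids,
            "cohort_id": spec.cohort_id,
            "sex": rng.integers(0, 2, size=n),
            "center": rng.integers(0, spec.n_centers, size=n),
            "entry_age": rng.uniform(*spec.entry_age_range, size=n),
        },
        index=dosages.index,
    )
    snps = pd.DataFrame(
        {
            "maf": mafs,
            "chrom": [s.chrom for s in snp_panel],
            "pos": [s.pos for s in snp_panel],
            "info_score": [s.info_score for s in snp_panel],
        },
        index=pd.Index([s.snp_id for s in snp_panel], name="snp_id"),
    )
    return GenotypeMatrix(dosages, subjects, snps)


def _effect_dosage(geno: GenotypeMatrix, snp_id: str) -> np.ndarray:
    """Dosage vector used in generative linear predictors.

    Missing dosages are replaced by the SNP's expected dosage so a
    platform-missing SNP contributes no association signal.
    """
    d = geno.dosages[snp_id].to_numpy(dtype=float)
    if np.isnan(d).any():
        fill = 2.0 * float(geno.snps.loc[snp_id, "maf"])
        d = np.where(np.isnan(d), fill, d)
    return d


def _trait_correlation(labels: list[str], trait_corr) -> np.ndarray:
    k = len(labels)
    if trait_corr is None:
        return np.eye(k)
    R = np.asarray(trait_corr, dtype=float)
    if R.shape != (k, k):
        raise ValueError(f"trait_corr must be {k}x{k} for panel {labels}")
    return R


def simulate_phenotypes(
    geno: GenotypeMatrix,
    spec: CohortSpec,
    effects: list[EffectSpec],
    variance_components: dict[str, VarianceComponents],
    seed: int,
    missing_rate: float = 0.0,
    trait_corr=None,
) -> pd.DataFrame:
    """Generate the long-format phenotype table for one cohort.

    Quantitative traits get ``spec.n_visits`` visits at ``visit_spacing``
    year intervals from entry; binary traits are cross-sectional (one row
    at entry, value in {0, 1} from a logistic model).  ``trait_corr``
    (quantitative traits only, panel order) correlates the family,
    subject and residual draws across traits with the same matrix, so the
    total cross-trait phenotype correlation equals ``trait_corr``
    regardless of the variance partition.
    """
    rng = substream(seed, "pheno", spec.cohort_id)
    quant = spec.panel_of_kind(QUANTITATIVE)
    binary = spec.panel_of_kind(BINARY)
    for label in quant + binary:
        if label not in variance_components:
            raise ValueError(f"no variance components for phenotype {label!r}")

    n = spec.n_subjects
    subj = geno.subjects
    fam_codes = pd.factorize(subj["family_id"])[0]
    n_fam = fam_codes.max() + 1
    sex = subj["sex"].to_numpy()
    entry = subj["entry_age"].to_numpy()

    rows: list[pd.DataFrame] = []
    if quant:
        R = _trait_correlation(quant, trait_corr)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(quant)))
        vcs = [variance_components[q] for q in quant]
        sd_fam = np.array([np.sqrt(v.family_var) for v in vcs])
        sd_sub = np.array([np.sqrt(v.subject_var) for v in vcs])
        sd_res = np.array([np.sqrt(v.resid_var) for v in vcs])

        b_fam = (rng.standard_normal((n_fam, len(quant))) @ L.T) * sd_fam
        b_sub = (rng.standard_normal((n, len(quant))) @ L.T) * sd_sub
        gen_effect = np.zeros((n, len(quant)))
        for eff in effects:
            if eff.snp_id not in geno.dosages.columns:
                continue
            d = _effect_dosage(geno, eff.snp_id)
            for k, label in enumerate(quant):
                beta = eff.effects.get(label, 0.0)
                if beta:
                    gen_effect[:, k] += beta * d

        for visit in range(spec.n_visits):
            age = entry + visit * spec.visit_spacing
            eps = (rng.standard_normal((n, len(quant))) @ L.T) * sd_res
            for k, label in enumerate(quant):
                v = vcs[k]
                value = (
                    v.intercept
                    + gen_effect[:, k]
                    + v.age_slope * age
                    + v.sex_effect * sex
                    + b_fam[fam_codes, k]
                    + b_sub[:, k]
                    + eps[:, k]
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": subj.index,
                            "family_id": subj["family_id"].to_numpy(),
                            "cohort_id": spec.cohort_id,
                            "age": age,
                            "phenotype": label,
                            "value": value,
                        }
                    )
                )

    for label in binary:
        v = variance_components[label]
        lp = v.intercept + v.age_slope * entry + v.sex_effect * sex
        for eff in effects:
            if eff.snp_id in geno.dosages.columns and eff.effects.get(label, 0.0):
                lp = lp + eff.effects[label] * _effect_dosage(geno, eff.snp_id)
        prob = 1.0 / (1.0 + np.exp(-lp))
        value = (rng.uniform(size=n) < prob).astype(float)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj.index,
                    "family_id": subj["family_id"].to_numpy(),
                    "cohort_id": spec.cohort_id,
                    "age": entry,
                    "phenotype": label,
                    "value": value,
                }
            )
        )

    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "family_id", "cohort_id", "age", "phenotype", "value"]
        )
    out = pd.concat(rows, ignore_index=True)
    if missing_rate > 0:
        keep = rng.uniform(size=len(out)) >= missing_rate
        out = out.loc[keep].reset_index(drop=True)
    out = out.sort_values(["phenotype", "subject_id", "age"], kind="mergesort").reset_index(
        drop=True
    )
    validate_phenotype_table(out)
    return out


def _merged_edges(
    baseline: PiecewiseHazard, effects: list[EffectSpec], disease: str, max_age: float
) -> np.ndarray:
    cuts = set(baseline.breakpoints)
    for eff in effects:
        if disease in eff.age_effects:
            cuts.update(eff.age_effects[disease].breakpoints)
    edges = np.array(sorted(c for c in cuts if c < max_age))
    return np.concatenate([[0.0], edges, [max_age]])


def simulate_events(
    geno: GenotypeMatrix,
    spec: CohortSpec,
    effects: list[EffectSpec],
    baseline_hazard,
    seed: int,
    mediator_values: pd.DataFrame | None = None,
    admin_age: float = 90.0,
    dropout_rate: float = 0.02,
    sex_loghr: float = 0.0,
    max_age: float = 110.0,
) -> pd.DataFrame:
    """Draw age-at-onset event records by hazard inversion.

    Age is the time scale: a subject's event age is drawn from the
    conditional distribution given survival to entry (equivalently the
    cumulative hazard is integrated from the entry age), which respects
    left truncation.  The hazard is

        lambda_i(a) = lambda0(a) * exp(beta(a)*g_i + gamma_m*M_i + sex_loghr*sex_i)

    with piecewise-constant lambda0 and beta(a).  Censoring is
    administrative at ``admin_age`` plus independent exponential dropout
    from entry at ``dropout_rate`` per year.  Mediator values (baseline
    measurement, centered at the cohort mean) feed the gamma_m term for
    diseases with a configured mediation path.
    """
    if isinstance(baseline_hazard, PiecewiseHazard):
        hazards = {d: baseline_hazard for d in spec.panel_of_kind(EVENT)}
    else:
        hazards = dict(baseline_hazard)

    rng = substream(seed, "events", spec.cohort_id)
    subj = geno.subjects
    n = spec.n_subjects
    entry = subj["entry_age"].to_numpy()
    sex = subj["sex"].to_numpy()
    if entry.max() >= max_age:
        raise ValueError("entry ages must be below max_age")

    baseline_mediator: dict[str, np.ndarray] = {}
    if mediator_values is not None and len(mediator_values):
        first = (
            mediator_values.sort_values("age", kind="mergesort")
            .groupby(["phenotype", "subject_id"], sort=False)["value"]
            .first()
        )
        for label in mediator_values["phenotype"].unique():
            vals = first.loc[label].reindex(subj.index)
            centered = vals.to_numpy(dtype=float)
            centered = np.where(np.isnan(centered), 0.0, centered - np.nanmean(centered))
            baseline_mediator[label] = centered

    frames = []
    for disease in spec.panel_of_kind(EVENT):
        if disease not in hazards:
            raise ValueError(f"no baseline hazard configured for disease {disease!r}")
        h0 = hazards[disease]
        edges = _merged_edges(h0, effects, disease, max_age)
        seg_mid = 0.5 * (edges[:-1] + edges[1:])
        seg_len = np.diff(edges)
        base_rate = np.asarray(h0.rates)[
            np.searchsorted(np.asarray(h0.breakpoints), seg_mid, side="right")
        ]
        if not (base_rate[edges[1:] > entry.min()] > 0).any():
            raise ValueError(
                f"baseline hazard for {disease!r} is zero over the whole "
                "observable age range"
            )

        lp_const = sex_loghr * sex
        for eff in effects:
            for path in eff.mediation:
                if path.disease == disease and path.mediator in baseline_mediator:
                    lp_const = lp_const + path.gamma_m * baseline_mediator[path.mediator]
        lp_age = np.zeros((n, len(seg_mid)))
        for eff in effects:
            if eff.snp_id not in geno.dosages.columns:
                continue
            d = _effect_dosage(geno, eff.snp_id)
            lp_age += eff.disease_loghr(disease, seg_mid[None, :], d[:, None])

        # subject x segment hazard, then invert the cumulative hazard from entry
        lam = base_rate[None, :] * np.exp(lp_const[:, None] + lp_age)
        # exposure time of each subject in each segment (0 before entry)
        lo = np.maximum(edges[:-1][None, :], entry[:, None])
        expo = np.clip(edges[1:][None, :] - lo, 0.0, None)
        cum = np.cumsum(lam * expo, axis=1)
        target = rng.exponential(size=n)
        seg_idx = np.argmax(cum >= target[:, None], axis=1)
        reached = cum[:, -1] >= target
        prev = np.where(seg_idx > 0, np.take_along_axis(cum, np.maximum(seg_idx - 1, 0)[:, None], 1)[:, 0], 0.0)
        lam_seg = np.take_along_axis(lam, seg_idx[:, None], 1)[:, 0]
        lo_seg = np.take_along_axis(lo, seg_idx[:, None], 1)[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            event_age = lo_seg + (target - prev) / lam_seg
        event_age = np.where(reached, event_age, np.inf)

        censor = entry + rng.exponential(scale=1.0 / max(dropout_rate, 1e-12), size=n)
        censor = np.minimum(censor, admin_age)
        exit_age = np.minimum(event_age, censor)
        indicator = (event_age <= censor).astype(int)
        exit_age = np.maximum(exit_age, entry + 1e-6)

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subj.index,
                    "family_id": subj["family_id"].to_numpy(),
                    "cohort_id": spec.cohort_id,
                    "entry_age": entry,
                    "exit_age": exit_age,
                    "event": indicator,
                    "disease": disease,
                }
            )
        )

    if not frames:
        return pd.DataFrame(
            columns=[
                "subject_id", "family_id", "cohort_id",
                "entry_age", "exit_age", "event", "disease",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    validate_event_table(out)
    return out


class SuiteConfig:
    """Global design of a simulated multi-cohort study."""

    def __init__(
        self,
        cohorts,
        snp_panel,
        effects=None,
        variance_components=None,
        baseline_hazards=None,
        trait_corr=None,
        missing_rate=0.0,
        admin_age=90.0,
        dropout_rate=0.02,
    ):
        self.cohorts = list(cohorts)
        self.snp_panel = list(snp_panel)
        self.effects = list(effects or [])
        self.variance_components = dict(variance_components or {})
        self.baseline_hazards = dict(baseline_hazards or {})
        self.trait_corr = trait_corr
        self.missing_rate = missing_rate
        self.admin_age = admin_age
        self.dropout_rate = dropout_rate


@dataclass
class SimulatedSuite:
    cohorts: dict[str, CohortData]
    truth: dict[str, str]


def truth_record(config: SuiteConfig, seed: int) -> dict[str, str]:
    """Flat key-value record of every generative signal (the 'truth')."""
    rec: dict[str, str] = {"seed": str(seed)}
    rec["cohorts"] = ",".join(c.cohort_id for c in config.cohorts)
    for eff in config.effects:
        for pheno, beta in sorted(eff.effects.items()):
            if beta != 0.0:
                rec[f"effect/{eff.snp_id}/{pheno}"] = repr(float(beta))
        for disease, ave in sorted(eff.age_effects.items()):
            rec[f"age_effect/{eff.snp_id}/{disease}/breakpoints"] = ",".join(
                repr(float(b)) for b in ave.breakpoints
            )
            rec[f"age_effect/{eff.snp_id}/{disease}/log_hazards"] = ",".join(
                repr(float(b)) for b in ave.log_hazards
            )
        for path in eff.mediation:
            rec[f"mediation/{eff.snp_id}/{path.disease}/{path.mediator}"] = (
                f"alpha={path.alpha!r};gamma_m={path.gamma_m!r}"
            )
    return rec


def simulate_suite(config: SuiteConfig, seed: int) -> SimulatedSuite:
    """Generate all cohorts of a study plus the truth record.

    Rejects configurations in which no SNP is genotyped in two or more
    cohorts, since cross-cohort meta-analysis would be empty.
    """
    if len(config.cohorts) < 1:
        raise ValueError("config lists no cohorts")
    if len(config.cohorts) >= 2:
        counts: dict[str, int] = {}
        for spec in config.cohorts:
            for s in config.snp_panel:
                if s.snp_id not in spec.snp_missing_set:
                    counts[s.snp_id] = counts.get(s.snp_id, 0) + 1
        if not any(v >= 2 for v in counts.values()):
            raise ValueError("no SNP overlaps between cohorts")

    cohorts: dict[str, CohortData] = {}
    for spec in config.cohorts:
        geno = simulate_genotypes(spec, config.snp_panel, seed)
        pheno = simulate_phenotypes(
            geno,
            spec,
            config.effects,
            config.variance_components,
            seed,
            missing_rate=config.missing_rate,
            trait_corr=config.trait_corr,
        )
        needs_mediator = any(
            path.disease in spec.panel_of_kind(EVENT)
            for eff in config.effects
            for path in eff.mediation
        )
        events = simulate_events(
            geno,
            spec,
            config.effects,
            config.baseline_hazards,
            seed,
            mediator_values=pheno if needs_mediator else None,
            admin_age=config.admin_age,
            dropout_rate=config.dropout_rate,
        )
        cohorts[spec.cohort_id] = CohortData(spec, geno, pheno, events)
    return SimulatedSuite(cohorts, truth_record(config, seed))
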