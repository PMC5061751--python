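"""Core data containers shared across the pipeline.

Tabular data (phenotype visits, event records, summary statistics) live in
plain :class:`pandas.DataFrame` objects with documented column contracts;
the dataclasses here carry the metadata those tables do not express —
cohort design, generative effect sizes, genotype panels and fitted-result
bundles.

Column contracts
----------------
Phenotype table (long format), one row per (subject, visit, phenotype):
    ``subject_id, family_id, cohort_id, age, phenotype, value``
Event table, one row per (subject, disease):
    ``subject_id, family_id, cohort_id, entry_age, exit_age, event, disease``
Summary statistics, one row per (SNP, phenotype):
    ``snp_id, phenotype, cohort_id, model, beta, se, z, p, n_obs, n_subjects, flag``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["subject_id", "family_id", "cohort_id", "age", "phenotype", "value"]
EVENT_COLUMNS = [
    "subject_id",
    "family_id",
    "cohort_id",
    "entry_age",
    "exit_age",
    "event",
    "disease",
]
STAT_COLUMNS = [
    "snp_id",
    "phenotype",
    "cohort_id",
    "model",
    "beta",
    "se",
    "z",
    "p",
    "n_obs",
    "n_subjects",
    "flag",
]

QUANTITATIVE = "quantitative-longitudinal"
BINARY = "binary-cross-sectional"
EVENT = "time-to-event"
PHENOTYPE_KINDS = (QUANTITATIVE, BINARY, EVENT)


@dataclass(frozen=True)
class PhenotypeDef:
    """One entry of a cohort's phenotype panel."""

    name: str
    kind: str = QUANTITATIVE

    def __post_init__(self) -> None:
        if self.kind not in PHENOTYPE_KINDS:
            raise ValueError(f"unknown phenotype kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class SNPDef:
    """A SNP in the simulated panel: identity, position and frequency."""

    snp_id: str
    maf: float
    chrom: str = "1"
    pos: int = 0
    info_score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(
                f"SNP {self.snp_id!r}: MAF must lie in (0, 0.5], got {self.maf}"
            )


@dataclass
class CohortSpec:
    """Design of one simulated cohort.

    ``phenotype_panel`` mirrors the heterogeneity of real multi-cohort
    studies: each cohort measures its own mix of longitudinal quantitative
    traits, cross-sectional binary outcomes and age-at-onset diseases,
    and may miss SNPs entirely (platform differences).
    """

    cohort_id: str
    n_subjects: int
    n_families: int
    phenotype_panel: list[PhenotypeDef]
    n_visits: int = 1
    entry_age_range: tuple[float, float] = (45.0, 65.0)
    visit_spacing: float = 3.0
    snp_missing_set: tuple[str, ...] = ()
    n_centers: int = 2

    def __post_init__(self) -> None:
        if self.n_families > self.n_subjects:
            raise ValueError("n_families must be <= n_subjects")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        names = [p.name for p in self.phenotype_panel]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate phenotype labels in panel: {names}")
        if not 2 <= self.n_centers <= 8:
            raise ValueError("n_centers must be between 2 and 8")

    @property
    def panel_names(self) -> list[str]:
        return [p.name for p in self.phenotype_panel]

    def panel_of_kind(self, kind: str) -> list[str]:
        return [p.name for p in self.phenotype_panel if p.kind == kind]


@dataclass(frozen=True)
class AgeVaryingEffect:
    """Piecewise-constant log-hazard ratio per minor allele over the age axis.

    ``breakpoints`` are the interior cut ages; ``log_hazards`` has one value
    per segment (``len(breakpoints) + 1``), so the segments partition the
    whole axis.
    """

    breakpoints: tuple[float, ...]
    log_hazards: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.log_hazards) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one log-hazard per age segment")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be increasing")

    def at(self, age: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.breakpoints), age, side="right")
        return np.asarray(self.log_hazards)[idx]


@dataclass(frozen=True)
class MediationPath:
    """A mediated path SNP -> mediator -> disease.

    alpha: mediator units per minor allele; gamma_m: log-hazard of the
    disease per mediator unit.
    """

    mediator: str
    disease: str
    alpha: float
    gamma_m: float


@dataclass
class EffectSpec:
    """Generative truth for one SNP.

    ``effects`` maps phenotype label to the constant per-allele effect
    (trait units, log-odds, or log-hazard depending on phenotype kind);
    ``age_effects`` overrides event-trait effects with piecewise
    log-hazards; ``mediation`` lists indirect paths.
    """

    snp_id: str
    effects: dict[str, float] = field(default_factory=dict)
    age_effects: dict[str, AgeVaryingEffect] = field(default_factory=dict)
    mediation: list[MediationPath] = field(default_factory=list)

    def disease_loghr(self, disease: str, age: np.ndarray, dosage: np.ndarray) -> np.ndarray:
        """Per-subject log-hazard contribution of this SNP at given ages."""
        if disease in self.age_effects:
            return self.age_effects[disease].at(age) * dosage
        return self.effects.get(disease, 0.0) * dosage


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive minor-allele dosages with sample metadata.

    dosages: DataFrame indexed by subject_id, one float column per SNP,
        values in {0, 1, 2} or NaN for missing.
    subjects: DataFrame indexed by subject_id with columns
        ``family_id, cohort_id, sex, center, entry_age``.
    snps: DataFrame indexed by snp_id with columns
        ``maf, chrom, pos, info_score``.
    """

    dosages: pd.DataFrame
    subjects: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.subjects.index):
            raise ValueError("dosages and subjects must share the subject index")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def cohort_id(self) -> str:
        return str(self.subjects["cohort_id"].iloc[0])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        keep = [s for s in snp_ids if s in self.dosages.columns]
        return GenotypeMatrix(
            self.dosages[keep].copy(), self.subjects, self.snps.loc[keep].copy()
        )


@dataclass
class CohortData:
    """Everything generated or loaded for one cohort."""

    spec: CohortSpec
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    events: pd.DataFrame


def validate_phenotype_table(df: pd.DataFrame) -> None:
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df.duplicated(["subject_id", "age", "phenotype"]).any():
        raise ValueError("duplicate (subject, visit age, phenotype) rows")


def validate_event_table(df: pd.DataFrame) -> None:
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if not (df["exit_age"] > df["entry_age"]).all():
        raise ValueError("exit age must exceed entry age")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0/1")


@dataclass
class SummaryStat:
    """Per (SNP, phenotype, cohort) univariate association result."""

    snp_id: str
    phenotype: str
    cohort_id: str
    model: str
    beta: float = np.nan
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan
    n_obs: int = 0
    n_subjects: int = 0
    flag: str = ""


def stats_frame(stats: list[SummaryStat]) -> pd.DataFrame:
    rows = [
        {
            "snp_id": s.snp_id,
            "phenotype": s.phenotype,
            "cohort_id": s.cohort_id,
            "model": s.model,
            "beta": s.beta,
            "se": s.se,
            "z": s.z,
            "p": s.p,
            "n_obs": s.n_obs,
            "n_subjects": s.n_subjects,
            "flag": s.flag,
        }
        for s in stats
    ]
    df = pd.DataFrame(rows, columns=STAT_COLUMNS)
    return df.sort_values(["snp_id", "phenotype"], kind="mergesort").reset_index(drop=True)
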