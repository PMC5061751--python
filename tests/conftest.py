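"""Shared fixtures: small simulated cohorts built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pleioscan.datatypes import (
    AgeVaryingEffect,
    CohortData,
    CohortSpec,
    EffectSpec,
    MediationPath,
    PhenotypeDef,
    SNPDef,
)
from pleioscan import synth


def build_cohort(
    cohort_id="C1",
    n_subjects=600,
    n_families=300,
    panel=None,
    snp_panel=None,
    effects=None,
    vcs=None,
    hazards=None,
    n_visits=2,
    seed=11,
    trait_corr=None,
    dropout_rate=0.02,
    admin_age=90.0,
    entry_age_range=(45.0, 65.0),
) -> CohortData:
    panel = panel or [
        PhenotypeDef("BMI"),
        PhenotypeDef("BG"),
        PhenotypeDef("CHD", "time-to-event"),
    ]
    snp_panel = snp_panel or [SNPDef("rs0", 0.3), SNPDef("rs1", 0.2)]
    effects = effects or []
    vcs = vcs or {
        p.name: synth.VarianceComponents(0.0, 0.3, 0.5, 1.0, 0.01, 0.2)
        for p in panel
        if p.kind != "time-to-event"
    }
    hazards = hazards or synth.PiecewiseHazard((60.0, 80.0), (0.01, 0.03, 0.06))
    spec = CohortSpec(
        cohort_id,
        n_subjects,
        n_families,
        panel,
        n_visits=n_visits,
        entry_age_range=entry_age_range,
    )
    geno = synth.simulate_genotypes(spec, snp_panel, seed)
    pheno = synth.simulate_phenotypes(
        geno, spec, effects, vcs, seed, trait_corr=trait_corr
    )
    needs_med = any(path for e in effects for path in e.mediation)
    events = synth.simulate_events(
        geno,
        spec,
        effects,
        hazards,
        seed,
        mediator_values=pheno if needs_med else None,
        dropout_rate=dropout_rate,
        admin_age=admin_age,
    )
    return CohortData(spec, geno, pheno, events)


@pytest.fixture(scope="session")
def null_cohort() -> CohortData:
    """Family cohort with two longitudinal traits and one disease, no effects."""
    return build_cohort()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
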