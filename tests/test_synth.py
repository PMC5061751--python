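"""Generator correctness: Hardy-Weinberg sampling, variance structure,
hazard inversion, and the suite's truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan import qc, synth
from pleioscan.datatypes import (
    AgeVaryingEffect,
    CohortSpec,
    EffectSpec,
    GenotypeMatrix,
    MediationPath,
    PhenotypeDef,
    SNPDef,
)

from conftest import build_cohort


def _one_trait_spec(n, n_families=None, n_visits=1, label="Q"):
    return CohortSpec(
        "G", n, n_families or n, [PhenotypeDef(label)], n_visits=n_visits
    )


@pytest.mark.parametrize("maf", [0.5, 0.2])
def test_genotypes_match_hwe_expectations(maf):
    """Dosage mean and genotype frequencies converge to HWE values at n=1e5."""
    n = 100_000
    spec = _one_trait_spec(n)
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", maf)], seed=3)
    d = geno.dosages["rs0"].to_numpy()
    se_mean = np.sqrt(2 * maf * (1 - maf) / n)
    assert abs(d.mean() - 2 * maf) < 3 * se_mean
    for g, expect in ((0, (1 - maf) ** 2), (1, 2 * maf * (1 - maf)), (2, maf**2)):
        freq = (d == g).mean()
        assert abs(freq - expect) < 3 * np.sqrt(expect * (1 - expect) / n)


@pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
def test_invalid_maf_rejected_naming_snp(maf):
    with pytest.raises(ValueError, match="badsnp"):
        SNPDef("badsnp", maf)


def test_simulated_genotypes_pass_hwe_filter():
    """The HWE chi-square is non-significant at the 1e-5 filter threshold
    in >= 95 of 100 seeds for genotypes drawn under HWE."""
    spec = _one_trait_spec(2000)
    ok = 0
    for seed in range(100):
        geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.2)], seed=seed)
        d = geno.dosages["rs0"].to_numpy()
        res = qc.hwe_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        ok += res.p >= 1e-5
    assert ok >= 95


def test_zero_variance_phenotype_is_constant():
    spec = _one_trait_spec(50, n_visits=2)
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=1)
    vcs = {"Q": synth.VarianceComponents(intercept=7.5, resid_var=0.0)}
    ph = synth.simulate_phenotypes(geno, spec, [], vcs, seed=1)
    assert np.allclose(ph["value"], 7.5)


def test_negative_variance_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        synth.VarianceComponents(resid_var=-1.0)


def test_ols_recovers_generated_slope():
    """beta=0.5, unit residual variance, singletons, one visit: the OLS
    slope (closed-form oracle) lands within 3 SE of truth."""
    n = 10_000
    spec = _one_trait_spec(n)
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=5)
    vcs = {"Q": synth.VarianceComponents(resid_var=1.0)}
    eff = [EffectSpec("rs0", {"Q": 0.5})]
    ph = synth.simulate_phenotypes(geno, spec, eff, vcs, seed=5)
    d = geno.dosages["rs0"].reindex(ph["subject_id"]).to_numpy()
    res = stats.linregress(d, ph["value"])
    assert abs(res.slope - 0.5) < 3 * res.stderr


def test_intraclass_correlation_of_repeat_visits():
    """family 2 + subject 1 + residual 1 => corr(visit1, visit2) ~ 3/4."""
    n = 8000
    spec = _one_trait_spec(n, n_families=n // 2, n_visits=2)
    vcs = {"Q": synth.VarianceComponents(0, 2.0, 1.0, 1.0)}
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=6)
    ph = synth.simulate_phenotypes(geno, spec, [], vcs, seed=6)
    per_subj = ph.sort_values(["subject_id", "age"]).groupby("subject_id")["value"]
    arr = np.array([g.to_numpy()[:2] for _, g in per_subj])
    icc = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
    assert abs(icc - 0.75) < 0.03


def test_null_event_times_are_exponential():
    """Constant hazard, no effects, no censoring: waiting times from entry
    are Exp(rate); KS non-rejection at alpha=0.01 in >= 95 of 100 seeds."""
    spec = CohortSpec("G", 300, 300, [PhenotypeDef("D", "time-to-event")],
                      entry_age_range=(50.0, 50.0))
    rate = 0.05
    ok = 0
    for seed in range(100):
        geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=seed)
        ev = synth.simulate_events(
            geno, spec, [], synth.PiecewiseHazard((), (rate,)), seed=seed,
            dropout_rate=0.0, admin_age=1e6, max_age=1e6 + 60,
        )
        wait = (ev["exit_age"] - ev["entry_age"]).to_numpy()
        assert ev["event"].all()
        p = stats.kstest(wait, "expon", args=(0, 1 / rate)).pvalue
        ok += p >= 0.01
    assert ok >= 95


def test_event_stream_independent_of_dosage_under_null():
    """With beta=0 the same seed yields identical event ages whether every
    dosage is 0 or 2."""
    spec = CohortSpec("G", 500, 500, [PhenotypeDef("D", "time-to-event")])
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=4)
    out = {}
    for fill in (0.0, 2.0):
        g2 = GenotypeMatrix(
            geno.dosages.copy() * 0 + fill, geno.subjects, geno.snps
        )
        out[fill] = synth.simulate_events(
            g2, spec, [EffectSpec("rs0", {"D": 0.0})],
            synth.PiecewiseHazard((), (0.03,)), seed=9,
        )
    pd.testing.assert_frame_equal(out[0.0], out[2.0])


def test_piecewise_generator_recovers_hr_below_breakpoint():
    """log-HR = log 2 below age 70, 0 above: a Cox fit restricted to risk
    sets below 70 recovers HR 2 within 3 SE."""
    from pleioscan import agedep

    cohort = build_cohort(
        n_subjects=3000,
        n_families=3000,
        panel=[PhenotypeDef("CHD", "time-to-event")],
        snp_panel=[SNPDef("rs0", 0.3)],
        effects=[EffectSpec("rs0", age_effects={
            "CHD": AgeVaryingEffect((70.0,), (np.log(2), 0.0))})],
        seed=21,
    )
    sh = agedep.stratified_cox(
        cohort.events, cohort.genotypes, "CHD", "rs0", [(40.0, 70.0)]
    )
    row = sh.table.iloc[0]
    assert abs(row["log_hr"] - np.log(2)) < 3 * row["se"]


def test_sibling_transmission_mode_correlates_families():
    """Sibling mode: within-family dosage correlation ~ 1/2 (Mendelian),
    marginal frequencies still HWE; independent mode stays uncorrelated."""
    spec = CohortSpec("G", 20_000, 10_000, [PhenotypeDef("Q")])
    for mode, target in (("sibling", 0.5), ("independent", 0.0)):
        geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3)], seed=13,
                                        family_mode=mode)
        d = geno.dosages["rs0"].to_numpy()
        assert abs(d.mean() - 0.6) < 3 * np.sqrt(0.42 / len(d))
        # round-robin assignment pairs subject i with subject i + n_families
        sib = np.corrcoef(d[:10_000], d[10_000:])[0, 1]
        assert abs(sib - target) < 0.03


def test_platform_missing_snps_all_nan():
    spec = CohortSpec("G", 100, 50, [PhenotypeDef("Q")], snp_missing_set=("rs1",))
    geno = synth.simulate_genotypes(spec, [SNPDef("rs0", 0.3), SNPDef("rs1", 0.2)], seed=2)
    assert geno.dosages["rs1"].isna().all()
    assert not geno.dosages["rs0"].isna().any()


class TestSuite:
    def _config(self, effects=(), cohorts=None):
        cohorts = cohorts or [
            CohortSpec("A", 60, 30, [PhenotypeDef("BMI"), PhenotypeDef("CHD", "time-to-event")]),
            CohortSpec("B", 50, 25, [PhenotypeDef("BMI")], snp_missing_set=("rs1",)),
        ]
        return synth.SuiteConfig(
            cohorts,
            [SNPDef("rs0", 0.3), SNPDef("rs1", 0.2)],
            effects=list(effects),
            variance_components={"BMI": synth.VarianceComponents()},
            baseline_hazards={"CHD": synth.PiecewiseHazard((), (0.03,))},
        )

    def test_null_config_has_empty_truth(self):
        suite = synth.simulate_suite(self._config(), seed=1)
        assert not [k for k in suite.truth if k.startswith(("effect/", "mediation/"))]

    def test_truth_round_trips_through_text(self, tmp_path):
        from pleioscan import io as pio

        eff = EffectSpec(
            "rs0", {"BMI": 0.2},
            mediation=[MediationPath("BMI", "CHD", 0.5, 0.3)],
        )
        suite = synth.simulate_suite(self._config([eff]), seed=1)
        path = tmp_path / "truth.tsv"
        pio.write_truth(suite.truth, path)
        assert pio.read_truth(path) == suite.truth
        assert suite.truth["mediation/rs0/CHD/BMI"] == "alpha=0.5;gamma_m=0.3"

    def test_panels_echo_config(self):
        """Heterogeneous panels (e.g. a cohort without SBP) come back exactly."""
        panels = {
            "ARIC": ["VR", "BG", "BMI", "SBP", "CHD"],
            "MESA": ["VR", "BG", "BMI", "CHD"],  # no SBP
            "HRS": ["BG", "BMI"],
        }
        cohorts = []
        for cid, names in panels.items():
            defs = [
                PhenotypeDef(n, "time-to-event" if n == "CHD" else "quantitative-longitudinal")
                for n in names
            ]
            cohorts.append(CohortSpec(cid, 40, 20, defs))
        cfg = self._config(cohorts=cohorts)
        cfg.variance_components = {
            n: synth.VarianceComponents() for names in panels.values() for n in names
        }
        suite = synth.simulate_suite(cfg, seed=2)
        for cid, names in panels.items():
            assert suite.cohorts[cid].spec.panel_names == names
            measured = set(suite.cohorts[cid].phenotypes["phenotype"]) | set(
                suite.cohorts[cid].events["disease"]
            )
            assert measured == set(names)

    def test_disjoint_snp_panels_rejected(self):
        cfg = self._config()
        cfg.cohorts[0].snp_missing_set = ("rs0",)
        cfg.cohorts[1].snp_missing_set = ("rs1",)
        cfg.cohorts[0].snp_missing_set = ("rs0", "rs1")
        with pytest.raises(ValueError, match="overlap"):
            synth.simulate_suite(cfg, seed=1)
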