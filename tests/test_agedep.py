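"""PH diagnostics, age-window stratification, the cumulative effect curve
and Kaplan-Meier curves against an independent product-limit oracle."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import agedep, assoc, synth
from pleioscan.datatypes import AgeVaryingEffect, EffectSpec, PhenotypeDef, SNPDef

from conftest import build_cohort


@pytest.fixture(scope="module")
def piecewise_cohort():
    """log-HR = log 2 below 70, 0 above; n = 5000."""
    return build_cohort(
        n_subjects=5000, n_families=2500,
        panel=[PhenotypeDef("CHD", "time-to-event")],
        snp_panel=[SNPDef("rs0", 0.3)],
        effects=[EffectSpec("rs0", age_effects={
            "CHD": AgeVaryingEffect((70.0,), (np.log(2), 0.0))})],
        seed=71,
    )


@pytest.fixture(scope="module")
def piecewise_fit(piecewise_cohort):
    _, fit = assoc.fit_cox(
        piecewise_cohort.events, piecewise_cohort.genotypes, "CHD", "rs0"
    )
    return fit


class TestPHTest:
    def test_detects_age_dependent_effect(self, piecewise_fit):
        res = agedep.ph_test(piecewise_fit)
        assert res.violation and res.p < 0.01
        assert -1 <= res.rho <= 1

    def test_null_does_not_systematically_reject(self):
        """Constant-effect simulations: rejections stay near the nominal
        5% level (loose bound on a small batch; the full calibration runs
        in the acceptance suite)."""
        rejections = 0
        reps = 30
        for seed in range(reps):
            cohort = build_cohort(
                n_subjects=700, n_families=700,
                panel=[PhenotypeDef("CHD", "time-to-event")],
                snp_panel=[SNPDef("rs0", 0.3)],
                effects=[EffectSpec("rs0", {"CHD": 0.3})],
                seed=100 + seed,
            )
            _, fit = assoc.fit_cox(cohort.events, cohort.genotypes, "CHD", "rs0")
            rejections += agedep.ph_test(fit).violation
        assert rejections <= 6  # P(X > 6 | p=0.05, n=30) < 0.5%

    def test_transform_configuration_surface(self, piecewise_fit):
        res_km = agedep.ph_test(piecewise_fit, transform="km")
        res_id = agedep.ph_test(piecewise_fit, transform="identity")
        assert res_km.transform == "km" and res_id.transform == "identity"
        assert res_km.statistic != res_id.statistic

    def test_quick_route_matches_lifelines_route(self, null_cohort):
        """The Newton-solver PH test agrees with the one computed from the
        lifelines fit (same residual machinery, near-identical beta)."""
        _, fit = assoc.fit_cox(null_cohort.events, null_cohort.genotypes, "CHD", "rs0",
                               covariates=("sex",))
        a = agedep.ph_test(fit)
        b = agedep.ph_test_quick(null_cohort.events, null_cohort.genotypes, "CHD", "rs0")
        assert b.statistic == pytest.approx(a.statistic, rel=1e-3, abs=1e-6)
        assert b.p == pytest.approx(a.p, abs=1e-4)

    def test_few_events_refused(self, null_cohort):
        _, fit = assoc.fit_cox(null_cohort.events, null_cohort.genotypes, "CHD", "rs0")
        fit.n_events = 5
        with pytest.raises(ValueError, match="at least 10"):
            agedep.ph_test(fit)


class TestStratifiedCox:
    def test_recovers_both_window_effects(self, piecewise_cohort):
        sh = agedep.stratified_cox(
            piecewise_cohort.events, piecewise_cohort.genotypes, "CHD", "rs0",
            [(40.0, 70.0), (70.0, 90.0)],
        )
        young, old = sh.table.iloc[0], sh.table.iloc[1]
        assert abs(young["log_hr"] - np.log(2)) < 3 * young["se"]
        assert abs(old["log_hr"]) < 3 * old["se"]

    def test_single_window_equals_unstratified_fit(self, null_cohort):
        stat, _ = assoc.fit_cox(null_cohort.events, null_cohort.genotypes, "CHD", "rs0")
        sh = agedep.stratified_cox(
            null_cohort.events, null_cohort.genotypes, "CHD", "rs0", [(0.0, 200.0)]
        )
        assert sh.table.loc[0, "log_hr"] == pytest.approx(stat.beta, abs=1e-8)
        assert sh.table.loc[0, "se"] == pytest.approx(stat.se, abs=1e-8)

    def test_event_counts_conserved_across_windows(self, piecewise_cohort):
        ev = piecewise_cohort.events
        windows = [(40.0, 60.0), (60.0, 75.0), (75.0, 95.0)]
        sh = agedep.stratified_cox(
            ev, piecewise_cohort.genotypes, "CHD", "rs0", windows
        )
        assert sh.table["n_events"].sum() == int(ev["event"].sum())

    def test_empty_window_flagged(self, null_cohort):
        sh = agedep.stratified_cox(
            null_cohort.events, null_cohort.genotypes, "CHD", "rs0", [(20.0, 30.0)]
        )
        assert sh.table.loc[0, "flag"] == "no-events"

    def test_invalid_window_rejected(self, null_cohort):
        with pytest.raises(ValueError):
            agedep.stratified_cox(
                null_cohort.events, null_cohort.genotypes, "CHD", "rs0", [(70.0, 60.0)]
            )


class TestPiecewiseCurve:
    def test_single_bin_collapses_to_unstratified_effect(self, null_cohort):
        from pleioscan import _fastcox

        ev = null_cohort.events
        width = float(np.ceil(ev["exit_age"].max())) - 40.0
        curve = agedep.piecewise_effect_curve(
            ev, null_cohort.genotypes, "CHD", "rs0", bin_width=width, n_boot=5, seed=1
        )
        assert len(curve) == 1
        dose = null_cohort.genotypes.dosages["rs0"].reindex(ev["subject_id"]).to_numpy()
        fit = _fastcox.cox_newton(
            dose[:, None],
            ev["entry_age"].to_numpy(), ev["exit_age"].to_numpy(),
            ev["event"].to_numpy(int),
        )
        assert curve.loc[0, "cum_loghr"] == pytest.approx(fit.beta[0] * width, rel=1e-6)

    def test_null_curve_bands_cover_zero(self):
        cohort = build_cohort(
            n_subjects=2000, n_families=1000,
            panel=[PhenotypeDef("CHD", "time-to-event")],
            snp_panel=[SNPDef("rs0", 0.3)],
            effects=[], seed=73,
        )
        curve = agedep.piecewise_effect_curve(
            cohort.events, cohort.genotypes, "CHD", "rs0",
            bin_width=10.0, n_boot=100, seed=2,
        )
        informative = curve[curve["flag"] == ""]
        cover = ((informative["lo"] <= 0) & (informative["hi"] >= 0)).mean()
        assert cover >= 0.9

    def test_breakpoint_visible_in_slope(self, piecewise_cohort):
        """The per-bin increment drops at the true breakpoint (age 70)."""
        curve = agedep.piecewise_effect_curve(
            piecewise_cohort.events, piecewise_cohort.genotypes, "CHD", "rs0",
            bin_width=10.0, start_age=40.0, end_age=90.0, n_boot=10, seed=3,
        )
        inc = np.diff(np.concatenate([[0.0], curve["cum_loghr"]]))
        per_year = inc / 10.0
        before = per_year[curve["age"] <= 70]
        after = per_year[curve["age"] > 70]
        assert before[-1] > 0.5 * np.log(2)
        assert np.abs(after).max() < 0.5 * np.log(2)


class TestKM:
    def test_no_events_curve_is_one(self, null_cohort):
        ev = null_cohort.events.copy()
        ev["event"] = 0
        km = agedep.km_by_genotype(ev, null_cohort.genotypes, "CHD", "rs0")
        for df in km.values():
            assert (df["survival"] == 1.0).all()

    def test_matches_independent_product_limit_oracle(self):
        """Left-truncation-aware product-limit computed longhand matches
        the packaged estimator to 1e-12, censoring included."""
        cohort = build_cohort(
            n_subjects=500, n_families=500,
            panel=[PhenotypeDef("CHD", "time-to-event")],
            snp_panel=[SNPDef("rs0", 0.4)], seed=74, dropout_rate=0.08,
        )
        ev = cohort.events
        km = agedep.km_by_genotype(ev, cohort.genotypes, "CHD", "rs0")
        dose = cohort.genotypes.dosages["rs0"].reindex(ev["subject_id"]).to_numpy()
        for g, df in km.items():
            sub = ev[dose == g]
            entry = sub["entry_age"].to_numpy()
            exit_ = sub["exit_age"].to_numpy()
            event = sub["event"].to_numpy().astype(bool)
            surv = 1.0
            oracle = {}
            for t in sorted(np.unique(exit_[event])):
                at_risk = ((entry < t) & (exit_ >= t)).sum()
                d = ((exit_ == t) & event).sum()
                surv *= 1.0 - d / at_risk
                oracle[t] = surv
            got = df.set_index("age")["survival"]
            for t, s in oracle.items():
                assert got.loc[t] == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        cohort = build_cohort(
            n_subjects=400, n_families=400,
            panel=[PhenotypeDef("CHD", "time-to-event")],
            snp_panel=[SNPDef("rs0", 0.4)], seed=75,
            dropout_rate=0.0, admin_age=1e5,
            hazards=synth.PiecewiseHazard((), (0.15,)),
            entry_age_range=(50.0, 50.0),  # common entry: no truncation effects
        )
        ev = cohort.events
        assert ev["event"].all()
        km = agedep.km_by_genotype(ev, cohort.genotypes, "CHD", "rs0")
        dose = cohort.genotypes.dosages["rs0"].reindex(ev["subject_id"]).to_numpy()
        for g, df in km.items():
            exits = ev[dose == g]["exit_age"].to_numpy()
            surv = df.set_index("age")["survival"]
            for t in exits:
                assert surv.loc[t] == pytest.approx((exits > t).mean(), abs=1e-12)
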