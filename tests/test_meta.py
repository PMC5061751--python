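"""Omnibus statistic, Fisher combination, Sigma estimation, normality
check, phenotype-subset pruning, pre-selection and the meta step."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pleioscan import meta
from pleioscan.datatypes import PhenotypeDef
from pleioscan.meta import ZCorrelation

from conftest import build_cohort


def _sigma(mat, phenos, cid="C"):
    return ZCorrelation(cid, list(phenos), np.asarray(mat, dtype=float), 1000)


class TestOmnibus:
    def test_identity_sigma_sums_squares(self):
        res = meta.omnibus([1.0, -1.0, 2.0], _sigma(np.eye(3), ["a", "b", "c"]))
        assert res.statistic == pytest.approx(6.0, abs=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(6.0, 3), rel=1e-12)
        assert res.df == 3

    def test_zero_vector(self):
        res = meta.omnibus([0.0, 0.0], _sigma(np.eye(2), ["a", "b"]))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_two_by_two_hand_inverse(self):
        """Sigma = [[1,.5],[.5,1]], z=(2,2): the explicit inverse gives
        T = (1/0.75) * (4 - 2 - 2 + 4) = 16/3."""
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([2.0, 2.0])
        hand = float(z @ np.linalg.inv(S) @ z)
        res = meta.omnibus(z, _sigma(S, ["a", "b"]))
        assert hand == pytest.approx(16.0 / 3.0, abs=1e-12)
        assert res.statistic == pytest.approx(hand, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            meta.omnibus([1.0, 2.0, 3.0], _sigma(np.eye(2), ["a", "b"]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariance_under_reordering_and_sign_flips(self, seed):
        """T is unchanged by permuting phenotypes and by flipping the sign
        of any z component together with its Sigma rows/columns."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        A = rng.standard_normal((k, k + 2))
        S = A @ A.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        z = rng.standard_normal(k)
        labels = [f"p{i}" for i in range(k)]
        base = meta.omnibus(z, _sigma(S, labels)).statistic

        perm = rng.permutation(k)
        r1 = meta.omnibus(z[perm], _sigma(S[np.ix_(perm, perm)], [labels[i] for i in perm]))
        assert r1.statistic == pytest.approx(base, rel=1e-9)

        signs = rng.choice([-1.0, 1.0], size=k)
        S2 = S * np.outer(signs, signs)
        r2 = meta.omnibus(z * signs, _sigma(S2, labels))
        assert r2.statistic == pytest.approx(base, rel=1e-9)


class TestFisher:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(1e-12, 1.0, exclude_min=False))
    def test_single_p_is_identity(self, p):
        stat, df, comb = meta.fisher_combine([p])
        assert df == 2
        assert comb == pytest.approx(p, rel=1e-9)

    def test_all_ones(self):
        stat, df, comb = meta.fisher_combine([1.0] * 6)
        assert stat == 0.0 and df == 12 and comb == 1.0

    def test_six_halves(self):
        stat, df, comb = meta.fisher_combine([0.5] * 6)
        assert stat == pytest.approx(-12 * np.log(0.5), rel=1e-12)
        assert df == 12
        assert comb == pytest.approx(stats.chi2.sf(-12 * np.log(0.5), 12), rel=1e-12)

    def test_zero_p_rejected_and_floor_warns(self):
        with pytest.raises(ValueError):
            meta.fisher_combine([0.0, 0.5])
        with pytest.warns(UserWarning, match="floored"):
            meta.fisher_combine([1e-310, 0.5])


class TestSigma:
    def test_independent_columns_near_identity(self, rng):
        Z = pd.DataFrame(rng.standard_normal((1000, 4)), columns=list("abcd"))
        sig = meta.estimate_sigma(Z, "C")
        off = sig.matrix[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert not sig.regularized

    def test_duplicated_column_triggers_regularization(self, rng):
        x = rng.standard_normal(500)
        Z = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.standard_normal(500), "c": rng.standard_normal(500)})
        sig = meta.estimate_sigma(Z, "C")
        assert sig.matrix[0, 1] >= 0.99
        assert sig.regularized
        assert np.linalg.eigvalsh(sig.matrix).min() > 0

    def test_single_phenotype(self, rng):
        Z = pd.DataFrame({"only": rng.standard_normal(200)})
        sig = meta.estimate_sigma(Z, "C")
        assert sig.matrix.shape == (1, 1) and sig.matrix[0, 0] == pytest.approx(1.0)

    def test_constant_column_named_in_error(self, rng):
        Z = pd.DataFrame({"a": rng.standard_normal(100), "flat": np.ones(100)})
        with pytest.raises(ValueError, match="flat"):
            meta.estimate_sigma(Z, "C")

    def test_too_few_rows_rejected(self, rng):
        Z = pd.DataFrame(rng.standard_normal((20, 2)))
        with pytest.raises(ValueError):
            meta.estimate_sigma(Z, "C")


class TestHenzeZirkler:
    def test_matches_reference_implementation(self, rng):
        from pingouin import multivariate_normality

        X = pd.DataFrame(rng.standard_normal((300, 4)))
        ours = meta.henze_zirkler(X)
        ref = multivariate_normality(X)
        assert ours.statistic == pytest.approx(float(ref.hz), abs=1e-10)
        assert ours.p == pytest.approx(float(ref.pval), abs=1e-10)

    def test_dim_one_matches_direct_univariate_formula(self, rng):
        """p=1 reduces to the univariate HZ statistic computed longhand."""
        x = rng.standard_normal(150)
        ours = meta.henze_zirkler(pd.DataFrame({"z": x}))

        n = len(x)
        s2 = x.var()  # ML variance
        y = (x - x.mean()) / np.sqrt(s2)
        b = (3 / 4) ** (1 / 5) * n ** (1 / 5) / np.sqrt(2)
        term1 = sum(
            np.exp(-(b**2) / 2 * (y[i] - y[j]) ** 2) for i in range(n) for j in range(n)
        ) / n
        # direct Dj uses raw Mahalanobis of uncentered X as in the
        # standard formulation: (x - xbar)^2 / s2 for the one-point term
        term2 = 2 * (1 + b**2) ** -0.5 * np.exp(-(b**2) / (2 * (1 + b**2)) * y**2).sum()
        hz = term1 - term2 + n * (1 + 2 * b**2) ** -0.5
        assert ours.statistic == pytest.approx(float(hz), abs=1e-10)

    def test_calibrated_under_normality(self, rng):
        """Rejection rate at alpha=0.05 stays within 3 binomial SE over
        100 repetitions of n=400, dim 3 standard-normal draws."""
        rej = 0
        reps = 100
        for _ in range(reps):
            X = pd.DataFrame(rng.standard_normal((400, 3)))
            rej += meta.henze_zirkler(X).p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se + 1e-9

    def test_power_against_heavy_tails(self, rng):
        rej = 0
        for _ in range(20):
            X = pd.DataFrame(rng.standard_t(3, size=(500, 3)))
            rej += meta.henze_zirkler(X).p < 0.05
        assert rej / 20 > 0.5

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            meta.henze_zirkler(pd.DataFrame(rng.standard_normal((4, 5))))
        x = rng.standard_normal(50)
        with pytest.raises(ValueError, match="singular"):
            meta.henze_zirkler(pd.DataFrame({"a": x, "b": 2 * x}))


class TestSubsetSelection:
    def test_all_below_threshold_keeps_everything(self):
        sig = _sigma(np.eye(3) + 0.3 - 0.3 * np.eye(3), ["A", "B", "C"])
        kept, audit = meta.select_phenotype_subset(sig)
        assert kept == ["A", "B", "C"] and audit == []

    def test_high_pair_drops_lower_priority(self):
        """corr(A,B)=0.83 with B lower priority: B goes, {A,C} stay."""
        S = np.array([[1.0, 0.83, 0.2], [0.83, 1.0, 0.1], [0.2, 0.1, 1.0]])
        sig = _sigma(S, ["A", "B", "C"])
        kept, audit = meta.select_phenotype_subset(sig, priority=["A", "C", "B"])
        assert kept == ["A", "C"]
        assert audit[0]["dropped"] == "B" and audit[0]["corr"] == pytest.approx(0.83)

    def test_chain_resolved_by_single_drop(self):
        """A-B 0.75, B-C 0.75, A-C 0.1 with priority A>C>B: dropping B
        alone yields the maximal valid set {A, C} (brute-force optimum)."""
        S = np.array([[1.0, 0.75, 0.1], [0.75, 1.0, 0.75], [0.1, 0.75, 1.0]])
        sig = _sigma(S, ["A", "B", "C"])
        kept, audit = meta.select_phenotype_subset(sig, priority=["A", "C", "B"])
        assert kept == ["A", "C"] and len(audit) == 1

        # brute force: largest subset with all |corr| < 0.7
        import itertools

        best = max(
            (
                s
                for r in range(4)
                for s in itertools.combinations(range(3), r)
                if all(abs(S[i, j]) < 0.7 for i in s for j in s if i < j)
            ),
            key=len,
        )
        assert sorted(kept) == sorted("ABC"[i] for i in best)


class TestPreselect:
    def _stats(self, pmap, cohort="D"):
        rows = []
        for snp, ps in pmap.items():
            for i, p in enumerate(ps):
                rows.append(
                    {"snp_id": snp, "phenotype": f"t{i}", "cohort_id": cohort,
                     "model": "lmm", "beta": 0.0, "se": 1.0, "z": 0.0, "p": p,
                     "n_obs": 100, "n_subjects": 100, "flag": ""}
                )
        return pd.DataFrame(rows)

    def test_flat_p_not_selected(self):
        df = self._stats({"rs1": [0.5] * 16})
        out = meta.preselect(df, {"rs1": 0.3})
        expected_p = stats.chi2.sf(-2 * 16 * np.log(0.5), 32)
        assert out.loc[0, "p_combined"] == pytest.approx(expected_p, rel=1e-9)
        assert not out.loc[0, "candidate"]

    def test_one_tiny_p_dominates(self):
        ps = [1e-12] + [0.5] * 5
        df = self._stats({"rs1": ps})
        out = meta.preselect(df, {"rs1": 0.3})
        stat = -2 * np.sum(np.log(ps))
        assert bool(out.loc[0, "candidate"]) == bool(stats.chi2.sf(stat, 12) < 5e-8)
        assert out.loc[0, "candidate"]

    def test_low_maf_excluded_regardless_of_p(self):
        df = self._stats({"rs1": [1e-30] * 8})
        out = meta.preselect(df, {"rs1": 0.015})
        assert not out.loc[0, "candidate"]


class TestMetaAnalyze:
    def _inputs(self, cohorts):
        panels, sigmas, stats_map = {}, {}, {}
        for cid in cohorts:
            panels[cid] = [PhenotypeDef("Q"), PhenotypeDef("D", "time-to-event")]
            sigmas[cid] = _sigma(np.eye(2), ["Q", "D"], cid)
            stats_map[cid] = pd.DataFrame(
                [
                    {"snp_id": "rs1", "phenotype": "Q", "cohort_id": cid, "model": "lmm",
                     "beta": 1.0, "se": 1.0, "z": 1.0, "p": 0.3, "n_obs": 10,
                     "n_subjects": 10, "flag": ""},
                    {"snp_id": "rs1", "phenotype": "D", "cohort_id": cid, "model": "cox",
                     "beta": 2.0, "se": 1.0, "z": 2.0, "p": 0.05, "n_obs": 10,
                     "n_subjects": 10, "flag": ""},
                ]
            )
        return stats_map, sigmas, panels

    @pytest.mark.parametrize("n_cohorts,df", [(6, 12), (4, 8)])
    def test_df_counts_contributing_cohorts(self, n_cohorts, df):
        cids = [f"C{i}" for i in range(n_cohorts)]
        stats_map, sigmas, panels = self._inputs(cids)
        out = meta.meta_analyze(["rs1"], stats_map, sigmas, panels, groups=("both",))
        assert int(out.loc[0, "df"]) == df
        # manual chain: per-cohort omnibus p then Fisher
        pj = stats.chi2.sf(1.0 + 4.0, 2)
        stat = -2 * n_cohorts * np.log(pj)
        assert out.loc[0, "p_meta"] == pytest.approx(stats.chi2.sf(stat, df), rel=1e-9)

    def test_absent_snp_gives_empty_result(self):
        stats_map, sigmas, panels = self._inputs(["C0"])
        stats_map["C0"]["flag"] = "not-genotyped"
        out = meta.meta_analyze(["rs1"], stats_map, sigmas, panels, groups=("both",))
        assert np.isnan(out.loc[0, "p_meta"]) and int(out.loc[0, "df"]) == 0

    def test_groups_partition_phenotypes(self):
        stats_map, sigmas, panels = self._inputs(["C0", "C1"])
        out = meta.meta_analyze(["rs1"], stats_map, sigmas, panels)
        out = out.set_index("group")
        pq = stats.chi2.sf(1.0, 1)
        pd_ = stats.chi2.sf(4.0, 1)
        assert out.loc["endophenotypes", "p_meta"] == pytest.approx(
            stats.chi2.sf(-4 * np.log(pq), 4), rel=1e-9
        )
        assert out.loc["diseases", "p_meta"] == pytest.approx(
            stats.chi2.sf(-4 * np.log(pd_), 4), rel=1e-9
        )


class TestNullZ:
    def test_deterministic(self, null_cohort):
        z1 = meta.simulate_null_z(null_cohort, n_snps=60, seed=5)
        z2 = meta.simulate_null_z(null_cohort, n_snps=60, seed=5)
        pd.testing.assert_frame_equal(z1, z2)

    def test_too_few_snps_refused(self, null_cohort):
        with pytest.raises(ValueError):
            meta.simulate_null_z(null_cohort, n_snps=20, seed=1)

    def test_duplicated_phenotypes_give_unit_correlation(self):
        """Two traits generated with cross-trait correlation ~1 produce
        null z columns correlated at >= 0.99."""
        cohort = build_cohort(
            panel=[PhenotypeDef("Q1"), PhenotypeDef("Q2")],
            trait_corr=np.array([[1.0, 0.999], [0.999, 1.0]]),
            n_subjects=400, n_families=400, seed=61,
        )
        Z = meta.simulate_null_z(cohort, n_snps=300, seed=6)
        assert np.corrcoef(Z["Q1"], Z["Q2"])[0, 1] >= 0.99

    def test_independent_phenotypes_near_zero_correlation(self):
        """With independent traits the null z correlation is O(1/sqrt(n))
        conditional on the phenotype data, so a reasonably large cohort
        keeps every off-diagonal inside +-0.1."""
        cohort = build_cohort(
            panel=[PhenotypeDef("Q1"), PhenotypeDef("Q2"), PhenotypeDef("Q3")],
            n_subjects=2000, n_families=2000, n_visits=1, seed=62,
        )
        Z = meta.simulate_null_z(cohort, n_snps=500, seed=7)
        C = np.corrcoef(Z.to_numpy(), rowvar=False)
        assert np.abs(C[~np.eye(3, dtype=bool)]).max() < 0.1
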