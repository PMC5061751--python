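"""Vectorised per-SNP association scans against fixed phenotype data.

For simulation-scale work (estimating the null z-score correlation from
1000 simulated SNPs, type-I-error and power studies) refitting a mixed
model or Cox model per SNP is wasteful: the phenotype data never change.
Each phenotype's null model (covariates and variance components only) is
fitted once; per-SNP statistics then come from

* quantitative traits: exact generalized-least-squares Wald statistics
  after whitening by the estimated random-effect covariance (the standard
  two-stage "population parameters previously determined" device),
* binary traits: Rao efficient score statistics from the null GLM,
* time-to-event traits: efficient score statistics from the null Cox
  model (see :mod:`pleioscan._fastcox`).

Exact per-SNP refits remain available in :mod:`pleioscan.assoc`; the two
routes are compared in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import solve_triangular

from . import _fastcox
from .datatypes import BINARY, EVENT, QUANTITATIVE, CohortData

__all__ = ["FastCohortScanner"]


def _covariate_matrix(df: pd.DataFrame, covariates, age_col="age") -> np.ndarray:
    cols = [np.ones(len(df))]
    if "age" in covariates and age_col is not None:
        cols.append(df[age_col].to_numpy(dtype=float))
    if "sex" in covariates:
        cols.append(df["sex"].to_numpy(dtype=float))
    if "center" in covariates and df["center"].nunique() > 1:
        dummies = pd.get_dummies(df["center"], drop_first=True, dtype=float)
        cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    return np.column_stack(cols)


def _null_formula(covariates, data: pd.DataFrame) -> str:
    terms = []
    if "age" in covariates:
        terms.append("age")
    if "sex" in covariates:
        terms.append("sex")
    if "center" in covariates and data["center"].nunique() > 1:
        terms.append("C(center)")
    return "value ~ " + (" + ".join(terms) if terms else "1")


def fit_mixedlm(md, maxiter: int = 200):
    """REML fit with optimizer fallbacks (lbfgs occasionally hits a
    singular region on near-degenerate variance surfaces)."""
    import warnings as _warnings

    last = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                return md.fit(reml=True, method=method, maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise last


def estimate_variance_components(
    data: pd.DataFrame, covariates, repeated: bool | None = None, clustered: bool | None = None
) -> tuple[float, float, float]:
    """REML (family, subject, residual) variances for one quantitative trait.

    The random structure adapts to the design: family and subject
    intercepts when families have multiple members and subjects multiple
    visits; a single level when only one source of clustering exists;
    plain OLS residual variance otherwise.
    """
    fam = pd.factorize(data["family_id"])[0]
    sub = pd.factorize(data["subject_id"])[0]
    if repeated is None:
        repeated = len(data) > sub.max() + 1
    if clustered is None:
        clustered = pd.Series(sub).groupby(fam).nunique().max() > 1
    formula = _null_formula(covariates, data)
    if clustered and repeated:
        md = sm.MixedLM.from_formula(
            formula,
            groups="family_id",
            re_formula="1",
            vc_formula={"subject": "0 + C(subject_id)"},
            data=data,
        )
        res = fit_mixedlm(md)
        return (
            max(float(res.cov_re.iloc[0, 0]), 0.0),
            max(float(res.vcomp[0]), 0.0) if len(res.vcomp) else 0.0,
            max(float(res.scale), 1e-12),
        )
    if clustered or repeated:
        groups = "family_id" if clustered else "subject_id"
        md = sm.MixedLM.from_formula(formula, groups=groups, re_formula="1", data=data)
        res = fit_mixedlm(md)
        var = max(float(res.cov_re.iloc[0, 0]), 0.0)
        fam_v, sub_v = (var, 0.0) if clustered else (0.0, var)
        return fam_v, sub_v, max(float(res.scale), 1e-12)
    res = sm.OLS.from_formula(formula, data=data).fit()
    return 0.0, 0.0, max(float(res.scale), 1e-12)


class _QuantNull:
    """Null LMM for one quantitative trait, ready to whiten new columns."""

    def __init__(self, data: pd.DataFrame, covariates):
        self.data = data
        X = _covariate_matrix(data, covariates)
        fam = pd.factorize(data["family_id"])[0]
        sub = pd.factorize(data["subject_id"])[0]
        y = data["value"].to_numpy(dtype=float)
        n_sub = sub.max() + 1
        repeated = len(data) > n_sub
        clustered = pd.Series(sub).groupby(fam).nunique().max() > 1

        sigma_f, sigma_s, sigma_e = estimate_variance_components(
            data, covariates, repeated=repeated, clustered=clustered
        )

        self.variances = (max(sigma_f, 0.0), max(sigma_s, 0.0), max(sigma_e, 1e-12))
        # per-family Cholesky factors of V = sf*J + ss*(subject blocks) + se*I
        self._blocks = []
        order = np.argsort(fam, kind="stable")
        self.order = order
        fam_o, sub_o = fam[order], sub[order]
        sf, ss, se = self.variances
        start = 0
        for g in range(fam_o.max() + 1):
            size = int((fam_o == g).sum())
            idx = slice(start, start + size)
            same_sub = (sub_o[idx][:, None] == sub_o[idx][None, :]).astype(float)
            V = sf + ss * same_sub + se * np.eye(size)
            self._blocks.append((idx, np.linalg.cholesky(V)))
            start += size

        yw = self.whiten(y)
        Xw = self.whiten(X)
        self._Q, _ = np.linalg.qr(Xw)
        self.y_resid = yw - self._Q @ (self._Q.T @ yw)

    def whiten(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        out = np.empty_like(a[self.order] if a.ndim == 1 else a[self.order, :])
        src = a[self.order]
        for idx, L in self._blocks:
            out[idx] = solve_triangular(L, src[idx], lower=True, check_finite=False)
        return out

    def scan(self, G_obs: np.ndarray):
        Gw = self.whiten(G_obs)
        Gr = Gw - self._Q @ (self._Q.T @ Gw)
        denom = np.einsum("ij,ij->j", Gr, Gr)
        denom = np.maximum(denom, 1e-300)
        beta = (Gr.T @ self.y_resid) / denom
        se = 1.0 / np.sqrt(denom)
        return beta, se, beta / se


class _BinaryNull:
    def __init__(self, data: pd.DataFrame, covariates):
        self.data = data
        X = _covariate_matrix(data, covariates)
        y = data["value"].to_numpy(dtype=float)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        mu = res.fittedvalues
        self.resid = y - mu
        self.w = mu * (1 - mu)
        self.X = X
        self.XtWX_inv = np.linalg.inv(X.T @ (self.w[:, None] * X))

    def scan(self, G_obs: np.ndarray):
        U = G_obs.T @ self.resid
        GtWX = G_obs.T @ (self.w[:, None] * self.X)
        V = np.einsum("ij,ij->j", G_obs, self.w[:, None] * G_obs)
        V = V - np.einsum("mk,kl,ml->m", GtWX, self.XtWX_inv, GtWX)
        V = np.maximum(V, 1e-300)
        z = U / np.sqrt(V)
        return U / V, 1.0 / np.sqrt(V), z


class _EventNull:
    def __init__(self, data: pd.DataFrame, covariates):
        self.data = data
        X = _covariate_matrix(data, covariates, age_col=None)[:, 1:]  # no intercept in Cox
        self.entry = data["entry_age"].to_numpy(dtype=float)
        self.exit = data["exit_age"].to_numpy(dtype=float)
        self.event = data["event"].to_numpy(dtype=int)
        if X.shape[1]:
            fit = _fastcox.cox_newton(X, self.entry, self.exit, self.event)
            self.offset = X @ fit.beta
            self.X = X
            self.info = np.linalg.inv(fit.cov)
        else:
            self.offset = np.zeros(len(data))
            self.X = X
            self.info = None

    def scan(self, G_obs: np.ndarray):
        return _fastcox.cox_score_scan(
            G_obs,
            self.entry,
            self.exit,
            self.event,
            offset=self.offset,
            X_null=self.X if self.X.shape[1] else None,
            info_null=self.info,
        )


class FastCohortScanner:
    """Scan many SNPs against one cohort's fixed phenotype/event data.

    Parameters
    ----------
    cohort : CohortData
    covariates : iterable of {'age', 'sex', 'center'}
    phenotypes : optional subset of the cohort panel to scan.
    """

    def __init__(self, cohort: CohortData, covariates=("age", "sex", "center"), phenotypes=None):
        self.cohort = cohort
        self.covariates = tuple(covariates)
        panel = cohort.spec.phenotype_panel
        if phenotypes is not None:
            panel = [p for p in panel if p.name in set(phenotypes)]
        self.panel = panel
        self.subject_index = cohort.genotypes.subjects.index
        self._nulls: dict[str, object] = {}
        self._row_maps: dict[str, np.ndarray] = {}

    @property
    def phenotype_names(self) -> list[str]:
        return [p.name for p in self.panel]

    def _null_for(self, pdef):
        if pdef.name in self._nulls:
            return self._nulls[pdef.name]
        subj = self.cohort.genotypes.subjects
        if pdef.kind in (QUANTITATIVE, BINARY):
            rows = self.cohort.phenotypes.query("phenotype == @pdef.name").reset_index(drop=True)
            if rows.empty:
                raise ValueError(f"phenotype {pdef.name!r} has no data in this cohort")
            data = rows.merge(
                subj[["sex", "center"]], left_on="subject_id", right_index=True, how="left"
            )
            null = (
                _QuantNull(data, self.covariates)
                if pdef.kind == QUANTITATIVE
                else _BinaryNull(data, self.covariates)
            )
        else:
            rows = self.cohort.events.query("disease == @pdef.name").reset_index(drop=True)
            if rows.empty:
                raise ValueError(f"disease {pdef.name!r} has no data in this cohort")
            data = rows.merge(
                subj[["sex", "center"]], left_on="subject_id", right_index=True, how="left"
            )
            null = _EventNull(data, self.covariates)
        self._nulls[pdef.name] = null
        pos = pd.Series(np.arange(len(self.subject_index)), index=self.subject_index)
        self._row_maps[pdef.name] = pos.loc[null.data["subject_id"]].to_numpy()
        return null

    def zscan(self, dosages: pd.DataFrame) -> dict[str, pd.DataFrame]:
        """Per-SNP statistics for every phenotype.

        ``dosages``: subjects x SNPs frame aligned (reindexed) to the
        cohort's subjects; missing dosages are mean-imputed, which keeps
        the score statistics well-defined.

        Returns ``{"beta": ..., "se": ..., "z": ...}`` frames indexed by
        SNP with one column per phenotype.
        """
        D = dosages.reindex(self.subject_index).to_numpy(dtype=float)
        col_mean = np.nanmean(D, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        D = np.where(np.isnan(D), col_mean[None, :], D)

        betas, ses, zs = {}, {}, {}
        for pdef in self.panel:
            null = self._null_for(pdef)
            G_obs = D[self._row_maps[pdef.name]]
            b, s, z = null.scan(G_obs)
            betas[pdef.name], ses[pdef.name], zs[pdef.name] = b, s, z
        idx = pd.Index(dosages.columns, name="snp_id")
        return {
            "beta": pd.DataFrame(betas, index=idx),
            "se": pd.DataFrame(ses, index=idx),
            "z": pd.DataFrame(zs, index=idx),
        }
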