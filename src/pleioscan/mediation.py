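"""Natural direct and indirect effects of a SNP on a disease hazard.

Implements the weighted marginal-structural-model (MSM) device for
causal mediation with a survival outcome: each subject's record is
duplicated once per auxiliary exposure level a*, weighted by the
Gaussian mediator-density ratio

    w = f(M | A = a*, C) / f(M | A = a_obs, C),

and a weighted Cox model with linear predictor gamma1*A + gamma2*A*
(+ covariates) is fitted to the expanded data.  gamma1 estimates the
natural direct effect (NDE) and gamma2 the natural indirect effect
(NIE), both on the log-hazard-ratio scale.  Confidence intervals come
from a family-cluster non-parametric bootstrap (500 replicates by
default).

Only the *baseline* mediator measurement is accepted, which enforces the
temporal ordering mediator-before-onset and rules out reverse causality.
The no-unmeasured-confounding assumption between mediator and disease is
asserted, not testable.  The proportion mediated is defined as
NIE / (NDE + NIE) on the log-HR scale and reported only when the total
effect exceeds a stability floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps

from . import _fastcox
from .datatypes import CohortData
from .synth import substream

__all__ = [
    "MediationSpec",
    "MediatorModel",
    "MediationResult",
    "assemble_mediation_data",
    "fit_mediator_model",
    "expand_and_weight",
    "fit_msm",
    "bootstrap_ci",
    "mediate",
]

TOTAL_EFFECT_FLOOR = 0.01


@dataclass
class MediationSpec:
    snp_id: str
    mediator: str
    disease: str
    covariates: tuple[str, ...] = ("age", "sex")
    exposure_levels: tuple[int, ...] = (0, 1, 2)
    truncate_weights: tuple[float, float] | None = (0.01, 0.99)


@dataclass
class MediatorModel:
    """Fitted Gaussian conditional density f(M | A, C)."""

    params: pd.Series
    resid_sd: float
    design_cols: list[str]
    n_dropped: int = 0

    def mean(self, df: pd.DataFrame, exposure: np.ndarray) -> np.ndarray:
        mu = np.full(len(df), self.params["Intercept"])
        mu = mu + self.params["dosage"] * exposure
        for c in self.design_cols:
            mu = mu + self.params[c] * df[c].to_numpy(dtype=float)
        return mu

    def density(self, m: np.ndarray, df: pd.DataFrame, exposure: np.ndarray) -> np.ndarray:
        return sps.norm.pdf(m, loc=self.mean(df, exposure), scale=self.resid_sd)


@dataclass
class MediationResult:
    spec: MediationSpec
    nde: float
    nie: float
    total: float
    proportion_mediated: float | None
    nde_ci: tuple[float, float]
    nie_ci: tuple[float, float]
    total_ci: tuple[float, float]
    n_boot: int
    n_boot_failed: int
    flag: str = ""


def assemble_mediation_data(cohort: CohortData, spec: MediationSpec) -> pd.DataFrame:
    """One row per subject: dosage, baseline mediator, event record, covariates.

    The mediator value is the subject's earliest visit measurement; the
    baseline age covariate is the age at that visit.  Subjects whose
    disease onset precedes the mediator measurement are excluded (the
    mediator must be measured before onset).
    """
    med = cohort.phenotypes[cohort.phenotypes["phenotype"] == spec.mediator]
    if med.empty:
        raise ValueError(f"mediator {spec.mediator!r} not measured in this cohort")
    baseline = (
        med.sort_values("age", kind="mergesort").groupby("subject_id").first()[["age", "value"]]
    )
    ev = cohort.events[cohort.events["disease"] == spec.disease].set_index("subject_id")
    if ev.empty:
        raise ValueError(f"disease {spec.disease!r} has no event records in this cohort")

    df = ev.join(baseline, how="inner").rename(columns={"value": "mediator", "age": "baseline_age"})
    df = df.join(cohort.genotypes.subjects[["sex", "center"]])
    df["dosage"] = cohort.genotypes.dosages[spec.snp_id].reindex(df.index)
    df = df.reset_index()
    df = df[df["exit_age"] > df["baseline_age"]]
    n0 = len(df)
    df = df.dropna(subset=["mediator", "dosage"]).reset_index(drop=True)
    df.attrs["n_dropped"] = n0 - len(df)
    return df


def fit_mediator_model(data: pd.DataFrame, spec: MediationSpec) -> MediatorModel:
    """Linear regression of the baseline mediator on exposure + covariates."""
    cols = []
    if "age" in spec.covariates:
        cols.append("baseline_age")
    if "sex" in spec.covariates:
        cols.append("sex")
    if "center" in spec.covariates and data["center"].nunique() > 1:
        cols.append("center")
    X = sm.add_constant(
        data[["dosage"] + cols].to_numpy(dtype=float), has_constant="add"
    )
    y = data["mediator"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.scale))
    if resid_sd <= 0 or not np.isfinite(resid_sd):
        raise ValueError("mediator model has zero residual variance")
    params = pd.Series(res.params, index=["Intercept", "dosage"] + cols)
    return MediatorModel(params, resid_sd, cols, data.attrs.get("n_dropped", 0))


def expand_and_weight(
    data: pd.DataFrame, model: MediatorModel, spec: MediationSpec
) -> pd.DataFrame:
    """Duplicate each row per auxiliary exposure level and attach weights.

    Rows with a* equal to the observed exposure get weight exactly 1
    (density ratio of identical densities).  Non-finite weights are
    dropped with a warning; extreme weights are truncated at the
    configured percentiles (on by default, recorded in ``attrs``).
    """
    frames = []
    a_obs = data["dosage"].to_numpy(dtype=float)
    m = data["mediator"].to_numpy(dtype=float)
    dens_obs = model.density(m, data, a_obs)
    for a_star in spec.exposure_levels:
        block = data.copy()
        block["a_star"] = float(a_star)
        same = a_obs == a_star
        w = np.ones(len(block))
        other = ~same
        if other.any():
            dens_star = model.density(
                m[other], data.iloc[other], np.full(other.sum(), float(a_star))
            )
            w[other] = dens_star / dens_obs[other]
        block["msm_weight"] = w
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)

    finite = np.isfinite(out["msm_weight"]) & (out["msm_weight"] > 0)
    n_bad = int((~finite).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} expanded rows with non-finite weights")
        out = out[finite].reset_index(drop=True)
    if spec.truncate_weights is not None:
        lo, hi = np.quantile(out["msm_weight"], spec.truncate_weights)
        out["msm_weight"] = out["msm_weight"].clip(lo, hi)
        out.attrs["weight_truncation"] = (float(lo), float(hi))
    out.attrs["n_dropped_weights"] = n_bad
    return out


def _msm_design(expanded: pd.DataFrame, spec: MediationSpec):
    cols = [expanded["dosage"].to_numpy(dtype=float), expanded["a_star"].to_numpy(dtype=float)]
    names = ["dosage", "a_star"]
    if "age" in spec.covariates:
        cols.append(expanded["baseline_age"].to_numpy(dtype=float))
        names.append("baseline_age")
    if "sex" in spec.covariates:
        cols.append(expanded["sex"].to_numpy(dtype=float))
        names.append("sex")
    if "center" in spec.covariates and expanded["center"].nunique() > 1:
        for lv in sorted(expanded["center"].unique())[1:]:
            cols.append((expanded["center"] == lv).to_numpy(dtype=float))
            names.append(f"center_{lv}")
    return np.column_stack(cols), names


def fit_msm(
    expanded: pd.DataFrame, spec: MediationSpec, engine: str = "fast"
) -> tuple[float, float]:
    """Weighted Cox fit on the expanded data; returns (NDE, NIE).

    The outcome model uses age as the time scale with delayed entry at
    the baseline mediator measurement.  engine='fast' uses the in-house
    Newton solver (bootstrap workhorse); engine='lifelines' the
    reference implementation with robust variance.
    """
    if (
        expanded["a_star"].nunique() < 2
        or (expanded["a_star"] == expanded["dosage"]).all()
    ):
        raise ValueError(
            "auxiliary exposure must vary independently of the observed "
            "exposure; expansion is degenerate"
        )
    X, names = _msm_design(expanded, spec)
    entry = expanded["baseline_age"].to_numpy(dtype=float)
    stop = expanded["exit_age"].to_numpy(dtype=float)
    event = expanded["event"].to_numpy(dtype=int)
    w = expanded["msm_weight"].to_numpy(dtype=float)

    if engine == "fast":
        fit = _fastcox.cox_newton(X, entry, stop, event, weights=w)
        if not fit.converged:
            raise RuntimeError("weighted Cox did not converge")
        return float(fit.beta[0]), float(fit.beta[1])
    if engine != "lifelines":
        raise ValueError("engine must be 'fast' or 'lifelines'")
    df = pd.DataFrame(X, columns=names)
    df["_entry"], df["_stop"], df["event"], df["_w"] = entry, stop, event, w
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="_stop",
            entry_col="_entry",
            event_col="event",
            weights_col="_w",
            robust=True,
        )
    return float(cph.params_["dosage"]), float(cph.params_["a_star"])


def _point_estimates(data: pd.DataFrame, spec: MediationSpec) -> tuple[float, float]:
    model = fit_mediator_model(data, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expanded = expand_and_weight(data, model, spec)
    return fit_msm(expanded, spec, engine="fast")


class _MediationArrays:
    """Array view of the mediation pipeline for the bootstrap loop.

    Runs mediator OLS -> density-ratio weights -> weighted Cox entirely
    in numpy; algebraically identical to the DataFrame pipeline (the
    weight for a* = a_obs reduces to exp(0) = 1 exactly), which the test
    suite asserts.
    """

    def __init__(self, data: pd.DataFrame, spec: MediationSpec):
        self.A = data["dosage"].to_numpy(dtype=float)
        self.M = data["mediator"].to_numpy(dtype=float)
        cols = []
        if "age" in spec.covariates:
            cols.append(data["baseline_age"].to_numpy(dtype=float))
        if "sex" in spec.covariates:
            cols.append(data["sex"].to_numpy(dtype=float))
        if "center" in spec.covariates and data["center"].nunique() > 1:
            for lv in sorted(data["center"].unique())[1:]:
                cols.append((data["center"] == lv).to_numpy(dtype=float))
        self.C = np.column_stack(cols) if cols else np.empty((len(data), 0))
        self.entry = data["baseline_age"].to_numpy(dtype=float)
        self.stop = data["exit_age"].to_numpy(dtype=float)
        self.event = data["event"].to_numpy(dtype=int)
        self.levels = np.asarray(spec.exposure_levels, dtype=float)
        self.trunc = spec.truncate_weights

    def estimates(self, idx: np.ndarray | None = None) -> tuple[float, float]:
        sl = slice(None) if idx is None else idx
        A, M, C = self.A[sl], self.M[sl], self.C[sl]
        entry, stop, event = self.entry[sl], self.stop[sl], self.event[sl]
        n = len(A)
        X = np.column_stack([np.ones(n), A, C])
        coef, *_ = np.linalg.lstsq(X, M, rcond=None)
        mu_obs = X @ coef
        resid = M - mu_obs
        sd2 = float(resid @ resid) / (n - X.shape[1])
        if sd2 <= 0:
            raise ValueError("mediator model has zero residual variance")

        L = len(self.levels)
        w = np.empty((L, n))
        for k, a in enumerate(self.levels):
            mu_star = mu_obs + coef[1] * (a - A)
            w[k] = np.exp(-((M - mu_star) ** 2 - (M - mu_obs) ** 2) / (2 * sd2))
        wflat = w.ravel()
        finite = np.isfinite(wflat) & (wflat > 0)
        if self.trunc is not None:
            lo, hi = np.quantile(wflat[finite], self.trunc)
            wflat = np.clip(wflat, lo, hi)
        Xc = np.column_stack(
            [np.tile(A, L), np.repeat(self.levels, n), np.tile(C, (L, 1))]
        )
        keep = finite
        fit = _fastcox.cox_newton(
            Xc[keep],
            np.tile(entry, L)[keep],
            np.tile(stop, L)[keep],
            np.tile(event, L)[keep],
            weights=wflat[keep],
        )
        return float(fit.beta[0]), float(fit.beta[1])


def bootstrap_ci(
    data: pd.DataFrame,
    spec: MediationSpec,
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> MediationResult:
    """Family-cluster bootstrap of the full mediation pipeline.

    Families are resampled with replacement; the mediator model,
    expansion and MSM are rerun per replicate.  Percentile intervals are
    reported; if more than 10% of replicates fail the result is flagged
    unreliable.  With singleton families this is the ordinary
    non-parametric bootstrap.
    """
    arrays = _MediationArrays(data, spec)
    nde, nie = arrays.estimates()

    rng = substream(seed, "mediation", spec.snp_id, spec.disease)
    fams = data["family_id"].unique()
    groups = {f: np.flatnonzero(data["family_id"].to_numpy() == f) for f in fams}
    est = np.full((n_boot, 2), np.nan)
    failed = 0
    for b in range(n_boot):
        pick = rng.choice(fams, size=len(fams), replace=True)
        idx = np.concatenate([groups[f] for f in pick])
        try:
            est[b] = arrays.estimates(idx)
        except Exception:
            failed += 1
    ok = est[~np.isnan(est).any(axis=1)]
    a = (1 - ci) / 2

    flag = ""
    if failed > 0.1 * n_boot:
        flag = "unreliable: >10% bootstrap failures"
    total = nde + nie
    prop = float(nie / total) if abs(total) > TOTAL_EFFECT_FLOOR else None
    tot_boot = ok.sum(axis=1)
    return MediationResult(
        spec,
        nde,
        nie,
        total,
        prop,
        (float(np.quantile(ok[:, 0], a)), float(np.quantile(ok[:, 0], 1 - a))),
        (float(np.quantile(ok[:, 1], a)), float(np.quantile(ok[:, 1], 1 - a))),
        (float(np.quantile(tot_boot, a)), float(np.quantile(tot_boot, 1 - a))),
        n_boot,
        failed,
        flag,
    )


def mediate(
    cohort: CohortData,
    snp_id: str,
    mediator: str,
    disease: str,
    covariates=("age", "sex"),
    n_boot: int = 500,
    seed: int = 0,
) -> MediationResult:
    """End-to-end mediation analysis for one (SNP, mediator, disease)."""
    spec = MediationSpec(snp_id, mediator, disease, tuple(covariates))
    data = assemble_mediation_data(cohort, spec)
    return bootstrap_ci(data, spec, n_boot=n_boot, seed=seed)
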