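"""Proportional-hazards diagnostics and age-dependent effect estimation.

A violation of the PH assumption for a SNP on an age-at-onset disease is
evidence of an age-dependent genetic effect.  The diagnostic is the
Grambsch-Therneau score test: the correlation between scaled Schoenfeld
residuals and a transform of event time (Kaplan-Meier transform by
default, as in the classical cox.zph diagnostic), with violation
declared at p < 0.05.  Flagged SNPs are then characterized by
age-window-stratified Cox fits (risk sets truncated to each window) and
a piecewise-constant cumulative effect curve — an explicitly simplified
substitute for resampling-based cumulative-coefficient estimators, and
labeled as such in its output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from . import _fastcox
from .assoc import CoxFit, fit_cox
from .datatypes import GenotypeMatrix
from .synth import substream

__all__ = [
    "PHTestResult",
    "StratifiedHR",
    "ph_test",
    "ph_test_quick",
    "stratified_cox",
    "piecewise_effect_curve",
    "km_by_genotype",
]

COUNTING_PROCESS_START = 40.0


@dataclass
class PHTestResult:
    snp_id: str
    disease: str
    cohort_id: str
    rho: float
    statistic: float
    p: float
    transform: str
    violation: bool
    n_events: int


@dataclass
class StratifiedHR:
    """Per-age-window hazard ratios for one SNP and disease.

    ``table`` columns: lo, hi, hr, log_hr, se, p, n_events, flag.
    """

    snp_id: str
    disease: str
    table: pd.DataFrame
    start_age: float = COUNTING_PROCESS_START


def ph_test(fit: CoxFit, transform: str = "km", covariate: str = "dosage") -> PHTestResult:
    """Grambsch-Therneau test of proportional hazards for the SNP term.

    Scaled Schoenfeld residuals are regressed on a transform g of event
    time; the 1-df score statistic for covariate j is

        [sum_e (g_e - gbar) r*_ej]^2 / ((V^-1)_jj * sum_e (g_e - gbar)^2)

    with r* = d V^{-1} s + beta_hat the scaled residuals, s the raw
    Schoenfeld residuals and V the observed partial-likelihood
    information.  Residuals are computed in-house because the risk sets
    carry delayed entry (age time scale).  The reported rho is the
    Pearson correlation between g(t) and the scaled residuals; violation
    is declared at p < 0.05.  Requires >= 10 events.
    """
    if fit.n_events < 10:
        raise ValueError(
            f"only {fit.n_events} events; at least 10 are required for the PH test"
        )
    beta = fit.fitter.params_.to_numpy(dtype=float)
    entry = fit.data["_entry"].to_numpy(dtype=float)
    stop = fit.data["_stop"].to_numpy(dtype=float)
    event = fit.data["event"].to_numpy(dtype=int)
    rho, stat, p = _gt_score_test(
        fit.design, entry, stop, event, beta, fit.columns.index(covariate), transform
    )
    return PHTestResult(
        fit.snp_id,
        fit.disease,
        str(fit.data["cohort_id"].iloc[0]) if "cohort_id" in fit.data else "",
        rho,
        stat,
        p,
        transform,
        bool(p < 0.05),
        fit.n_events,
    )


def _gt_score_test(X, entry, stop, event, beta, j, transform):
    times, resid, info = _fastcox.schoenfeld_residuals(X, entry, stop, event, beta)
    d = len(times)
    vinv = np.linalg.inv(info)
    scaled = d * resid @ vinv.T + np.asarray(beta)[None, :]
    g = _transform_values(times, entry, stop, event, transform)
    gc = g - g.mean()
    stat = float(gc @ scaled[:, j]) ** 2 / float(d * vinv[j, j] * (gc @ gc))
    p = float(sps.chi2.sf(stat, df=1))
    rho = float(np.corrcoef(g, scaled[:, j])[0, 1])
    return rho, stat, p


def ph_test_quick(
    events: pd.DataFrame,
    geno: GenotypeMatrix,
    disease: str,
    snp_id: str,
    covariates=("sex",),
    transform: str = "km",
) -> PHTestResult:
    """Grambsch-Therneau test from a direct partial-likelihood fit.

    Same diagnostic as :func:`ph_test` but fits the Cox model with the
    in-house Newton solver (no robust variance, which the score test
    does not use) — the right tool inside simulation loops.
    """
    ev = events[events["disease"] == disease].reset_index(drop=True)
    dose = geno.dosages[snp_id].reindex(ev["subject_id"]).to_numpy(dtype=float)
    keep = ~np.isnan(dose)
    ev, dose = ev[keep].reset_index(drop=True), dose[keep]
    cols = [dose]
    names = ["dosage"]
    subj = geno.subjects
    if "sex" in covariates:
        cols.append(subj["sex"].reindex(ev["subject_id"]).to_numpy(dtype=float))
        names.append("sex")
    X = np.column_stack(cols)
    entry = ev["entry_age"].to_numpy(dtype=float)
    stop = ev["exit_age"].to_numpy(dtype=float)
    event = ev["event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < 10:
        raise ValueError(f"only {n_events} events; at least 10 are required for the PH test")
    fit = _fastcox.cox_newton(X, entry, stop, event)
    rho, stat, p = _gt_score_test(X, entry, stop, event, fit.beta, 0, transform)
    return PHTestResult(
        snp_id, disease, str(ev["cohort_id"].iloc[0]) if len(ev) else "",
        rho, stat, p, transform, bool(p < 0.05), n_events,
    )


def _transform_values(times, entry, stop, event, transform: str) -> np.ndarray:
    if transform == "identity":
        return times
    if transform == "log":
        return np.log(times)
    if transform == "rank":
        return np.argsort(np.argsort(times)).astype(float)
    if transform == "km":
        km = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(stop, event, entry=entry)
        surv = km.survival_function_at_times(times).to_numpy()
        return 1.0 - surv
    raise ValueError(f"unknown time transform {transform!r}")


def _window_slice(events: pd.DataFrame, lo: float, hi: float) -> pd.DataFrame:
    """Truncate risk sets to [lo, hi): delayed entry at lo, censor at hi."""
    df = events.copy()
    df["entry_age"] = np.maximum(df["entry_age"], lo)
    in_window = df["exit_age"] > df["entry_age"]
    df = df[in_window].copy()
    past_hi = df["exit_age"] >= hi
    df.loc[past_hi, "exit_age"] = hi - 1e-9
    df.loc[past_hi, "event"] = 0
    return df[df["exit_age"] > df["entry_age"]]


def stratified_cox(
    events: pd.DataFrame,
    geno: GenotypeMatrix,
    disease: str,
    snp_id: str,
    windows: list[tuple[float, float]],
    covariates=("sex", "center"),
) -> StratifiedHR:
    """Cox fit of the SNP effect within each age window.

    Windows are half-open [lo, hi); subjects enter a window's risk set at
    max(entry, lo), leave at min(exit, hi), and count as events only if
    the event age falls inside.  Each window is fitted marginally with
    family-robust variance.  A window with no events yields a flagged
    empty row.
    """
    rows = []
    for lo, hi in windows:
        if hi <= lo:
            raise ValueError(f"invalid window [{lo}, {hi})")
        sub = _window_slice(events[events["disease"] == disease], lo, hi)
        n_events = int(sub["event"].sum()) if len(sub) else 0
        if n_events == 0:
            rows.append(
                {
                    "lo": lo, "hi": hi, "hr": np.nan, "log_hr": np.nan,
                    "se": np.nan, "p": np.nan, "n_events": 0, "flag": "no-events",
                }
            )
            continue
        stat, _ = fit_cox(sub, geno, disease, snp_id, covariates=covariates, timescale="age")
        rows.append(
            {
                "lo": lo, "hi": hi,
                "hr": float(np.exp(stat.beta)) if stat.flag == "" else np.nan,
                "log_hr": stat.beta, "se": stat.se, "p": stat.p,
                "n_events": n_events, "flag": stat.flag,
            }
        )
    return StratifiedHR(snp_id, disease, pd.DataFrame(rows))


def _window_loghr_fast(df: pd.DataFrame, dosage: np.ndarray) -> float:
    """Point estimate of the SNP log-HR in a prepared window slice."""
    try:
        fit = _fastcox.cox_newton(
            dosage[:, None],
            df["entry_age"].to_numpy(dtype=float),
            df["exit_age"].to_numpy(dtype=float),
            df["event"].to_numpy(dtype=int),
        )
    except (ValueError, np.linalg.LinAlgError):
        return np.nan
    return float(fit.beta[0])


def piecewise_effect_curve(
    events: pd.DataFrame,
    geno: GenotypeMatrix,
    disease: str,
    snp_id: str,
    bin_width: float = 5.0,
    start_age: float = COUNTING_PROCESS_START,
    end_age: float | None = None,
    n_boot: int = 100,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Cumulative age-dependent effect: sum of (bin log-HR x bin width).

    The counting process starts at ``start_age`` (default 40).  Pointwise
    confidence bands come from a family-cluster bootstrap.  Bins with no
    events contribute a flat, flagged segment.  This is a deliberately
    simplified piecewise-constant estimator of the cumulative regression
    coefficient, not a resampling-based functional estimator.

    Returns a frame with columns ``age`` (bin upper edge), ``cum_loghr``,
    ``lo``, ``hi``, ``n_events``, ``flag``.
    """
    ev = events[events["disease"] == disease].reset_index(drop=True)
    if end_age is None:
        end_age = float(np.ceil(ev["exit_age"].max()))
    edges = np.arange(start_age, end_age + bin_width, bin_width)
    edges[-1] = max(edges[-1], end_age)

    dose = geno.dosages[snp_id].reindex(ev["subject_id"]).to_numpy(dtype=float)
    keep = ~np.isnan(dose)
    ev, dose = ev[keep].reset_index(drop=True), dose[keep]

    def curve_for(df: pd.DataFrame, d: np.ndarray):
        increments, counts = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sl = _window_slice(df, lo, hi)
            n_ev = int(sl["event"].sum()) if len(sl) else 0
            counts.append(n_ev)
            if n_ev == 0:
                increments.append(0.0)
                continue
            d_sl = pd.Series(d, index=df.index).loc[sl.index].to_numpy()
            b = _window_loghr_fast(sl, d_sl)
            increments.append(0.0 if not np.isfinite(b) else b * (hi - lo))
        return np.cumsum(increments), counts

    cum, counts = curve_for(ev, dose)

    rng = substream(seed, "piecewise", disease, snp_id)
    fam_ids = ev["family_id"].unique()
    boots = np.empty((n_boot, len(cum)))
    fam_groups = {f: np.flatnonzero(ev["family_id"].to_numpy() == f) for f in fam_ids}
    for b in range(n_boot):
        pick = rng.choice(fam_ids, size=len(fam_ids), replace=True)
        idx = np.concatenate([fam_groups[f] for f in pick])
        boots[b], _ = curve_for(ev.iloc[idx].reset_index(drop=True), dose[idx])
    a = (1 - ci) / 2
    lo_band = np.quantile(boots, a, axis=0)
    hi_band = np.quantile(boots, 1 - a, axis=0)

    return pd.DataFrame(
        {
            "age": edges[1:],
            "cum_loghr": cum,
            "lo": lo_band,
            "hi": hi_band,
            "n_events": counts,
            "flag": ["no-events" if c == 0 else "" for c in counts],
        }
    )


def km_by_genotype(
    events: pd.DataFrame, geno: GenotypeMatrix, disease: str, snp_id: str
) -> dict[int, pd.DataFrame]:
    """Left-truncation-aware Kaplan-Meier curves per dosage group.

    Returns, per dosage in {0, 1, 2} present in the data, a frame with
    the product-limit survival estimate and Greenwood standard error.
    Groups without subjects (or with no events) are skipped or returned
    as the constant-1 curve respectively.
    """
    ev = events[events["disease"] == disease].reset_index(drop=True)
    dose = geno.dosages[snp_id].reindex(ev["subject_id"]).to_numpy(dtype=float)
    out: dict[int, pd.DataFrame] = {}
    for g in (0, 1, 2):
        mask = dose == g
        if mask.sum() == 0:
            warnings.warn(f"no subjects with dosage {g} for {snp_id}; group skipped")
            continue
        sub = ev[mask]
        km = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(sub["exit_age"], sub["event"], entry=sub["entry_age"], label=str(g))
        df = km.survival_function_.copy()
        df.columns = ["survival"]
        var = km._cumulative_sq_ if hasattr(km, "_cumulative_sq_") else None
        df["se"] = (
            np.sqrt(np.asarray(var).ravel()) * df["survival"].to_numpy()
            if var is not None
            else np.nan
        )
        out[g] = df.reset_index().rename(columns={"timeline": "age"})
    return out
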