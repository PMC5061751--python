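"""Compact Newton solver and score tests for the Cox partial likelihood.

Supports left truncation (delayed entry on the age time scale), case
weights, and an offset.  Ties are handled by Breslow's approximation; the
simulators draw continuous ages, so ties are measure-zero there.  This
engine exists for the simulation-scale loops (null-SNP scans, bootstrap
replicates); user-facing fits go through lifelines and the two are
cross-checked in the test suite.

Risk sets with delayed entry are evaluated with two sorted suffix sums:

    sum over R(t) = {j : entry_j < t <= exit_j} of a_j
        = sum_{exit_j >= t} a_j - sum_{entry_j >= t} a_j

which is exact because entry < exit always holds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CoxNewtonResult", "cox_newton", "cox_score_scan", "schoenfeld_residuals"]


class _RiskSets:
    """Precomputed sort orders for suffix-sum risk-set evaluation."""

    def __init__(self, entry, exit_, event):
        self.entry = np.asarray(entry, dtype=float)
        self.exit = np.asarray(exit_, dtype=float)
        self.event = np.asarray(event).astype(bool)
        self.n = len(self.exit)
        self.exit_order = np.argsort(self.exit, kind="stable")
        self.entry_order = np.argsort(self.entry, kind="stable")
        self.exit_sorted = self.exit[self.exit_order]
        self.entry_sorted = self.entry[self.entry_order]
        self.event_times = self.exit[self.event]
        # position of each event time in the two sorted arrays
        self.ix_exit = np.searchsorted(self.exit_sorted, self.event_times, side="left")
        self.ix_entry = np.searchsorted(self.entry_sorted, self.event_times, side="left")

    def risk_sum(self, a: np.ndarray) -> np.ndarray:
        """Risk-set sums of per-subject values at every event time.

        ``a`` is (n,) or (n, m); returns (n_events,) or (n_events, m).
        """
        a = np.asarray(a, dtype=float)
        ae = a[self.exit_order]
        an = a[self.entry_order]
        suf_exit = np.concatenate(
            [np.cumsum(ae[::-1], axis=0)[::-1], np.zeros((1,) + a.shape[1:])]
        )
        suf_entry = np.concatenate(
            [np.cumsum(an[::-1], axis=0)[::-1], np.zeros((1,) + a.shape[1:])]
        )
        return suf_exit[self.ix_exit] - suf_entry[self.ix_entry]


class CoxNewtonResult:
    def __init__(self, beta, cov, loglik, converged, n_events):
        self.beta = beta
        self.cov = cov
        self.loglik = loglik
        self.converged = converged
        self.n_events = n_events

    @property
    def se(self):
        return np.sqrt(np.diag(self.cov))


def _loglik_parts(rs: _RiskSets, X, eta, w):
    r = w * np.exp(eta)
    s0 = rs.risk_sum(r)
    if (s0 <= 0).any():
        return None, None, None, None
    s1 = rs.risk_sum(r[:, None] * X)
    w_e = w[rs.event]
    ll = float(np.sum(w_e * (eta[rs.event] - np.log(s0))))
    return r, s0, s1, ll


def cox_newton(
    X,
    entry,
    exit_,
    event,
    weights=None,
    offset=None,
    beta0=None,
    max_iter=50,
    tol=1e-9,
) -> CoxNewtonResult:
    """Maximize the (weighted, Breslow) Cox partial likelihood by Newton steps.

    X: (n, p) covariates; entry/exit: ages; event: 0/1.  Returns the
    coefficient vector, the inverse observed information as ``cov``, the
    final partial log-likelihood, and a convergence flag.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rs = _RiskSets(entry, exit_, event)
    if rs.event.sum() == 0:
        raise ValueError("no events")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    iu, ju = np.triu_indices(p)
    ll_prev = -np.inf
    converged = False
    info = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta + off
        r, s0, s1, ll = _loglik_parts(rs, X, eta, w)
        if r is None:
            beta *= 0.5  # step back from a degenerate region
            continue
        w_e = w[rs.event]
        mean = s1 / s0[:, None]
        grad = (w_e[:, None] * (X[rs.event] - mean)).sum(axis=0)

        xx = X[:, iu] * X[:, ju]
        s2u = rs.risk_sum(r[:, None] * xx) / s0[:, None]
        info = np.zeros((p, p))
        acc = (w_e[:, None] * (s2u - mean[:, iu] * mean[:, ju])).sum(axis=0)
        info[iu, ju] = acc
        info[ju, iu] = acc

        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving if the likelihood does not improve
        scale = 1.0
        for _h in range(8):
            cand = beta + scale * step
            parts = _loglik_parts(rs, X, X @ cand + off, w)
            if parts[0] is not None and parts[3] >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(parts[3] - ll_prev) < tol * (abs(ll) + 1.0) and np.abs(grad).max() < 1e-4 * (
            1 + rs.event.sum()
        ):
            converged = True
            ll_prev = parts[3]
            break
        ll_prev = parts[3]

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return CoxNewtonResult(beta, cov, ll_prev, converged, int(rs.event.sum()))


def schoenfeld_residuals(X, entry, exit_, event, beta, offset=None):
    """Schoenfeld residuals and observed information at ``beta``.

    Returns ``(event_times, resid, info)`` where ``resid`` is
    (n_events, p) of x_e - E[x | risk set at t_e] ordered by event time,
    and ``info`` the observed information matrix of the partial
    likelihood (Breslow).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rs = _RiskSets(entry, exit_, event)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    r = np.exp(X @ np.asarray(beta, dtype=float) + off)
    s0 = rs.risk_sum(r)
    mean = rs.risk_sum(r[:, None] * X) / s0[:, None]
    resid = X[rs.event] - mean

    iu, ju = np.triu_indices(p)
    s2u = rs.risk_sum(r[:, None] * (X[:, iu] * X[:, ju])) / s0[:, None]
    acc = (s2u - mean[:, iu] * mean[:, ju]).sum(axis=0)
    info = np.zeros((p, p))
    info[iu, ju] = acc
    info[ju, iu] = acc

    order = np.argsort(rs.event_times, kind="stable")
    return rs.event_times[order], resid[order], info


def cox_score_scan(
    G,
    entry,
    exit_,
    event,
    offset=None,
    X_null=None,
    info_null=None,
):
    """Efficient score test of each column of G in a Cox model with offset.

    The null model (covariates only) is summarized by its linear
    predictor ``offset``; if ``X_null`` and its observed information
    ``info_null`` are supplied, the score variance is corrected for
    nuisance-parameter estimation (the efficient information
    I_gg - I_gx I_xx^-1 I_xg).  Returns (beta_onestep, se, z) arrays.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    rs = _RiskSets(entry, exit_, event)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    r = np.exp(off)
    s0 = rs.risk_sum(r)
    mean_g = rs.risk_sum(r[:, None] * G) / s0[:, None]
    mom2_g = rs.risk_sum(r[:, None] * G * G) / s0[:, None]
    U = (G[rs.event] - mean_g).sum(axis=0)
    V = (mom2_g - mean_g**2).sum(axis=0)

    if X_null is not None and info_null is not None and X_null.shape[1] > 0:
        X = np.asarray(X_null, dtype=float)
        mean_x = rs.risk_sum(r[:, None] * X) / s0[:, None]
        C = np.zeros((m, X.shape[1]))
        for k in range(X.shape[1]):
            cross = rs.risk_sum(r[:, None] * G * X[:, k : k + 1]) / s0[:, None]
            C[:, k] = (cross - mean_g * mean_x[:, k : k + 1]).sum(axis=0)
        V = V - np.einsum("mk,kl,ml->m", C, np.linalg.inv(info_null), C)

    V = np.maximum(V, 1e-300)
    z = U / np.sqrt(V)
    beta = U / V
    se = 1.0 / np.sqrt(V)
    return beta, se, z
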