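"""Survival analysis: Kaplan–Meier, k-group log-rank, and Cox regression
with backward-stepwise Wald covariate selection.

The Cox fitter maximizes the partial likelihood by Newton iterations
(gradient norm < 1e-8) with Breslow handling of tied event times by default
(Efron available), and reports per-covariate coefficients, hazard ratios,
Wald 95% CIs and p-values.  Backward selection repeatedly drops the
covariate with the largest Wald p while that p exceeds ``p_remove``
(default 0.10) and records the full elimination trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .stats import StatResult


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous step function from S(0)=1."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t) for any t >= 0."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group")
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e]) if e.any() else np.array([], dtype=float)
    surv, at_risk, d_at = [], [], []
    s = 1.0
    for u in uniq:
        n_i = int((t >= u).sum())
        d_i = int(((t == u) & e).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_at.append(d_i)
    return KMCurve(
        uniq, np.asarray(surv), np.asarray(at_risk, int), np.asarray(d_at, int)
    )


def km_by_group(times, events, groups) -> dict:
    """Kaplan–Meier curve per group label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    return {
        g: km_estimate(times[groups == g], events[groups == g])
        for g in np.unique(groups)
    }


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank(times, events, groups) -> StatResult:
    """Mantel–Haenszel log-rank chi-square over k >= 2 groups, df = k-1.

    Observed-minus-expected event counts per group are accumulated over the
    distinct event times; the quadratic form uses the hypergeometric
    covariance of the per-time event split.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if not events.any():
        raise ValueError("no events: log-rank undefined")
    gidx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for u in event_times:
        at_risk = times >= u
        n = at_risk.sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dying = at_risk & events & (times == u)
        d = dying.sum()
        d_g = np.bincount(gidx[dying], minlength=k).astype(float)
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1)
            cov += v * (np.diag(frac) - np.outer(frac, frac))
    # drop one group: the k-vector is singular by construction
    z = o_minus_e[:-1]
    v = cov[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(v) @ z)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return StatResult("logrank", chi2, p, df)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Fitted Cox model: per-covariate inference plus the selection trace."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    ties: str = "breslow"
    converged: bool = True
    elimination_trace: list = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.wald_z))

    def summary(self) -> dict:
        return {
            name: {
                "coef": float(c),
                "hr": float(h),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "p": float(pp),
            }
            for name, c, h, lo, hi, pp in zip(
                self.names, self.coef, self.hr, self.ci_lower, self.ci_upper, self.p
            )
        }


class CoxConvergenceError(RuntimeError):
    """Monotone likelihood / non-convergence of the Newton iterations."""


def _cox_loglik(beta, x, times, events, ties):
    """Partial-likelihood statistics: (loglik, grad, hess).

    Breslow: tied events share the full risk-set denominator.  Efron:
    tied events progressively down-weight their own contribution.
    Risk-set sums are suffix cumulative sums over descending time.
    """
    eta = x @ beta
    # cap to avoid overflow in pathological steps
    w = np.exp(np.clip(eta, -500, 500))
    order = np.argsort(-times, kind="stable")  # descending time
    x_o, t_o, e_o, w_o, eta_o = x[order], times[order], events[order], w[order], eta[order]
    n, p = x.shape
    wx = w_o[:, None] * x_o
    wxx = np.einsum("i,ij,ik->ijk", w_o, x_o, x_o)
    c0 = np.cumsum(w_o)
    c1 = np.cumsum(wx, axis=0)
    c2 = np.cumsum(wxx, axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # group boundaries of tied times in the descending ordering
    boundaries = np.flatnonzero(np.diff(t_o) != 0)
    ends = np.append(boundaries, n - 1)  # last index of each tie group
    starts = np.append(0, boundaries + 1)
    for i, j in zip(starts, ends):
        dead = np.flatnonzero(e_o[i : j + 1]) + i
        d = dead.size
        if d == 0:
            continue
        s0, s1, s2 = c0[j], c1[j], c2[j]
        loglik += float(eta_o[dead].sum())
        xd = x_o[dead]
        if ties == "breslow" or d == 1:
            loglik -= d * np.log(s0)
            grad += xd.sum(axis=0) - d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        else:  # efron
            wd = w_o[dead]
            d0 = wd.sum()
            d1 = (wd[:, None] * xd).sum(axis=0)
            d2 = np.einsum("i,ij,ik->jk", wd, xd, xd)
            grad += xd.sum(axis=0)
            for r in range(d):
                f = r / d
                a0 = s0 - f * d0
                a1 = s1 - f * d1
                a2 = s2 - f * d2
                loglik -= np.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
    return loglik, grad, hess


def cox_fit(
    x,
    times,
    events,
    names: list | None = None,
    ties: str = "breslow",
    max_iter: int = 60,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    x : (n, p) covariate matrix
    times, events : right-censored follow-up
    ties : "breslow" (default) or "efron"
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(times).size > 1:
        x = x.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = x.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if n <= p:
        raise ValueError("need more subjects than covariates")
    if not events.any():
        raise ValueError("no events: partial likelihood undefined")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant covariate in design matrix")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")

    beta = np.zeros(p)
    loglik = -np.inf
    # absolute gradient tolerance, relaxed by the problem scale (summing
    # thousands of partial-likelihood terms floors the reachable gradient)
    d_events = int(events.sum())
    gtol = max(tol, tol * d_events)
    for _ in range(max_iter):
        loglik, grad, hess = _cox_loglik(beta, x, times, events, ties)
        if np.linalg.norm(grad) < gtol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise CoxConvergenceError(f"singular Hessian: {err}") from err
        # damped Newton: halve until the likelihood does not decrease
        new = beta - step
        for _ in range(30):
            ll_new, _, _ = _cox_loglik(new, x, times, events, ties)
            if ll_new >= loglik - 1e-12:
                break
            new = (beta + new) / 2.0
        beta = new
    else:
        raise CoxConvergenceError(
            "Newton iterations did not reach gradient tolerance "
            "(possible monotone likelihood / complete separation)"
        )
    loglik, grad, hess = _cox_loglik(beta, x, times, events, ties)
    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if np.abs(beta).max() > 15 or not np.isfinite(se).all() or se.max() > 50:
        raise CoxConvergenceError(
            "monotone likelihood / complete separation: diverging coefficient"
        )
    return CoxResult(list(names), beta, se, float(loglik), ties=ties)


def backward_stepwise_wald(
    x,
    times,
    events,
    names: list,
    p_remove: float = 0.10,
    ties: str = "breslow",
) -> CoxResult:
    """Backward covariate elimination on Wald p-values.

    Start from the full model; while the largest Wald p exceeds ``p_remove``
    and more than one covariate remains, drop that covariate and refit.  The
    returned model carries the elimination trace (covariate, p at removal).
    Pure backward: removed covariates never re-enter.
    """
    x = np.asarray(x, dtype=float)
    names = list(names)
    keep = list(range(x.shape[1]))
    trace = []
    fit = cox_fit(x, times, events, names=names, ties=ties)
    while len(keep) > 1:
        pvals = fit.p
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_remove:
            break
        trace.append((fit.names[worst], float(pvals[worst])))
        keep.pop(worst)
        fit = cox_fit(
            x[:, keep], times, events,
            names=[names[i] for i in keep], ties=ties,
        )
    fit.elimination_trace = trace
    return fit
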