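"""Survival estimators implemented from first principles.

Kaplan-Meier product-limit curves, the (multi-group) log-rank test, Cox
proportional hazards with Efron handling of tied event times, and Harrell's
concordance index.  These are the building blocks for quantifying the
association between trajectory classes and time to first heart-failure
hospitalization; an established survival package is used only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class CoxConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (e.g. monotone likelihood)."""


class CoxRankError(RuntimeError):
    """Observed information matrix is singular."""


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same shape")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    if not np.all(np.isin(events, [0, 1])):
        raise ValueError("event indicators must be 0 or 1")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KmCurve:
    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S(t); S = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def kaplan_meier(times, events) -> KmCurve:
    """Product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j / n_j).

    Censored subjects leave the risk set immediately after their time, so a
    censoring tied to an event time is still at risk for that event.
    """
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    at_risk = np.empty(len(ev_times))
    d = np.empty(len(ev_times))
    for i, tj in enumerate(ev_times):
        at_risk[i] = np.sum(t >= tj)
        d[i] = np.sum((t == tj) & (e == 1))
    surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(event_times=ev_times, survival=surv, at_risk=at_risk, events=d)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    groups: list


def logrank_test(times, events, group_labels) -> LogrankResult:
    """G-sample log-rank test (hypergeometric variance form).

    At each distinct event time the observed events per group are compared
    with their expectation under a common hazard; the quadratic form of
    O - E over the first G-1 groups is chi-square with G-1 df.
    """
    times, events = _check_times_events(times, events)
    labels = np.asarray(group_labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    for g in groups:
        if np.sum(labels == g) == 0:
            raise ValueError(f"group {g!r} has no subjects")
    if events.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    G = len(groups)
    gidx = np.searchsorted(np.asarray(groups), labels) if np.issubdtype(
        labels.dtype, np.number
    ) else np.array([groups.index(v) for v in labels])

    ev_times = np.unique(times[events == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for tj in ev_times:
        risk = times >= tj
        n_j = risk.sum()
        n_gj = np.bincount(gidx[risk], minlength=G).astype(float)
        dead = risk & (times == tj) & (events == 1)
        d_j = dead.sum()
        d_gj = np.bincount(gidx[dead], minlength=G).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            f = d_j * (n_j - d_j) / (n_j - 1)
            V += f * (np.diag(n_gj / n_j) - np.outer(n_gj, n_gj) / n_j**2)
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if np.allclose(z, 0.0):
        chi2 = 0.0
    else:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    df = G - 1
    return LogrankResult(
        statistic=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0,
        observed=O,
        expected=E,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    coef: np.ndarray
    covariance: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # (p, 2)
    wald_p: np.ndarray
    loglik: float
    concordance: float
    names: list
    dropped: list = field(default_factory=list)
    n: int = 0
    n_events: int = 0
    converged: bool = True

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hr,
                "hr_lo95": self.ci95[:, 0],
                "hr_hi95": self.ci95[:, 1],
                "p": self.wald_p,
            },
            index=self.names,
        )


def _efron_loglik_grad_hess(beta, X, times, events, want_derivs=True):
    """Efron partial log-likelihood with analytic gradient and Hessian.

    Risk sums are suffix cumulative sums over subjects sorted by time; at
    each tied event time the Efron correction subtracts l/d of the tied
    deaths' contribution from the risk sums, l = 0..d-1.
    """
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = Xs * w[:, None]
    # suffix sums: risk set at time t = indices with time >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    if want_derivs:
        wXX = wX[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = np.arange(i, j)[e[i:j] == 1]
        d = len(dead)
        if d > 0:
            s0 = S0[i]
            s1 = S1[i]
            d0 = w[dead].sum()
            d1 = wX[dead].sum(axis=0)
            ll += eta[dead].sum()
            grad += Xs[dead].sum(axis=0)
            if want_derivs:
                s2 = S2[i]
                d2 = (wX[dead][:, :, None] * Xs[dead][:, None, :]).sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = s0 - f * d0
                phi1 = s1 - f * d1
                ll -= np.log(phi0)
                if want_derivs:
                    phi2 = s2 - f * d2
                    grad -= phi1 / phi0
                    hess -= phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
        i = j
    return (ll, grad, hess) if want_derivs else ll


def cox_fit(
    X,
    times,
    events,
    names=None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox PH fit by Newton-Raphson with step-halving.

    Constant covariate columns carry no information for the partial
    likelihood and are dropped with a warning.  Monotone likelihood (perfect
    separation) raises :class:`CoxConvergenceError` naming the covariate.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    times, events = _check_times_events(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        raise ValueError("X rows must match number of subjects")
    if events.sum() == 0:
        raise ValueError("Cox regression needs at least one event")
    p_all = X.shape[1]
    names = list(names) if names is not None else [f"x{j}" for j in range(p_all)]

    keep = [j for j in range(p_all) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(p_all) if j not in keep]
    if dropped:
        warnings.warn(f"dropping constant covariate columns: {dropped}")
    Xk = X[:, keep]
    if Xk.shape[1] == 0:
        raise ValueError("no non-constant covariates to fit")
    if np.linalg.matrix_rank(Xk - Xk.mean(axis=0)) < Xk.shape[1]:
        raise CoxRankError("covariate matrix is rank-deficient after centering")
    kept_names = [names[j] for j in keep]

    # center columns for numerical stability; coef estimates are unchanged
    mu = Xk.mean(axis=0)
    Xc = Xk - mu
    beta = np.zeros(Xc.shape[1])
    ll, grad, hess = _efron_loglik_grad_hess(beta, Xc, times, events)
    for _ in range(max_iter):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxRankError("singular information matrix") from exc
        # step-halving until the likelihood improves
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new = _efron_loglik_grad_hess(beta_new, Xc, times, events, want_derivs=False)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll_prev = beta_new, ll
        ll, grad, hess = _efron_loglik_grad_hess(beta, Xc, times, events)
        if np.any(np.abs(beta) > 100):
            worst = kept_names[int(np.argmax(np.abs(beta)))]
            raise CoxConvergenceError(
                f"monotone likelihood: coefficient for {worst!r} is diverging"
            )
        if abs(ll - ll_prev) < tol * max(abs(ll), 1.0) and np.max(np.abs(grad)) < 1e-5 * max(
            abs(ll), 1.0
        ):
            break
    else:
        raise CoxConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxRankError("singular information matrix at the optimum") from exc
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    hr = np.exp(beta)
    with np.errstate(over="ignore"):
        ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    lp = Xc @ beta
    c = concordance_index(times, events, lp)
    return CoxFit(
        coef=beta,
        covariance=cov,
        hr=hr,
        ci95=ci,
        wald_p=wald_p,
        loglik=float(ll),
        concordance=c,
        names=kept_names,
        dropped=dropped,
        n=len(times),
        n_events=int(events.sum()),
    )


def cox_null_loglik(times, events) -> float:
    """Efron partial log-likelihood at beta = 0 (no covariates needed)."""
    times, events = _check_times_events(times, events)
    return float(
        _efron_loglik_grad_hess(
            np.zeros(1), np.zeros((len(times), 1)), times, events, want_derivs=False
        )
    )


def cox_predict_risk(fit: CoxFit, covariate_rows) -> np.ndarray:
    """Linear predictor x' beta; monotone in the hazard, so sufficient for
    ranking.  Rows must match the fitted (non-dropped) covariates."""
    rows = np.atleast_2d(np.asarray(covariate_rows, dtype=float))
    if rows.shape[1] != len(fit.coef):
        raise ValueError(
            f"expected {len(fit.coef)} covariates ({fit.names}), got {rows.shape[1]}"
        )
    return rows @ fit.coef


# ---------------------------------------------------------------------------
# Harrell's concordance
# ---------------------------------------------------------------------------


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C for right-censored data.

    Comparable pairs: t_i < t_j with event_i = 1, plus tied-time pairs where
    exactly one of the two had the event (the censored subject is assumed to
    outlive it).  A pair is concordant when the earlier event carries the
    higher risk score; score ties count 1/2.
    """
    times, events = _check_times_events(times, events)
    r = np.asarray(risk_scores, dtype=float)
    ti = times[:, None]
    tj = times[None, :]
    ei = events[:, None].astype(bool)
    ej = events[None, :].astype(bool)
    comparable = ((ti < tj) & ei) | ((ti == tj) & ei & ~ej)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        warnings.warn("no comparable pairs; concordance undefined")
        return float("nan")
    ri = r[:, None]
    rj = r[None, :]
    conc = (comparable & (ri > rj)).sum() + 0.5 * (comparable & (ri == rj)).sum()
    return float(conc / n_pairs)


# ---------------------------------------------------------------------------
# Records-table interface
# ---------------------------------------------------------------------------


def records_from_frame(df: pd.DataFrame, covariate_cols):
    """(X, times, events) from a records table with ``time_weeks`` and
    ``event`` columns plus covariates."""
    times = df["time_weeks"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    X = df[list(covariate_cols)].to_numpy(dtype=float)
    return X, times, events
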