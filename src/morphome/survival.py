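"""Survival and categorical statistics implemented from first principles.

Everything here operates on right-censored follow-up data: ``time`` is
months from surgery, ``event`` is True when death was observed.  The module
provides the Cox proportional hazards model (Newton-Raphson on the partial
likelihood, Breslow or Efron ties), the Kaplan-Meier product-limit
estimator, the two-group log-rank test and Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError

#: |beta| beyond which the partial likelihood is treated as monotone
#: (diverging estimate, e.g. perfect group separation): a log hazard ratio
#: of 15 per unit covariate is already far outside anything estimable.
MONOTONE_BETA = 15.0


def _as_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    return time, event


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox proportional hazards model."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    ties_method: str
    converged: bool
    feature_names: list[str] = field(default_factory=list)
    n_events: int = 0
    n_iter: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> np.ndarray:
        """Per-coefficient hazard-ratio 95% CI, shape (p, 2)."""
        half = 1.959963984540054 * self.se
        return np.exp(
            np.column_stack([self.coefficients - half, self.coefficients + half])
        )

    @property
    def wald_p(self) -> np.ndarray:
        z = np.divide(self.coefficients, self.se,
                      out=np.zeros_like(self.coefficients), where=self.se > 0)
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        """Hazard ratios with 95% CIs and Wald p-values, one row per feature."""
        names = self.feature_names or [f"x{i}" for i in range(len(self.coefficients))]
        ci = self.ci95
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "hazard_ratio": self.hazard_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.wald_p,
            },
            index=pd.Index(names, name="feature"),
        )


def _tie_groups(time_sorted: np.ndarray) -> np.ndarray:
    """Start indices of tie groups in an ascending-sorted time vector."""
    return np.flatnonzero(np.r_[True, np.diff(time_sorted) > 0])


def cox_fit(
    X,
    time,
    event,
    ties: str = "breslow",
    feature_names: Sequence[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step-halving.

    Convergence when the largest coefficient update or the relative change
    in partial log-likelihood drops below ``tol``.  A diverging coefficient
    (|beta| > 22, monotone likelihood / separation) flags the fit
    non-converged with a warning; a singular information matrix raises
    :class:`~morphome.errors.FitError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = _as_survival(time, event)
    if isinstance(feature_names, pd.Index):
        feature_names = list(feature_names)
    n, p = X.shape
    if int(event.sum()) < 2:
        raise FitError("Cox fit requires at least 2 events")
    if np.any(np.isnan(X)):
        raise ValueError("X contains missing values")
    if p and np.any(X.std(axis=0) == 0):
        raise FitError("constant covariate column(s) in X")

    beta = np.zeros(p)
    ll, g, I = _cox_derivs(beta, X, time, event, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(I, g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix") from exc
        if not np.all(np.isfinite(step)):
            raise FitError("non-finite Newton step")
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, I_new = _cox_derivs(cand, X, time, event, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2
        delta = np.max(np.abs(cand - beta)) if p else 0.0
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta, ll, g, I = cand, ll_new, g_new, I_new
        if np.max(np.abs(beta), initial=0.0) > MONOTONE_BETA:
            warnings.warn(
                "monotone partial likelihood: coefficient diverging, "
                "fit flagged non-converged",
                RuntimeWarning,
                stacklevel=2,
            )
            converged = False
            break
        if delta < tol or rel < tol:
            converged = True
            if np.max(np.abs(beta), initial=0.0) > MONOTONE_BETA:
                warnings.warn(
                    "monotone partial likelihood: coefficient diverging, "
                    "fit flagged non-converged",
                    RuntimeWarning,
                    stacklevel=2,
                )
                converged = False
            break
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix at the optimum") from exc
    return CoxFit(
        coefficients=beta,
        covariance=cov,
        log_partial_likelihood=float(ll),
        ties_method=ties,
        converged=converged,
        feature_names=list(feature_names) if feature_names is not None else [],
        n_events=int(event.sum()),
        n_iter=it,
    )


def _cox_derivs(beta, X, time, event, ties):
    """Partial log-likelihood, gradient and observed information."""
    idx = np.argsort(time, kind="stable")
    t, d, Xs = time[idx], event[idx], X[idx]
    eta = Xs @ beta
    shift = eta.max() if len(eta) else 0.0
    r = np.exp(eta - shift)
    n, p = Xs.shape
    s0 = np.cumsum(r[::-1])[::-1]
    rX = r[:, None] * Xs
    s1 = np.cumsum(rX[::-1], axis=0)[::-1]
    rXX = rX[:, :, None] * Xs[:, None, :]
    s2 = np.cumsum(rXX[::-1], axis=0)[::-1]
    starts = _tie_groups(t)
    ends = np.r_[starts[1:], n]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for gs, ge in zip(starts, ends):
        ev = np.flatnonzero(d[gs:ge]) + gs
        m = len(ev)
        if m == 0:
            continue
        ll += float(eta[ev].sum())
        grad += Xs[ev].sum(axis=0)
        if ties == "breslow" or m == 1:
            ll -= m * (np.log(s0[gs]) + shift)
            mu = s1[gs] / s0[gs]
            grad -= m * mu
            info += m * (s2[gs] / s0[gs] - np.outer(mu, mu))
        elif ties == "efron":
            r_tie = float(r[ev].sum())
            s1_tie = rX[ev].sum(axis=0)
            s2_tie = rXX[ev].sum(axis=0)
            for l in range(m):
                f = l / m
                d0 = s0[gs] - f * r_tie
                d1 = s1[gs] - f * s1_tie
                d2 = s2[gs] - f * s2_tie
                ll -= np.log(d0) + shift
                mu = d1 / d0
                grad -= mu
                info += d2 / d0 - np.outer(mu, mu)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, info


def cox_loglik(beta, X, time, event, ties: str = "breslow") -> float:
    """Partial log-likelihood at ``beta`` (used for deviance and AIC)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.asarray(beta, dtype=float)
    time, event = _as_survival(time, event)
    ll, _, _ = _cox_derivs(beta, X, time, event, ties)
    return float(ll)


def cox_score(beta, X, time, event, ties: str = "breslow") -> np.ndarray:
    """Analytic gradient of the partial log-likelihood at ``beta``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = _as_survival(time, event)
    _, g, _ = _cox_derivs(np.asarray(beta, float), X, time, event, ties)
    return g


def cox_score_test(X, time, event) -> tuple[float, float]:
    """Score (Rao) test of beta = 0; equals the log-rank statistic for a
    single binary covariate without ties."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = _as_survival(time, event)
    _, g, I = _cox_derivs(np.zeros(X.shape[1]), X, time, event, "breslow")
    chi2 = float(g @ np.linalg.solve(I, g))
    return chi2, float(stats.chi2.sf(chi2, X.shape[1]))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit estimate of the survival function."""

    event_times: np.ndarray  # times at which the curve steps down
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median_survival: float  # nan when the curve never reaches 0.5

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def risk_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def kaplan_meier(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are counted at risk for that time
    (censoring is taken to happen just after the deaths).  The median is the
    first time at which the curve reaches 0.5 or below; ``nan`` means the
    median was not reached.
    """
    time, event = _as_survival(time, event)
    if time.size == 0:
        raise ValueError("empty survival data")
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    uniq = np.unique(t[d]) if d.any() else np.array([])
    surv, at_risk, events = [], [], []
    s = 1.0
    for u in uniq:
        n_risk = int((t >= u).sum())
        n_ev = int(((t == u) & d).sum())
        s *= 1.0 - n_ev / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        events.append(n_ev)
    surv = np.asarray(surv)
    median = float(uniq[np.argmax(surv <= 0.5)]) if np.any(surv <= 0.5) else float("nan")
    return KMEstimate(
        event_times=np.asarray(uniq, dtype=float),
        survival=surv,
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(events, dtype=int),
        median_survival=median,
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def logrank_test(time1, event1, time2, event2) -> tuple[float, float]:
    """Two-group log-rank test.

    Observed-minus-expected events in group 1 summed over event times, with
    the hypergeometric variance; the statistic is chi-square with 1 df and
    the p-value two-sided.
    """
    t1, d1 = _as_survival(time1, event1)
    t2, d2 = _as_survival(time2, event2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be nonempty")
    if d1.sum() + d2.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    t = np.r_[t1, t2]
    d = np.r_[d1, d2]
    grp = np.r_[np.zeros(t1.size, bool), np.ones(t2.size, bool)]
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(t[d]):
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & ~grp).sum())
        ev = (t == u) & d
        m = int(ev.sum())
        o1 = int((ev & ~grp).sum())
        e1 = m * n1 / n
        o_minus_e += o1 - e1
        if n > 1:
            var += m * (n1 / n) * (1 - n1 / n) * (n - m) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 table of nonnegative counts.

    Sums the probabilities, under the hypergeometric null with fixed
    margins, of all tables at most as probable as the observed one.  A table
    with an all-zero margin is degenerate and returns p = 1.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("table must be 2x2 with nonnegative integers")
    a = int(tab[0, 0])
    r1, r2 = int(tab[0].sum()), int(tab[1].sum())
    c1 = int(tab[:, 0].sum())
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    # relative tolerance guards against ties lost to floating-point noise
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if p > 1.0 - 1e-12:  # full-support sums carry float noise
        return 1.0
    return p
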