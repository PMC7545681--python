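"""Lasso / elastic-net penalized Cox regression along a regularization path.

The solver follows the classic coordinate-descent scheme: at each penalty
value an outer loop forms the iteratively-reweighted quadratic approximation
of the Breslow partial likelihood in the linear predictor, and an inner loop
solves the penalized weighted least-squares problem by cyclic coordinate
descent with soft-thresholding, warm-starting down a geometric lambda grid.
Features are standardized internally (mean 0, population SD 1) and the
penalty applies on the standardized scale; coefficients are reported back on
the original scale.

Objective (standardized scale):

    -(1/n) * loglik(beta)  +  lambda * sum_j [ alpha*|b_j| + (1-alpha)*b_j^2/2 ]

Tuning uses V-fold cross-validated partial-likelihood deviance: the
contribution of fold k is -2*[ loglik_all(beta_{-k}) - loglik_train(beta_{-k}) ]
(the cross-validated partial likelihood of van Houwelingen), summed into a
per-lambda mean and standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import FitError
from .survival import _as_survival

_EPS_W = 1e-10


# ---------------------------------------------------------------------------
# numba kernels (all operate on time-ascending-sorted arrays)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _irls_weights(eta, delta, group_start, group_events):
    """Score g, curvature w (diagonal Hessian approx) and Breslow loglik."""
    n = eta.shape[0]
    G = group_start.shape[0]
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    r = np.empty(n)
    for i in range(n):
        r[i] = np.exp(eta[i] - shift)
    suff = np.empty(n + 1)
    suff[n] = 0.0
    for i in range(n - 1, -1, -1):
        suff[i] = suff[i + 1] + r[i]
    g = np.empty(n)
    w = np.empty(n)
    ll = 0.0
    a = 0.0  # sum over event groups so far of d/S0
    b = 0.0  # sum of d/S0^2
    gi = 0
    for gi in range(G):
        gs = group_start[gi]
        ge = group_start[gi + 1] if gi + 1 < G else n
        d = group_events[gi]
        if d > 0:
            s0 = suff[gs]
            if s0 < 1e-300:  # underflow guard (diverging linear predictor)
                s0 = 1e-300
            a += d / s0
            b += d / (s0 * s0)
            ll -= d * (np.log(s0) + shift)
        for i in range(gs, ge):
            ra = r[i] * a
            g[i] = (1.0 if delta[i] else 0.0) - ra
            w[i] = ra - r[i] * r[i] * b
            if delta[i]:
                ll += eta[i]
    return g, w, ll


@njit(cache=True, fastmath=True)
def _breslow_loglik(eta, delta, group_start, group_events):
    n = eta.shape[0]
    G = group_start.shape[0]
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    suff = 0.0
    # suffix sums per group start, walk groups from the end
    s0g = np.empty(G)
    gi = G - 1
    i = n - 1
    for gi in range(G - 1, -1, -1):
        gs = group_start[gi]
        while i >= gs:
            suff += np.exp(eta[i] - shift)
            i -= 1
        s0g[gi] = suff
    ll = 0.0
    for gi in range(G):
        d = group_events[gi]
        if d > 0:
            s0 = s0g[gi]
            if s0 < 1e-300:
                s0 = 1e-300
            ll -= d * (np.log(s0) + shift)
    for j in range(n):
        if delta[j]:
            ll += eta[j]
    return ll


@njit(cache=True, fastmath=True)
def _cd_update(j, XT, w, e, beta, wx2, l1, l2, n):
    """One coordinate update; returns |change|."""
    bj = beta[j]
    num = bj * wx2[j]
    s = 0.0
    for i in range(n):
        s += w[i] * XT[j, i] * e[i]
    num += s / n
    if num > l1:
        bn = (num - l1) / (wx2[j] + l2)
    elif num < -l1:
        bn = (num + l1) / (wx2[j] + l2)
    else:
        bn = 0.0
    diff = bn - bj
    if diff != 0.0:
        for i in range(n):
            e[i] -= XT[j, i] * diff
        beta[j] = bn
        return abs(diff)
    return 0.0


@njit(cache=True, fastmath=True)
def _cd_path(XT, delta, group_start, group_events, lambdas, alpha,
             tol, max_outer, max_sweeps):
    """Coordinate-descent solve of the whole lambda path (warm starts).

    ``XT`` is the standardized feature matrix transposed to (p, n) for
    column-contiguous access.  After each full sweep the inner loop cycles
    over the active (nonzero) set only until it stabilizes, then re-checks
    all features — the standard active-set strategy.  Returns
    (coefficients[p, L] on the standardized scale, converged[L]).
    """
    p, n = XT.shape
    L = lambdas.shape[0]
    beta = np.zeros(p)
    coefs = np.zeros((p, L))
    conv = np.zeros(L, dtype=np.bool_)
    eta = np.zeros(n)
    strong = np.zeros(p, dtype=np.bool_)
    for li in range(L):
        lam = lambdas[li]
        lam_prev = lambdas[li - 1] if li > 0 else lam
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        # sequential strong rule: screen to features whose score at the
        # previous solution exceeds alpha*(2*lam - lam_prev); violations are
        # caught by the KKT check below and trigger a re-solve
        g, w, ll = _irls_weights(eta, delta, group_start, group_events)
        thr = alpha * (2.0 * lam - lam_prev)
        for j in range(p):
            if beta[j] != 0.0:
                strong[j] = True
            else:
                s = 0.0
                for i in range(n):
                    s += XT[j, i] * g[i]
                strong[j] = abs(s) / n >= thr
        ok = False
        for _kkt_round in range(6):
            obj_prev = np.inf
            for _outer in range(max_outer):
                g, w, ll = _irls_weights(eta, delta, group_start, group_events)
                pen = 0.0
                for j in range(p):
                    pen += l1 * abs(beta[j]) + 0.5 * l2 * beta[j] * beta[j]
                obj = -ll / n + pen
                # objective-change stop: the penalized deviance has settled
                # even if large nearly-unpenalized coefficients still wiggle
                if abs(obj_prev - obj) < 1e-9 * (1.0 + abs(obj)):
                    ok = True
                    break
                obj_prev = obj
                for i in range(n):
                    if w[i] < _EPS_W:
                        w[i] = _EPS_W
                # working residual e_i = z_i - eta_i = g_i / w_i
                e = np.empty(n)
                for i in range(n):
                    e[i] = g[i] / w[i]
                wx2 = np.empty(p)
                for j in range(p):
                    if not strong[j]:
                        continue
                    s = 0.0
                    for i in range(n):
                        s += w[i] * XT[j, i] * XT[j, i]
                    wx2[j] = s / n
                beta_out_start = beta.copy()
                sweeps = 0
                while sweeps < max_sweeps:
                    # full sweep over the screened set
                    dmax = 0.0
                    for j in range(p):
                        if strong[j]:
                            d = _cd_update(j, XT, w, e, beta, wx2, l1, l2, n)
                            if d > dmax:
                                dmax = d
                    sweeps += 1
                    if dmax < tol:
                        break
                    # cycle over the active set until it stabilizes
                    while sweeps < max_sweeps:
                        dmax = 0.0
                        for j in range(p):
                            if beta[j] != 0.0:
                                d = _cd_update(j, XT, w, e, beta, wx2, l1, l2, n)
                                if d > dmax:
                                    dmax = d
                        sweeps += 1
                        if dmax < tol:
                            break
                # refresh eta from beta
                for i in range(n):
                    s = 0.0
                    for j in range(p):
                        if beta[j] != 0.0:
                            s += XT[j, i] * beta[j]
                    eta[i] = s
                moved = 0.0
                bmax = 0.0
                for j in range(p):
                    ad = abs(beta[j] - beta_out_start[j])
                    if ad > moved:
                        moved = ad
                    ab = abs(beta[j])
                    if ab > bmax:
                        bmax = ab
                if bmax > 30.0:
                    # monotone likelihood: a standardized coefficient this
                    # large means separation; stop polishing this lambda
                    ok = False
                    break
                # relative: large nearly-unpenalized coefficients need not
                # settle to the absolute tolerance of the sparse segment
                if moved < tol * 10.0 * (1.0 + bmax):
                    ok = True
                    break
            # KKT check on the screened-out features
            bmax = 0.0
            for j in range(p):
                ab = abs(beta[j])
                if ab > bmax:
                    bmax = ab
            if bmax > 30.0:
                break  # diverged; re-solving cannot help
            g, w, ll = _irls_weights(eta, delta, group_start, group_events)
            violations = 0
            for j in range(p):
                if strong[j]:
                    continue
                s = 0.0
                for i in range(n):
                    s += XT[j, i] * g[i]
                if abs(s) / n > l1 * (1.0 + 1e-9):
                    strong[j] = True
                    violations += 1
            if violations == 0:
                break
            ok = False
        for j in range(p):
            coefs[j, li] = beta[j]
        conv[li] = ok
        bmax = 0.0
        for j in range(p):
            ab = abs(beta[j])
            if ab > bmax:
                bmax = ab
        if bmax > 30.0:
            # monotone likelihood: smaller penalties only diverge further;
            # truncate the path here (remaining entries flagged, frozen)
            for lj in range(li + 1, L):
                for j in range(p):
                    coefs[j, lj] = beta[j]
                conv[lj] = False
            break
    return coefs, conv


@njit(cache=True, fastmath=True)
def _loglik_over_path(X, delta, group_start, group_events, coefs):
    """Breslow loglik at each column of ``coefs`` (original-scale X)."""
    n, p = X.shape
    L = coefs.shape[1]
    out = np.empty(L)
    eta = np.empty(n)
    for li in range(L):
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += X[i, j] * coefs[j, li]
            eta[i] = s
        out[li] = _breslow_loglik(eta, delta, group_start, group_events)
    return out


# ---------------------------------------------------------------------------
# data preparation and public API
# ---------------------------------------------------------------------------

def _prepare(time, event):
    """Sort ascending by time; build tie-group structure for Breslow terms."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0]).astype(np.int64)
    G = len(starts)
    ends = np.r_[starts[1:], len(t)]
    group_events = np.array(
        [int(d[s:e].sum()) for s, e in zip(starts, ends)], dtype=np.int64
    )
    return order, d.astype(np.bool_), starts, group_events


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, glmnet-style
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe, mean, sd


@dataclass
class CoxnetPath:
    """Solution path of the penalized Cox model."""

    alpha: float
    lambdas: np.ndarray
    coefficients: np.ndarray  # (p, L), original feature scale
    converged: np.ndarray  # (L,)
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: list[str]

    def nonzero(self, lam: float, tol: float = 0.0) -> list[str]:
        li = int(np.argmin(np.abs(self.lambdas - lam)))
        names = self.feature_names or [f"x{j}" for j in range(self.coefficients.shape[0])]
        return [n for n, c in zip(names, self.coefficients[:, li]) if abs(c) > tol]

    def coefficients_at(self, lam: float) -> np.ndarray:
        li = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefficients[:, li]

    def to_long_frame(self):
        import pandas as pd

        names = self.feature_names or [f"x{j}" for j in range(self.coefficients.shape[0])]
        rows = [
            (lam, name, self.coefficients[j, li])
            for li, lam in enumerate(self.lambdas)
            for j, name in enumerate(names)
        ]
        return pd.DataFrame(rows, columns=["lambda", "feature", "coefficient"])


def lambda_max(X, time, event, alpha: float = 1.0) -> float:
    """Smallest penalty with an all-zero solution.

    Equal to the largest absolute component of the score of the partial
    likelihood at beta = 0 on the standardized scale, divided by n*alpha.
    """
    X = np.asarray(X, dtype=float)
    time, event = _as_survival(time, event)
    Xs, _, _ = _standardize(X)
    order, delta, starts, group_events = _prepare(time, event)
    g, _, _ = _irls_weights(np.zeros(len(time)), delta, starts, group_events)
    score = Xs[order].T @ g
    return float(np.max(np.abs(score)) / (len(time) * alpha))


def coxnet_path(
    X,
    time,
    event,
    alpha: float = 1.0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    lambdas=None,
    feature_names=None,
    tol: float = 1e-7,
    max_outer: int = 25,
    max_sweeps: int = 150,
) -> CoxnetPath:
    """Fit the penalized Cox path by cyclic coordinate descent.

    ``alpha`` = 1 is the pure lasso; ``alpha`` in (0, 1) mixes in a ridge
    term.  The default grid has ``n_lambda`` log-spaced values from
    ``lambda_max`` (all-zero solution) down to
    ``lambda_max * lambda_min_ratio``.  Constant feature columns keep a zero
    coefficient throughout.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    time, event = _as_survival(time, event)
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if int(event.sum()) == 0:
        raise FitError("penalized Cox fit requires at least one event")
    if hasattr(X, "columns") and feature_names is None:
        feature_names = list(X.columns)
    n, p = X.shape
    Xs, mean, sd = _standardize(X)
    order, delta, starts, group_events = _prepare(time, event)
    XsoT = np.ascontiguousarray(Xs[order].T)
    if lambdas is None:
        lmax = lambda_max(X, time, event, alpha)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("lambdas must be decreasing")
    coefs_std, conv = _cd_path(
        XsoT, delta, starts, group_events, lambdas, float(alpha),
        tol, max_outer, max_sweeps,
    )
    if not conv.all():
        warnings.warn(
            f"{int((~conv).sum())} of {len(lambdas)} path points did not "
            "converge within the iteration budget",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(sd > 0, sd, 1.0)
    coefs = coefs_std / safe[:, None]
    coefs[sd == 0, :] = 0.0
    return CoxnetPath(
        alpha=float(alpha),
        lambdas=lambdas,
        coefficients=coefs,
        converged=conv,
        feature_means=mean,
        feature_sds=sd,
        feature_names=list(feature_names) if feature_names is not None else [],
    )


@dataclass
class CVResult:
    """V-fold cross-validation of the penalty strength."""

    fold_assignment: np.ndarray  # subject -> fold index 0..V-1
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_opt: float  # deviance-minimizing penalty
    lambda_1se: float  # largest penalty within one SE of the minimum
    path: CoxnetPath  # full-data path on the same grid

    def nonzero_at_opt(self, tol: float = 0.0) -> list[str]:
        return self.path.nonzero(self.lambda_opt, tol)


def _make_folds(n, V, event, rng, max_attempts=10):
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        fold = np.empty(n, dtype=np.int64)
        fold[perm] = np.arange(n) % V
        ok = all(event[fold == k].sum() >= 1 for k in range(V))
        if ok:
            return fold
    raise FitError(
        f"could not build {V} folds each containing an event "
        f"in {max_attempts} attempts"
    )


def cv_coxnet(
    X,
    time,
    event,
    V: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    feature_names=None,
    tol: float = 1e-6,
    fold_tol: float = 3e-5,
    fold_max_outer: int = 8,
    fold_max_sweeps: int = 30,
) -> CVResult:
    """Cross-validate the lambda grid by partial-likelihood deviance.

    Folds are drawn by a seeded shuffle and balanced to within one subject;
    a shuffle that leaves some fold without any event is redrawn (at most 10
    attempts).  Fold k's deviance contribution at each lambda is
    ``-2 * [loglik_all(beta_hat_minus_k) - loglik_train(beta_hat_minus_k)]``.

    Fold fits run under a bounded iteration budget (``fold_*`` arguments):
    the deep overfit tail of the grid, where coordinate descent on the
    collinear fraction triples converges slowly, contributes its current
    iterate to the deviance curve instead of being polished — the deviance
    minimum sits far above that region, so the tuned lambda is unaffected
    while fold fitting stays fast.  The full-data path, whose nonzero set
    at the tuned lambda defines the selection, uses the strict settings.
    """
    X = np.asarray(X, dtype=float)
    time, event = _as_survival(time, event)
    n = len(time)
    if V < 2:
        raise ValueError("V must be >= 2")
    if n < V:
        raise ValueError("need at least V subjects")
    full = coxnet_path(
        X, time, event, alpha=alpha, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, feature_names=feature_names, tol=tol,
    )
    lambdas = full.lambdas
    rng = np.random.default_rng(seed)
    fold = _make_folds(n, V, event, rng)

    order_all, delta_all, starts_all, ge_all = _prepare(time, event)
    Xo_all = np.ascontiguousarray(X[order_all])
    dev = np.empty((V, len(lambdas)))
    for k in range(V):
        train = fold != k
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pk = coxnet_path(
                X[train], time[train], event[train], alpha=alpha,
                lambdas=lambdas, tol=fold_tol,
                max_outer=fold_max_outer, max_sweeps=fold_max_sweeps,
            )
        order_tr, delta_tr, starts_tr, ge_tr = _prepare(time[train], event[train])
        Xo_tr = np.ascontiguousarray(X[train][order_tr])
        ll_all = _loglik_over_path(Xo_all, delta_all, starts_all, ge_all, pk.coefficients)
        ll_tr = _loglik_over_path(Xo_tr, delta_tr, starts_tr, ge_tr, pk.coefficients)
        dev[k] = -2.0 * (ll_all - ll_tr)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(V)
    i_opt = int(np.argmin(mean))
    within = mean <= mean[i_opt] + se[i_opt]
    i_1se = int(np.flatnonzero(within)[0])  # lambdas are decreasing
    return CVResult(
        fold_assignment=fold,
        lambdas=lambdas,
        mean_deviance=mean,
        se_deviance=se,
        lambda_opt=float(lambdas[i_opt]),
        lambda_1se=float(lambdas[i_1se]),
        path=full,
    )
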