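"""Survival analysis from first principles.

Kaplan-Meier product-limit estimation, the two-group log-rank test, Cox
proportional-hazards fitting by Newton-Raphson on the Efron-approximated
partial likelihood, and L1-penalized (LASSO) Cox regression by cyclic
coordinate descent with k-fold cross-validation on the partial-likelihood
deviance.

Conventions
-----------
* Times are positive reals (days).  At tied times, events precede
  censorings: a sample censored at an event time is still at risk for that
  event.
* Tie handling in the partial likelihood is the Efron approximation by
  default (Breslow available via ``ties="breslow"``).
* Standard errors come from the inverse observed information; Wald p-values
  are two-sided normal; 95% CIs are exp(beta +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _spdist

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "CoxFit",
    "LassoCoxPath",
    "km_curve",
    "logrank",
    "cox_fit",
    "lasso_cox",
    "cv_folds",
]

_BETA_CAP = 20.0  # |beta| beyond this signals monotone likelihood / separation


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate over the distinct event times."""

    times: np.ndarray      # distinct event times, increasing
    survival: np.ndarray   # S(t) just after each event time
    n_risk: np.ndarray     # at-risk count just before each event time
    n_event: np.ndarray    # events at each time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit (one row per covariate)."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, 0.0)
        return 2.0 * _spdist.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "HR": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.wald_p,
            }
        ).set_index("covariate")


@dataclass
class LassoCoxPath:
    """Coefficient path of an L1-penalized Cox regression with CV selection."""

    covariates: list[str]
    lambdas: np.ndarray            # decreasing grid
    coefs: np.ndarray              # (n_lambda, p) on the original scale
    cv_deviance: np.ndarray        # mean CV partial-likelihood deviance
    cv_se: np.ndarray              # SE of the CV deviance across folds
    selected_lambda: float
    selected_index: int
    selection_rule: str
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def selected_coefs(self) -> pd.Series:
        return pd.Series(self.coefs[self.selected_index], index=self.covariates)

    @property
    def active_set(self) -> list[str]:
        c = self.coefs[self.selected_index]
        return [name for name, b in zip(self.covariates, c) if b != 0.0]


def _check_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if t.ndim != 1 or e.shape != t.shape:
        raise ValueError("time and event must be 1-D and equal length")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("survival times must be positive and finite")
    if not np.all(np.isin(e, [0, 1])):
        raise ValueError("event indicator must be 0 or 1")
    return t, e.astype(int)


def km_curve(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimator for one group.

    Censored observations at an event time remain at risk through that
    event (event-before-censor tie convention).
    """
    t, e = _check_surv(time, event)
    if t.size == 0:
        raise ValueError("empty group")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    surv = []
    n_risk = []
    n_event = []
    s = 1.0
    for tau in event_times:
        at_risk = int(np.sum(t >= tau))
        d = int(np.sum((t == tau) & (e == 1)))
        s *= 1.0 - d / at_risk
        n_risk.append(at_risk)
        n_event.append(d)
        surv.append(s)
    return KMEstimate(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        n_risk=np.asarray(n_risk, dtype=int),
        n_event=np.asarray(n_event, dtype=int),
    )


def logrank(time, event, group) -> LogRankResult:
    """Two-group log-rank test.

    chi2 = (O - E)^2 / V with hypergeometric variance summed over the
    distinct event times; p from the chi-square distribution with 1 df.
    """
    t, e = _check_surv(time, event)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    if e.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    in1 = g == levels[0]
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for tau in event_times:
        at_risk = t >= tau
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d_tot = int(((t == tau) & (e == 1)).sum())
        d1 = int(((t == tau) & (e == 1) & in1).sum())
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += (
                d_tot
                * (n1 / n_tot)
                * (1.0 - n1 / n_tot)
                * (n_tot - d_tot)
                / (n_tot - 1)
            )
    if var <= 0:
        return LogRankResult(chi2=0.0, df=1, p=1.0)
    chi2 = o_minus_e**2 / var
    return LogRankResult(chi2=float(chi2), df=1, p=float(_spdist.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery
# ---------------------------------------------------------------------------


def _sort_for_cox(time, event, X):
    order = np.argsort(time, kind="mergesort")
    return time[order], event[order], X[order], order


def _partial_loglik(time, event, X, beta, ties: str = "efron") -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient, and observed information.

    Inputs must be sorted by ascending time.  Returns (loglik, grad, info)
    where info is the negated Hessian (p x p).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    # suffix sums over the risk set {t_i >= tau}
    s0_suffix = np.cumsum(w[::-1])[::-1]
    s1_suffix = np.cumsum(wx[::-1], axis=0)[::-1]
    # for S2 accumulate lazily per event time (p is small)
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    # precompute suffix of w_i * x_i x_i^T via cumulative on reversed arrays
    wxx = wx[:, :, None] * X[:, None, :]
    s2_suffix = np.cumsum(wxx[::-1], axis=0)[::-1]
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j + 1) if event[k] == 1]
        d = len(d_idx)
        if d > 0:
            s0 = s0_suffix[i]
            s1 = s1_suffix[i]
            s2 = s2_suffix[i]
            s0d = w[d_idx].sum()
            s1d = wx[d_idx].sum(axis=0)
            s2d = wxx[d_idx].sum(axis=0)
            loglik += eta[d_idx].sum()
            grad += X[d_idx].sum(axis=0)
            if ties == "breslow":
                fracs = np.zeros(d)
            else:
                fracs = np.arange(d) / d
            for f in fracs:
                phi = s0 - f * s0d
                psi1 = s1 - f * s1d
                psi2 = s2 - f * s2d
                loglik -= np.log(phi)
                mu = psi1 / phi
                grad -= mu
                info += psi2 / phi - np.outer(mu, mu)
        i = j + 1
    return float(loglik), grad, info


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    The log partial likelihood is guaranteed non-decreasing across
    iterations by step-halving.  Divergence (any |beta| exceeding 20,
    typical of monotone likelihood under separation) or a singular
    information matrix yields a fit flagged ``converged=False`` rather
    than silently reported coefficients.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (time_col, event_col)]
    if not covariates:
        raise ValueError("no covariates to fit")
    t, e = _check_surv(data[time_col].to_numpy(), data[event_col].to_numpy())
    if e.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    X = data[covariates].to_numpy(dtype=float)
    for k, name in enumerate(covariates):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    t, e, X, _ = _sort_for_cox(t, e, X)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _partial_loglik(t, e, X, beta, ties)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving: never accept a decrease in the partial likelihood
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, info_new = _partial_loglik(t, e, X, beta_new, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            break
        beta, ll_prev = beta_new, ll
        ll, grad, info = ll_new, grad_new, info_new
        if np.any(np.abs(beta) > _BETA_CAP):
            break
        if np.max(np.abs(grad)) < tol_score or abs(ll - ll_prev) < tol_loglik * (
            abs(ll_prev) + 1e-12
        ):
            converged = True
            break
    if np.any(np.abs(beta) > _BETA_CAP):
        converged = False
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        if np.any(~np.isfinite(se)):
            converged = False
            se = np.where(np.isfinite(se), se, np.inf)
    except np.linalg.LinAlgError:
        converged = False
        se = np.full(p, np.inf)
    return CoxFit(
        covariates=list(covariates),
        beta=beta,
        se=se,
        loglik=ll,
        loglik_null=ll_null,
        iterations=it,
        converged=converged,
    )


def cox_score_test(data: pd.DataFrame, covariate: str, time_col="time", event_col="event",
                   ties: str = "efron") -> float:
    """Score (Rao) test statistic at beta = 0 for a single covariate.

    For a binary covariate without tied event times this equals the
    log-rank chi-square.
    """
    t, e = _check_surv(data[time_col].to_numpy(), data[event_col].to_numpy())
    X = data[[covariate]].to_numpy(dtype=float)
    t, e, X, _ = _sort_for_cox(t, e, X)
    _, grad, info = _partial_loglik(t, e, X, np.zeros(1), ties)
    return float(grad[0] ** 2 / info[0, 0])


# ---------------------------------------------------------------------------
# LASSO-Cox by cyclic coordinate descent
# ---------------------------------------------------------------------------


def _eta_derivatives(time, event, eta, ties: str = "efron"):
    """Per-observation first/second derivatives of the log partial
    likelihood with respect to the linear predictor.

    Inputs sorted by ascending time.  Returns (loglik, g, h) with
    g_i = dl/deta_i and h_i = -d2l/deta_i^2 >= 0 (diagonal only).
    """
    n = time.size
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    s0_suffix = np.cumsum(w[::-1])[::-1]
    if np.unique(time).size == n:
        # all times distinct: Efron and Breslow coincide and everything
        # vectorizes as cumulative sums over the sort order
        ev = event.astype(float)
        inv = np.where(event == 1, 1.0 / s0_suffix, 0.0)
        cum_c = np.cumsum(inv)
        cum_c2 = np.cumsum(np.where(event == 1, 1.0 / s0_suffix**2, 0.0))
        loglik = float(np.sum(ev * eta) - np.sum(np.log(s0_suffix[event == 1])))
        g = ev - w * cum_c
        h = np.clip(w * cum_c - w**2 * cum_c2, 0.0, None)
        return loglik, g, h
    loglik = 0.0
    # per-event-time scalar sums; then distribute to observations
    # c  = sum_r 1/phi, c2 = sum_r 1/phi^2   (cumulative over earlier times)
    # b  = sum_r (r/d)/phi, b2 = sum_r (2(r/d) - (r/d)^2)/phi^2  (tied-set only)
    cum_c = np.zeros(n)
    cum_c2 = np.zeros(n)
    own_b = np.zeros(n)
    own_b2 = np.zeros(n)
    c_running = 0.0
    c2_running = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j + 1) if event[k] == 1]
        d = len(d_idx)
        if d > 0:
            s0 = s0_suffix[i]
            s0d = w[d_idx].sum()
            fracs = np.zeros(d) if ties == "breslow" else np.arange(d) / d
            phi = s0 - fracs * s0d
            loglik += eta[d_idx].sum() - np.log(phi).sum()
            c_running += np.sum(1.0 / phi)
            c2_running += np.sum(1.0 / phi**2)
            bk = np.sum(fracs / phi)
            b2k = np.sum((2.0 * fracs - fracs**2) / phi**2)
            for k in d_idx:
                own_b[k] = bk
                own_b2[k] = b2k
        cum_c[i : j + 1] = c_running
        cum_c2[i : j + 1] = c2_running
        i = j + 1
    ev = event.astype(float)
    a1 = cum_c - ev * own_b        # sum of a/phi terms seen by each obs
    a2 = cum_c2 - ev * own_b2      # sum of a^2/phi^2 terms
    g = ev - w * a1
    h = w * a1 - (w**2) * a2
    h = np.clip(h, 0.0, None)
    return float(loglik), g, h


def _soft_threshold(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def _cd_fit(time, event, Xs, lam, beta0, ties="efron", max_outer=50, tol=1e-7):
    """Penalized fit at one lambda on standardized covariates.

    Outer loop: quadratic approximation of the partial likelihood at the
    current beta (diagonal weights); inner loop: cyclic coordinate descent
    on the penalized weighted least squares.
    """
    n, p = Xs.shape
    beta = beta0.copy()
    converged = False
    for _ in range(max_outer):
        eta = Xs @ beta
        _, g, h = _eta_derivatives(time, event, eta, ties)
        wgt = np.clip(h, 1e-6, None)
        z = eta + g / wgt
        denom = (wgt[:, None] * Xs**2).sum(axis=0) / n
        beta_old_outer = beta.copy()
        r = z - eta  # working residual
        for _ in range(200):
            max_delta = 0.0
            for j in range(p):
                bj = beta[j]
                zj = np.sum(wgt * Xs[:, j] * r) / n + denom[j] * bj
                bj_new = _soft_threshold(zj, lam) / denom[j]
                if bj_new != bj:
                    r -= (bj_new - bj) * Xs[:, j]
                    max_delta = max(max_delta, abs(bj_new - bj))
                    beta[j] = bj_new
            if max_delta < tol:
                break
        if np.max(np.abs(beta - beta_old_outer)) < 10 * tol:
            converged = True
            break
    return beta, converged


def cv_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold assignment: a pure function of (seed, n)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[perm] = np.arange(n) % n_folds
    return fold


def lasso_cox(
    data: pd.DataFrame,
    covariates: list[str],
    n_folds: int = 10,
    seed: int = 0,
    time_col: str = "time",
    event_col: str = "event",
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    selection: str = "lambda.min",
    ties: str = "efron",
) -> LassoCoxPath:
    """L1-penalized Cox regression over a lambda path with k-fold CV.

    The penalized objective is -(1/n) l(beta) + lambda * ||beta||_1 on
    internally standardized covariates; returned coefficients are on the
    original scale.  lambda_max is the smallest lambda with an all-zero
    solution and the grid descends ``-log10(lambda_min_ratio)`` decades
    from it.  CV deviance is the Verweij-van Houwelingen cross-validated
    partial-likelihood deviance; selection is ``"lambda.min"`` (default)
    or ``"lambda.1se"``.
    """
    if len(covariates) < 2:
        raise ValueError("LASSO needs at least 2 covariates")
    t, e = _check_surv(data[time_col].to_numpy(), data[event_col].to_numpy())
    if e.sum() < n_folds:
        raise ValueError("need at least as many events as CV folds")
    X = data[covariates].to_numpy(dtype=float)
    t, e, X, order = _sort_for_cox(t, e, X)
    n, p = X.shape

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [covariates[j] for j in range(p) if sd[j] == 0]
        raise ValueError(f"constant covariates: {bad}")
    Xs = (X - mean) / sd

    _, g0, _ = _eta_derivatives(t, e, np.zeros(n), ties)
    lam_max = float(np.max(np.abs(Xs.T @ g0)) / n) * (1.0 + 1e-6)
    if lam_max <= 0:
        lam_max = 1e-3
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)

    notes: list[str] = []
    all_ok = True

    def _path(ti, ev, Xmat):
        coefs = np.zeros((n_lambda, p))
        beta = np.zeros(p)
        ok = True
        for li, lam in enumerate(lambdas):
            beta, conv = _cd_fit(ti, ev, Xmat, lam, beta, ties)
            ok = ok and conv
            coefs[li] = beta
        return coefs, ok

    full_coefs, full_ok = _path(t, e, Xs)
    all_ok = all_ok and full_ok

    folds = cv_folds(n, n_folds, seed)
    dev_fold = np.zeros((n_folds, n_lambda))
    for f in range(n_folds):
        keep = folds != f
        tf, ef, Xf = t[keep], e[keep], Xs[keep]
        if ef.sum() == 0:
            notes.append(f"fold {f} had no events; skipped")
            continue
        coefs_f, ok_f = _path(tf, ef, Xf)
        all_ok = all_ok and ok_f
        for li in range(n_lambda):
            b = coefs_f[li]
            ll_full, _, _ = _eta_derivatives(t, e, Xs @ b, ties)
            ll_train, _, _ = _eta_derivatives(tf, ef, Xf @ b, ties)
            dev_fold[f, li] = -2.0 * (ll_full - ll_train)
    cv_dev = dev_fold.mean(axis=0)
    cv_se = dev_fold.std(axis=0, ddof=1) / np.sqrt(n_folds)

    idx_min = int(np.argmin(cv_dev))
    if selection == "lambda.1se":
        bound = cv_dev[idx_min] + cv_se[idx_min]
        candidates = np.where(cv_dev <= bound)[0]
        idx_sel = int(candidates.min())  # largest lambda within 1 SE
        rule = "lambda.1se"
    else:
        idx_sel = idx_min
        rule = "lambda.min"

    coefs_orig = full_coefs / sd[None, :]
    return LassoCoxPath(
        covariates=list(covariates),
        lambdas=lambdas,
        coefs=coefs_orig,
        cv_deviance=cv_dev,
        cv_se=cv_se,
        selected_lambda=float(lambdas[idx_sel]),
        selected_index=idx_sel,
        selection_rule=rule,
        converged=all_ok,
        notes=notes,
    )
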