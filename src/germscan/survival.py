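"""Survival-analysis kernel: Kaplan-Meier, Cox partial likelihood, Lasso
covariate selection, BH FDR, the scan-wide significance level, and analytic
Cox power.

The Cox fitter is a Newton-Raphson maximizer of the partial likelihood written
directly in numpy so that genome-scale scans (one fit per variant per cancer)
stay fast.  Tie handling follows the Efron approximation by default; with no
tied event times a fully vectorized cumulative-sum path is used (Breslow and
Efron coincide there).  Estimates are cross-checked against lifelines in the
test suite.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CoxResult

__all__ = [
    "km_estimate",
    "cox_fit",
    "cox_score_test",
    "cox_partial_loglik",
    "lasso_select_covariates",
    "bh_fdr",
    "scan_alpha",
    "cox_power",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.Series:
    """Product-limit survival estimate, returned as a right-continuous step
    function: S(t) indexed by the distinct event times, with S(0) = 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    return s


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery


def _prep(times, events, X):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(times) != len(events) or len(times) != X.shape[0]:
        raise ValueError("times, events and design matrix must have equal length")
    if events.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("design matrix contains a constant column")
    return times, events, X


def _loglik_grad_hess_noties(beta, times, events, X, order):
    """Tie-free path: risk-set sums via reverse cumulative sums.

    ``order`` sorts ascending by time with events preceding censored entries
    at equal times, so the suffix starting at an event row is exactly its
    risk set.
    """
    t = times[order]
    e = events[order]
    x = X[order]
    eta = x @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    n, k = x.shape
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    xxt = x[:, :, None] * x[:, None, :]
    S2 = np.cumsum((w[:, None, None] * xxt)[::-1], axis=0)[::-1]
    ev = e.astype(bool)
    mean = S1[ev] / S0[ev, None]
    loglik = float(np.sum(eta[ev] - np.log(S0[ev])))
    grad = np.sum(x[ev] - mean, axis=0)
    hess = -np.sum(
        S2[ev] / S0[ev, None, None] - mean[:, :, None] * mean[:, None, :], axis=0
    )
    return loglik, grad, hess


def _loglik_grad_hess_efron(beta, times, events, X):
    """General path with Efron's correction for tied event times."""
    eta = np.clip(X @ beta, -200, 200)
    w = np.exp(eta)
    k = X.shape[1]
    loglik = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        wr, wd = w[risk], w[dead]
        S0r, S0d = wr.sum(), wd.sum()
        S1r = wr @ X[risk]
        S1d = wd @ X[dead]
        S2r = (wr[:, None] * X[risk]).T @ X[risk]
        S2d = (wd[:, None] * X[dead]).T @ X[dead]
        loglik += float(eta[dead].sum())
        for l in range(d):
            f = l / d
            phi = S0r - f * S0d
            z = S1r - f * S1d
            q = S2r - f * S2d
            loglik -= np.log(phi)
            grad += -z / phi
            hess -= q / phi - np.outer(z, z) / phi**2
        grad += X[dead].sum(axis=0)
    return loglik, grad, hess


def _has_tied_events(times, events):
    et = times[events == 1]
    return len(et) != len(np.unique(et))


def cox_fit(
    X,
    times,
    events,
    terms: Sequence[str] | None = None,
    ties: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxResult:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Parameters
    ----------
    X : (n, k) array or DataFrame
        Covariate design matrix (no intercept; Cox absorbs the baseline).
    ties : "efron" or "breslow"
        Tie approximation.  With no tied event times the two coincide and a
        vectorized path is used.
    """
    if isinstance(X, pd.DataFrame):
        if terms is None:
            terms = list(X.columns)
        X = X.to_numpy(dtype=float)
    times, events, X = _prep(times, events, X)
    n, k = X.shape
    if terms is None:
        terms = [f"x{i}" for i in range(k)]
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")

    tied = _has_tied_events(times, events)
    order = np.lexsort((-events, times))  # events before censored at equal times
    use_fast = not tied  # Breslow == Efron without ties

    def evaluate(beta):
        if use_fast:
            return _loglik_grad_hess_noties(beta, times, events, X, order)
        if ties == "efron":
            return _loglik_grad_hess_efron(beta, times, events, X)
        # Breslow with ties: Efron machinery with the within-tie fraction off
        return _breslow_tied(beta, times, events, X)

    beta = np.zeros(k)
    loglik, grad, hess = evaluate(beta)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # step-halving line search on the partial likelihood; the acceptance
        # slack is relative to |loglik| to stay above floating-point noise
        slack = 1e-9 * (abs(loglik) + 1.0)
        scale = 1.0
        for _ in range(30):
            new = beta + scale * step
            ll_new, g_new, h_new = evaluate(new)
            if np.isfinite(ll_new) and ll_new >= loglik - slack:
                break
            scale *= 0.5
        else:  # pragma: no cover - pathological
            break
        beta, loglik, grad, hess = new, ll_new, g_new, h_new
    if np.max(np.abs(beta)) > 50:
        converged = False  # monotone likelihood / separation
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(k, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxResult(
        terms=list(terms),
        log_hr=beta,
        se=se,
        p=p,
        n=n,
        n_events=int(events.sum()),
        converged=bool(converged),
    )


def _breslow_tied(beta, times, events, X):
    eta = np.clip(X @ beta, -200, 200)
    w = np.exp(eta)
    k = X.shape[1]
    loglik, grad, hess = 0.0, np.zeros(k), np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        wr = w[risk]
        S0 = wr.sum()
        S1 = wr @ X[risk]
        S2 = (wr[:, None] * X[risk]).T @ X[risk]
        loglik += float(eta[dead].sum()) - d * np.log(S0)
        grad += X[dead].sum(axis=0) - d * S1 / S0
        hess -= d * (S2 / S0 - np.outer(S1 / S0, S1 / S0))
    return loglik, grad, hess


def cox_score_test(x, times, events) -> tuple[float, float]:
    """Score (Rao) test of a single-covariate Cox model at beta = 0.

    For one binary covariate with no tied event times this statistic equals
    the log-rank chi-square.
    """
    times, events, X = _prep(times, events, np.asarray(x, dtype=float))
    if _has_tied_events(times, events):
        _, grad, hess = _loglik_grad_hess_efron(np.zeros(X.shape[1]), times, events, X)
    else:
        order = np.lexsort((-events, times))
        _, grad, hess = _loglik_grad_hess_noties(
            np.zeros(X.shape[1]), times, events, X, order
        )
    info = -hess
    chi2 = float(grad @ np.linalg.solve(info, grad))
    p = float(stats.chi2.sf(chi2, df=X.shape[1]))
    return chi2, p


def cox_partial_loglik(X, beta, times, events) -> float:
    """Breslow partial log-likelihood of ``beta`` on held-out data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.asarray(beta, dtype=float)
    if _has_tied_events(times, events):
        ll, _, _ = _breslow_tied(beta, times, events, X)
        return float(ll)
    order = np.lexsort((-events, times))
    ll, _, _ = _loglik_grad_hess_noties(beta, times, events, X, order)
    return float(ll)


# ---------------------------------------------------------------------------
# Lasso covariate selection


def lasso_select_covariates(
    candidates: pd.DataFrame,
    times,
    events,
    cv_folds: int = 5,
    seed: int = 0,
    alphas: Sequence[float] | None = None,
) -> list[str]:
    """Clinical-covariate selection by L1-penalized Cox regression.

    Fits the Lasso-Cox path (100 log-spaced penalties by default), picks the
    penalty minimizing the cross-validated partial-likelihood deviance, and
    returns the covariates with nonzero coefficients there.  An empty list is
    a valid outcome (no covariate carries signal).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv
    from sklearn.model_selection import KFold

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cols = [c for c in candidates.columns if candidates[c].nunique() > 1]
    if not cols:
        return []
    Xdf = candidates[cols]
    X = Xdf.to_numpy(dtype=float)
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=100, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    if alphas is not None:
        path.set_params(alphas=list(alphas))
    path.fit(X, y)
    grid = np.asarray(path.alphas_)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    deviance = np.zeros((cv_folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(X)):
        if events[tr].sum() == 0 or events[te].sum() == 0:
            deviance[f] = np.nan
            continue
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(grid), fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # all-zero path ends are fine
            model.fit(X[tr], y[tr])
        coefs = model.coef_  # (k, n_alphas) on the fitted grid
        fitted = np.asarray(model.alphas_)
        for j, a in enumerate(grid):
            jj = int(np.argmin(np.abs(fitted - a)))
            beta = coefs[:, jj]
            deviance[f, j] = -2.0 * cox_partial_loglik(X[te], beta, times[te], events[te])
    mean_dev = np.nanmean(deviance, axis=0)
    best = int(np.nanargmin(mean_dev))
    coef = path.coef_[:, best]
    return [c for c, b in zip(cols, coef) if b != 0.0]


# ---------------------------------------------------------------------------
# Multiple testing and power


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def scan_alpha(n_tested: int) -> float:
    """Scan-wide significance level: 0.10 divided by the number of variants
    tested in that cancer (comparable stringency to BH at FDR 0.10)."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    return 0.10 / n_tested


def cox_power(
    n: int,
    event_rate: float,
    exposed_fraction: float,
    hr: float,
    alpha: float,
    r2_other_covariates: float = 0.0,
) -> float:
    """Analytic power of a two-sided Wald test for one binary exposure in a
    Cox model (Schoenfeld events formula with variance inflation).

    power = Phi( |ln hr| * sqrt(D * p * (1-p) * (1 - R^2)) - z_{1-alpha/2} ),
    with D = n * event_rate expected events and p the exposed fraction.
    """
    if not 0.0 <= event_rate <= 1.0 or not 0.0 < exposed_fraction < 1.0:
        raise ValueError("event_rate in [0,1] and exposed_fraction in (0,1) required")
    if not 0.0 < alpha < 1.0 or not 0.0 <= r2_other_covariates < 1.0:
        raise ValueError("alpha in (0,1) and r2 in [0,1) required")
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    d = n * event_rate
    z = stats.norm.ppf(1 - alpha / 2)
    effect = abs(np.log(hr)) * np.sqrt(
        d * exposed_fraction * (1 - exposed_fraction) * (1 - r2_other_covariates)
    )
    return float(stats.norm.cdf(effect - z))
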