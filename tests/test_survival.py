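"""Kernel checks: KM, Cox fitting, Lasso selection, BH, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from germscan.survival import (
    bh_fdr,
    cox_fit,
    cox_power,
    cox_score_test,
    km_estimate,
    lasso_select_covariates,
    scan_alpha,
)
from germscan.survival import _loglik_grad_hess_noties

from conftest import make_survival_data


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_events_is_flat():
    s = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert (s.to_numpy() == 1.0).all()


def test_km_closed_form_all_events():
    s = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(s.loc[[1.0, 2.0, 3.0]], [2 / 3, 1 / 3, 0.0])


def test_km_matches_product_limit_oracle(rng):
    """KM equals the brute-force product over risk sets at event times."""
    for _ in range(20):
        n = rng.integers(5, 40)
        t = np.round(rng.exponential(size=n), 1)  # ties on purpose
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            continue
        s = km_estimate(t, e)
        for tq in np.unique(t[e == 1]):
            prod = 1.0
            for ti in np.unique(t[e == 1]):
                if ti <= tq:
                    d = ((t == ti) & (e == 1)).sum()
                    at_risk = (t >= ti).sum()
                    prod *= 1 - d / at_risk
            np.testing.assert_allclose(s.loc[tq], prod, atol=1e-12)


# ---------------------------------------------------------------------------
# Cox partial likelihood


@pytest.mark.parametrize("seed,ties", [(0, False), (1, False), (2, True)])
def test_cox_matches_lifelines(seed, ties):
    from lifelines import CoxPHFitter

    X, t, e = make_survival_data(n=250, beta=[0.6, -0.3], seed=seed)
    if ties:
        t = np.round(t, 1) + 0.01  # heavy ties, keep > 0
    res = cox_fit(X, t, e)
    df = X.copy()
    df["T"], df["E"] = t, e
    cph = CoxPHFitter().fit(df, "T", "E")
    # agreement is limited by lifelines' own stopping rule (~1e-5 on beta)
    np.testing.assert_allclose(res.log_hr, cph.params_.to_numpy(), atol=1e-4)
    np.testing.assert_allclose(res.se, cph.standard_errors_.to_numpy(), atol=1e-4)
    assert res.converged


def test_cox_gradient_vanishes_at_solution():
    X, t, e = make_survival_data(n=300, beta=[0.5, 0.0], seed=5)
    res = cox_fit(X, t, e)
    order = np.lexsort((-e, t))
    _, grad, _ = _loglik_grad_hess_noties(res.log_hr, t, e, X.to_numpy(), order)
    assert np.max(np.abs(grad)) < 1e-6


def test_cox_score_equals_logrank_for_binary_covariate():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(7)
    n = 200
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(np.where(x == 1, 0.6, 1.0))
    e = (rng.random(n) < 0.8).astype(int)
    chi2, _ = cox_score_test(x, t, e)
    lr = logrank_test(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
    assert abs(chi2 - lr.test_statistic) / lr.test_statistic < 1e-6


def test_cox_null_p_uniform():
    """Wald p of an effect-free covariate is ~Uniform(0,1)."""
    ps = []
    for seed in range(200):
        X, t, e = make_survival_data(n=120, beta=[0.0], seed=seed, k_covariates=1)
        ps.append(cox_fit(X, t, e).p[0])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_cox_recovers_planted_loghr():
    X, t, e = make_survival_data(n=1000, beta=[np.log(2), 0.0], seed=11)
    res = cox_fit(X, t, e)
    assert abs(res.log_hr[0] - np.log(2)) < 3 * res.se[0]


def test_cox_rejects_degenerate_inputs():
    X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError):
        cox_fit(X, [1, 2, 3], [1, 0, 1])  # constant column
    with pytest.raises(ValueError):
        cox_fit(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), [1, 2, 3], [0, 0, 0])  # no events


# ---------------------------------------------------------------------------
# Lasso covariate selection


def test_lasso_selects_signal_drops_noise():
    hits, noise_counts = 0, []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 800
        X = pd.DataFrame(
            rng.normal(size=(n, 10)), columns=["signal"] + [f"n{i}" for i in range(9)]
        )
        eta = np.log(3) * X["signal"].to_numpy()
        T = np.exp(-eta) * rng.exponential(size=n)
        C = rng.uniform(0, np.quantile(T, 0.8) * 2, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        sel = lasso_select_covariates(X, t, e, seed=seed)
        hits += "signal" in sel
        noise_counts.append(len([s for s in sel if s != "signal"]))
    assert hits == 5
    assert np.mean(noise_counts) <= 3


def test_lasso_infinite_penalty_selects_nothing():
    X, t, e = make_survival_data(n=200, beta=[0.5, 0.5], seed=0)
    assert lasso_select_covariates(X, t, e, alphas=[1e6]) == []


# ---------------------------------------------------------------------------
# BH FDR


def _bh_bruteforce(p):
    """min over j >= i of m * p_(j) / j, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj[order[rank - 1]] = min(running, 1.0)
    return adj


def test_bh_hand_example_and_single():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_fdr([0.37]), [0.37])


def test_bh_matches_bruteforce_oracle(rng):
    for _ in range(100):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), _bh_bruteforce(p), atol=1e-12)


def test_bh_monotone_in_sorted_order(rng):
    p = rng.random(50)
    adj = bh_fdr(p)
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-15).all()
    assert (adj >= p).all() and (adj <= 1.0).all()


# ---------------------------------------------------------------------------
# Scan alpha and power


def test_scan_alpha():
    assert scan_alpha(10) == pytest.approx(0.01)
    assert scan_alpha(1) == pytest.approx(0.10)
    with pytest.raises(ValueError):
        scan_alpha(0)


def test_power_null_effect_is_alpha_tail():
    z = stats.norm.ppf(1 - 0.05 / 2)
    assert cox_power(500, 0.5, 0.2, hr=1.0, alpha=0.05) == pytest.approx(
        stats.norm.cdf(-z)
    )


def test_power_monotonicity_and_symmetry():
    base = dict(event_rate=0.5, exposed_fraction=0.2, alpha=0.05)
    assert cox_power(500, hr=3, **base) > cox_power(500, hr=2, **base)
    assert cox_power(1000, hr=2, **base) > cox_power(500, hr=2, **base)
    assert cox_power(500, hr=2, **base) == pytest.approx(cox_power(500, hr=0.5, **base))


def test_power_rejects_invalid_fractions():
    with pytest.raises(ValueError):
        cox_power(100, 1.2, 0.2, 2, 0.05)
    with pytest.raises(ValueError):
        cox_power(100, 0.5, 0.0, 2, 0.05)
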