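"""Shared fixtures: small synthetic cohorts with planted effects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germscan.datatypes import EffectPlan, GenotypeMatrix, SourceCallSet
from germscan import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_survival_data(n=200, beta=None, seed=0, censoring=0.3, k_covariates=2):
    """Simple Weibull-PH survival data with known coefficients.

    Returns (X DataFrame, times, events).  Continuous event times (no ties).
    """
    rng = np.random.default_rng(seed)
    names = [f"c{i}" for i in range(k_covariates)]
    X = pd.DataFrame(rng.normal(size=(n, k_covariates)), columns=names)
    if beta is None:
        beta = np.zeros(k_covariates)
    eta = X.to_numpy() @ np.asarray(beta, dtype=float)
    T = np.exp(-eta) * rng.exponential(size=n)
    if censoring > 0:
        C = rng.uniform(0, np.quantile(T, 1 - censoring) * 2.2, size=n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
    else:
        t, e = T, np.ones(n, dtype=int)
    return X, t, e


@pytest.fixture
def survival_data():
    return make_survival_data(n=250, beta=[0.5, -0.4], seed=3)


def toy_callsets(values: np.ndarray, depth: int = 30):
    """Wrap one genotype matrix as three identical call sets."""
    n, m = values.shape
    gm = GenotypeMatrix(
        values.astype(np.int8),
        pd.Index([f"P{i}" for i in range(n)]),
        pd.Index([f"v{j}" for j in range(m)]),
    )
    d = np.full(values.shape, depth)
    return {
        s: SourceCallSet(s, gm.copy(), d.copy())
        for s in ("WXS_NORMAL", "WXS_TUMOR", "RNA_TUMOR")
    }


def planted_cohort(
    n=400,
    n_variants=50,
    cancer_codes=("X",),
    variant_effects=None,
    covariate_effects=None,
    censoring=0.3,
    seed=0,
    af_range=(0.1, 0.5),
):
    """One-call helper: variants, genotypes, cohort with outcomes, plan."""
    variants = syn.generate_variants(n_variants, af_range=af_range, seed=seed)
    cohort = syn.generate_baseline_cohort(
        n,
        list(cancer_codes),
        {"age": {"dist": "normal", "mean": 0, "sd": 1}},
        seed=seed,
    )
    plan = EffectPlan(
        variant_effects=variant_effects or {},
        covariate_effects=covariate_effects or {"age": 0.3},
        censoring_rate=censoring,
    )
    genotypes = syn.generate_genotypes(variants, n, seed=seed)
    cohort = syn.simulate_outcomes(cohort, genotypes, plan, seed=seed)
    return variants, genotypes, cohort, plan
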