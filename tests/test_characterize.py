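"""Characterization statistics: concordance index, HR correlations,
minor-allele enrichment, LD pruning, region calls, pair independence,
driver associations."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from germscan.datatypes import UNKNOWN, GenotypeMatrix
from germscan.characterize import (
    classify_region,
    direction_index_stats,
    driver_association_scan,
    effect_size_af_correlation,
    hr_pair_correlation,
    ld_prune,
    minor_allele_risk_test,
    pair_hr_table,
    pair_independence_test,
    partial_spearman,
)


def _results(rows):
    return pd.DataFrame(rows, columns=["variant_id", "stratum", "log_hr", "p"])


# ---------------------------------------------------------------------------
# Direction-concordance index


def test_index_perfect_concordance_is_one():
    res = _results([("v", f"c{i}", 0.4, 0.01) for i in range(5)])
    indices, expected, _ = direction_index_stats(res)
    assert len(indices) == 1
    assert indices[0].index == 1.0
    assert expected == 1.0


def test_index_formula_two_one():
    res = _results(
        [("v", "c0", 0.4, 0.01), ("v", "c1", 0.4, 0.01), ("v", "c2", -0.4, 0.01)]
    )
    indices, _, _ = direction_index_stats(res)
    assert indices[0].index == pytest.approx(2 / 3)
    assert indices[0].n_poor == 2 and indices[0].n_favorable == 1


def test_index_bounds_property():
    rng = np.random.default_rng(0)
    rows = []
    for v in range(30):
        for c in range(rng.integers(3, 8)):
            rows.append((f"v{v}", f"c{c}", rng.normal(), 0.01))
    indices, expected, _ = direction_index_stats(_results(rows))
    for d in indices:
        assert 0.5 <= d.index <= 1.0
        assert (d.index == 1.0) == (d.n_poor == 0 or d.n_favorable == 0)
    assert 0.5 <= expected <= 1.0


def test_index_random_direction_expectation_enumeration():
    """Under 50/50 directions with k=3 per variant, E[index] = 0.75 exactly
    (binomial enumeration); a large simulation through the real code path
    must agree to ~3 decimals."""
    exact = sum(
        comb(3, x) * 0.5**3 * max(x, 3 - x) / 3 for x in range(4)
    )
    assert exact == pytest.approx(0.75)
    rng = np.random.default_rng(1)
    rows = []
    for v in range(50_000):
        for c in range(3):
            rows.append((f"v{v}", f"c{c}", 1.0 if rng.random() < 0.5 else -1.0, 0.01))
    indices, _, _ = direction_index_stats(_results(rows))
    assert np.mean([d.index for d in indices]) == pytest.approx(exact, abs=5e-3)


# ---------------------------------------------------------------------------
# HR correlations


def test_hr_pairs_identical_within_variant_rho_one():
    rows = []
    for v, hr in enumerate([1.5, 2.5, 4.0]):
        for c in range(3):
            rows.append((f"v{v}", f"c{c}", np.log(hr), 0.01))
    rho, _ = hr_pair_correlation(_results(rows), direction="poor")
    assert rho == pytest.approx(1.0)


def test_partial_spearman_matches_residual_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        z = rng.normal(size=40)
        x = z + rng.normal(size=40)
        y = -z + rng.normal(size=40)
        got = partial_spearman(x, y, z)
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        ex = rx - np.polyval(np.polyfit(rz, rx, 1), rz)
        ey = ry - np.polyval(np.polyfit(rz, ry, 1), rz)
        oracle = np.corrcoef(ex, ey)[0, 1]
        assert got == pytest.approx(oracle, abs=1e-10)


def test_hr_pairs_independent_hrs_rho_near_zero():
    rng = np.random.default_rng(3)
    rhos = []
    for rep in range(40):
        rows = []
        for v in range(25):
            for c in range(3):
                rows.append((f"v{v}", f"c{c}", abs(rng.normal(0.5, 0.2)), 0.01))
        rho, _ = hr_pair_correlation(_results(rows), direction="poor")
        rhos.append(rho)
    se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
    assert abs(np.mean(rhos)) < 4 * se + 0.05


# ---------------------------------------------------------------------------
# Minor-allele enrichment and effect-size/AF correlation


def test_minor_allele_fisher_closed_form():
    hits = pd.DataFrame(
        {
            "population_af": [0.1] * 10 + [0.9] * 10,
            "log_hr": [0.5] * 10 + [-0.5] * 10,
        }
    )
    p, table = minor_allele_risk_test(hits)
    assert np.array_equal(table, [[10, 0], [0, 10]])
    assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)


def test_minor_allele_degenerate_margin():
    hits = pd.DataFrame({"population_af": [0.1, 0.2], "log_hr": [0.5, -0.5]})
    p, _ = minor_allele_risk_test(hits)  # all minor: no contrast
    assert p == 1.0


def test_effect_size_af_inverse_construction():
    afs = np.linspace(0.05, 0.5, 10)
    hits = pd.DataFrame({"population_af": afs, "log_hr": 1.0 / np.arange(1, 11)})
    rho, _ = effect_size_af_correlation(hits)
    assert rho == pytest.approx(-1.0)
    const = pd.DataFrame({"population_af": [0.2] * 5, "log_hr": np.arange(1.0, 6.0)})
    rho_c, p_c = effect_size_af_correlation(const)
    assert np.isnan(rho_c) and np.isnan(p_c)


# ---------------------------------------------------------------------------
# LD pruning


def _gm(columns: dict[str, np.ndarray]):
    names = list(columns)
    values = np.column_stack([columns[c] for c in names]).astype(np.int8)
    return GenotypeMatrix(
        values, pd.Index([f"P{i}" for i in range(values.shape[0])]), pd.Index(names)
    )


def test_ld_prune_keeps_first_by_position():
    rng = np.random.default_rng(4)
    shared = rng.choice([0, 1, 2], size=80)
    other = rng.choice([0, 1, 2], size=80)
    gm = _gm({"vA": shared, "vB": shared, "vC": other})
    ann = pd.DataFrame(
        {"chrom": ["1"] * 3, "pos": [200, 100, 300]}, index=["vA", "vB", "vC"]
    )
    kept = ld_prune(["vA", "vB", "vC"], gm, ann)
    assert kept == ["vB", "vC"]  # vB at pos 100 wins the linked pair
    # order independence
    assert ld_prune(["vC", "vB", "vA"], gm, ann) == kept


def test_ld_prune_three_way_cluster_single_survivor():
    rng = np.random.default_rng(5)
    shared = rng.choice([0, 1, 2], size=60)
    gm = _gm({"v1": shared, "v2": shared, "v3": shared})
    ann = pd.DataFrame({"chrom": ["1"] * 3, "pos": [30, 10, 20]}, index=["v1", "v2", "v3"])
    assert ld_prune(["v1", "v2", "v3"], gm, ann) == ["v2"]


def test_ld_prune_identity_when_unlinked():
    rng = np.random.default_rng(6)
    gm = _gm({f"v{i}": rng.choice([0, 1, 2], size=100) for i in range(4)})
    ann = pd.DataFrame(
        {"chrom": ["1"] * 4, "pos": [10, 20, 30, 40]}, index=[f"v{i}" for i in range(4)]
    )
    assert ld_prune([f"v{i}" for i in range(4)], gm, ann) == [f"v{i}" for i in range(4)]


# ---------------------------------------------------------------------------
# Region classification


@pytest.fixture
def transcripts():
    # + strand gene: tx 1000-2000, CDS 1200-1800, exons [1000-1400, 1600-2000]
    # - strand gene on same chrom further away
    return pd.DataFrame(
        [
            {
                "transcript_id": "tA", "chrom": "1", "strand": "+",
                "tx_start": 1000, "tx_end": 2000, "cds_start": 1200, "cds_end": 1800,
                "exon_starts": [1000, 1600], "exon_ends": [1400, 2000],
            },
            {
                "transcript_id": "tB", "chrom": "1", "strand": "+",
                "tx_start": 1300, "tx_end": 1550, "cds_start": 1300, "cds_end": 1550,
                "exon_starts": [1300], "exon_ends": [1550],
            },
        ]
    )


def test_region_exonic_intronic_utr(transcripts):
    assert "exonic" in classify_region("1", 1250, transcripts)
    # 1100: 5'UTR of tA (exonic, before CDS) and inside tB's upstream window
    assert classify_region("1", 1100, transcripts) == {"5'UTR", "upstream"}
    assert "3'UTR" in classify_region("1", 1900, transcripts)


def test_region_upstream_window(transcripts):
    assert classify_region("1", 500, transcripts) == {"upstream"}
    assert classify_region("1", 2400, transcripts) == {"downstream"}
    assert classify_region("2", 1250, transcripts) == {"intergenic"}


def test_region_multi_transcript_multiple_labels(transcripts):
    # 1450: intronic for tA (between exons), exonic for tB
    labels = classify_region("1", 1450, transcripts)
    assert labels == {"intronic", "exonic"}


# ---------------------------------------------------------------------------
# Pair independence


def _pair_cohort(beta2, n=600, seed=0):
    rng = np.random.default_rng(seed)
    d1 = rng.choice([0, 1], size=n, p=[0.6, 0.4])
    d2 = rng.choice([0, 1], size=n, p=[0.6, 0.4])
    eta = np.log(2) * d1 + beta2 * d2
    T = np.exp(-eta) * rng.exponential(size=n)
    gm = _gm({"vP": d1, "vQ": d2})
    cohort = pd.DataFrame(
        {"time": T, "event": 1}, index=gm.patients
    )
    return gm, cohort


def test_pair_table_multiplicative_hazards():
    gm, cohort = _pair_cohort(beta2=np.log(2), n=4000, seed=7)
    table = pair_hr_table(["vP", "vQ"], gm, cohort)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["hr_2v1"] == pytest.approx(2.0, rel=0.2)
    assert row["hr_3v1"] == pytest.approx(4.0, rel=0.25)


def test_pair_second_variant_null_no_boost():
    # group 3 (het for both) carries only the first variant's hazard, so its
    # HR stays at ~2 instead of the ~4 seen when both variants act
    gm, cohort = _pair_cohort(beta2=0.0, n=4000, seed=8)
    row = pair_hr_table(["vP", "vQ"], gm, cohort).iloc[0]
    assert row["hr_3v1"] == pytest.approx(2.0, rel=0.2)
    # group 2 mixes carriers of the active and the inert variant: HR in (1, 2)
    assert 1.0 < row["hr_2v1"] < 2.0


def test_pair_skipped_when_group_empty():
    gm = _gm({"vP": np.array([0, 1, 0, 1]), "vQ": np.zeros(4, dtype=int)})
    cohort = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": 1}, index=gm.patients)
    assert pair_hr_table(["vP", "vQ"], gm, cohort).empty


def test_pair_independence_signed_rank_direction():
    rng = np.random.default_rng(9)
    table = pd.DataFrame(
        {"hr_2v1": 2 + rng.normal(0, 0.1, 25), "hr_3v1": 4 + rng.normal(0, 0.1, 25)}
    )
    assert pair_independence_test(table) < 0.001
    flipped = table.rename(columns={"hr_2v1": "hr_3v1", "hr_3v1": "hr_2v1"})
    assert pair_independence_test(flipped) > 0.9


# ---------------------------------------------------------------------------
# Driver associations


def test_driver_fisher_matches_hypergeometric_tail():
    rng = np.random.default_rng(10)
    gm = _gm({"v": rng.choice([0, 1], size=100, p=[0.6, 0.4])})
    drivers = pd.DataFrame(
        {"d": rng.choice([0, 1], size=100, p=[0.8, 0.2])}, index=gm.patients
    )
    out = driver_association_scan(gm, drivers, prognostic_ids=["v"], tested_ids=["v"])
    carrier = gm.dosage("v") >= 1
    mut = drivers["d"].to_numpy(dtype=bool)
    a = int((carrier & mut).sum())
    # one-sided Fisher = hypergeometric upper tail by direct summation
    M, K, N = 100, int(mut.sum()), int(carrier.sum())
    tail = sum(
        comb(K, x) * comb(M - K, N - x) / comb(M, N)
        for x in range(a, min(K, N) + 1)
    )
    assert out["pairs"]["p"].iloc[0] == pytest.approx(tail, abs=1e-12)


def test_driver_min_mutated_exclusion():
    gm = _gm({"v": np.tile([0, 1], 50)})
    drivers = pd.DataFrame(
        {"rare": [1] * 4 + [0] * 96, "common": [1] * 10 + [0] * 90},
        index=gm.patients,
    )
    out = driver_association_scan(gm, drivers, ["v"], ["v"], min_mutated=5)
    assert set(out["pairs"]["driver_gene"]) == {"common"}
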