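"""Merge precedence, depth masking, concordance, cohort AF and the three
discovery filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from germscan.datatypes import UNKNOWN, GenotypeMatrix, QcThresholds, SourceCallSet
from germscan.mergeqc import (
    cohort_allele_frequency,
    concordance_percent,
    cross_source_af_correlation,
    mask_low_depth,
    merge_calls,
    qc_filter,
)

from conftest import toy_callsets


def _callset(source, values, depth=30):
    values = np.asarray(values, dtype=np.int8)
    gm = GenotypeMatrix(
        values,
        pd.Index([f"P{i}" for i in range(values.shape[0])]),
        pd.Index([f"v{j}" for j in range(values.shape[1])]),
    )
    d = np.broadcast_to(depth, values.shape).copy()
    return SourceCallSet(source, gm, d)


# ---------------------------------------------------------------------------
# Depth masking


def test_mask_low_depth_thresholds():
    cs = _callset("WXS_NORMAL", [[1, 2], [0, 1]], depth=np.array([[9, 10], [30, 30]]))
    masked = mask_low_depth(cs, min_depth=10)
    assert masked.genotypes.values[0, 0] == UNKNOWN  # 9 reads: masked
    assert masked.genotypes.values[0, 1] == 2  # exactly 10 reads: kept
    identity = mask_low_depth(cs, min_depth=0)
    assert np.array_equal(identity.genotypes.values, cs.genotypes.values)


# ---------------------------------------------------------------------------
# Merge precedence


def test_merge_precedence_and_provenance():
    normal = _callset("WXS_NORMAL", [[UNKNOWN, 0]])
    tumor = _callset("WXS_TUMOR", [[1, 2]])
    rna = _callset("RNA_TUMOR", [[2, 1]])
    merged = merge_calls(normal, tumor, rna)
    assert merged.genotypes.values[0, 0] == 1  # tumor wins over rna
    assert merged.source_provenance[0, 0] == "WXS_TUMOR"
    assert merged.genotypes.values[0, 1] == 0  # normal known: wins
    assert merged.source_provenance[0, 1] == "WXS_NORMAL"


def test_merge_all_unknown_stays_unknown():
    sets = [_callset(s, [[UNKNOWN]]) for s in ("WXS_NORMAL", "WXS_TUMOR", "RNA_TUMOR")]
    merged = merge_calls(*sets)
    assert merged.genotypes.values[0, 0] == UNKNOWN
    assert merged.source_provenance[0, 0] == "UNKNOWN"


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_merge_idempotent_and_normal_precedence(seed):
    rng = np.random.default_rng(seed)
    vals = [rng.choice([UNKNOWN, 0, 1, 2], size=(6, 4)) for _ in range(3)]
    sets = [
        _callset(s, v)
        for s, v in zip(("WXS_NORMAL", "WXS_TUMOR", "RNA_TUMOR"), vals)
    ]
    merged = merge_calls(*sets)
    # wherever normal is known, merged equals normal
    known = vals[0] != UNKNOWN
    assert np.array_equal(merged.genotypes.values[known], vals[0][known])
    # merging (merged, merged, merged) is the identity
    m = merged.genotypes.values
    again = merge_calls(
        _callset("WXS_NORMAL", m), _callset("WXS_TUMOR", m), _callset("RNA_TUMOR", m)
    )
    assert np.array_equal(again.genotypes.values, m)


# ---------------------------------------------------------------------------
# Concordance


def test_concordance_definition_arithmetic():
    # 20 patients, one variant; 18 agree across sources, 2 differ in RNA
    base = np.ones((20, 1), dtype=np.int8)
    rna = base.copy()
    rna[:2, 0] = 0
    conc = concordance_percent(
        _callset("WXS_NORMAL", base), _callset("WXS_TUMOR", base), _callset("RNA_TUMOR", rna)
    )
    assert conc.iloc[0] == pytest.approx(90.0)
    all_same = concordance_percent(
        _callset("WXS_NORMAL", base), _callset("WXS_TUMOR", base), _callset("RNA_TUMOR", base)
    )
    assert all_same.iloc[0] == pytest.approx(100.0)


def test_concordance_unknown_counts_as_discordant():
    base = np.ones((10, 1), dtype=np.int8)
    unknown = np.full((10, 1), UNKNOWN, dtype=np.int8)
    conc = concordance_percent(
        _callset("WXS_NORMAL", base),
        _callset("WXS_TUMOR", base),
        _callset("RNA_TUMOR", unknown),
    )
    assert conc.iloc[0] == 0.0


# ---------------------------------------------------------------------------
# Cohort AF


def test_cohort_af_examples():
    gm = GenotypeMatrix(
        np.array([[1, 0, UNKNOWN], [1, 0, UNKNOWN], [1, 1, UNKNOWN], [1, 2, UNKNOWN]], dtype=np.int8),
        pd.Index(list("abcd")),
        pd.Index(["all_het", "mixed", "missing"]),
    )
    af = cohort_allele_frequency(gm)
    assert af["all_het"] == pytest.approx(0.5)
    assert af["mixed"] == pytest.approx(3 / 8)
    assert np.isnan(af["missing"])


# ---------------------------------------------------------------------------
# QC filter


def _fixture_sixvariant():
    """6 variants x 30 patients, one cancer: v0 fails population AF, v1 fails
    carriers, v2 fails concordance, v3-v5 pass."""
    n = 30
    values = np.zeros((n, 6), dtype=np.int8)
    for j in [0, 2, 3, 4, 5]:
        values[:20, j] = 1  # 20 carriers
    values[:10, 1] = 1  # only 10 carriers: fails min_carriers=15
    sets = toy_callsets(values)
    # break concordance of v2 for 4/30 patients (86.7% <= 90)
    rna = sets["RNA_TUMOR"].genotypes.values
    rna[:4, 2] = 2
    merged = merge_calls(sets["WXS_NORMAL"], sets["WXS_TUMOR"], sets["RNA_TUMOR"])
    ann = pd.DataFrame(
        {"population_af": [0.04, 0.3, 0.3, 0.3, 0.3, 0.3]},
        index=merged.genotypes.variants,
    )
    cancer = pd.Series("X", index=merged.genotypes.patients)
    return merged, ann, cancer


def test_qc_filter_six_variant_fixture():
    merged, ann, cancer = _fixture_sixvariant()
    report = qc_filter(merged, ann, QcThresholds(), cancer)
    assert sorted(report.survivors["X"]) == ["v3", "v4", "v5"]
    assert report.exclusions["X"] == {
        "population_af": 1,
        "carriers": 1,
        "concordance": 1,
    }


def test_qc_filter_zero_thresholds_pass_everything():
    merged, ann, cancer = _fixture_sixvariant()
    report = qc_filter(
        merged,
        ann,
        QcThresholds(min_depth=0, min_population_af=0.0, min_carriers=0, min_concordance_pct=0.0),
        cancer,
    )
    assert len(report.survivors["X"]) == 6


def test_qc_filter_population_af_strictly_greater():
    merged, ann, cancer = _fixture_sixvariant()
    ann2 = ann.copy()
    ann2.loc["v3", "population_af"] = 0.05  # exactly at threshold: excluded
    report = qc_filter(merged, ann2, QcThresholds(), cancer)
    assert "v3" not in report.survivors["X"]


def test_qc_filter_monotone_in_thresholds():
    merged, ann, cancer = _fixture_sixvariant()
    loose = qc_filter(merged, ann, QcThresholds(min_carriers=5), cancer)
    tight = qc_filter(merged, ann, QcThresholds(min_carriers=25), cancer)
    assert len(tight.survivors["X"]) <= len(loose.survivors["X"])


# ---------------------------------------------------------------------------
# Cross-source AF correlation


def test_af_correlation_identical_sets_is_one():
    rng = np.random.default_rng(0)
    values = rng.choice([0, 1, 2], size=(40, 30), p=[0.5, 0.35, 0.15])
    sets = toy_callsets(values)
    merged = merge_calls(sets["WXS_NORMAL"], sets["WXS_TUMOR"], sets["RNA_TUMOR"])
    rho = cross_source_af_correlation(sets, merged)
    np.testing.assert_allclose(rho.to_numpy(), 1.0, atol=1e-12)


def test_af_correlation_matches_rank_pearson_oracle():
    rng = np.random.default_rng(1)
    values = rng.choice([0, 1, 2], size=(60, 50), p=[0.5, 0.35, 0.15])
    sets = toy_callsets(values)
    flip = rng.random((60, 50)) < 0.1
    sets["RNA_TUMOR"].genotypes.values[flip] = (
        sets["RNA_TUMOR"].genotypes.values[flip] + 1
    ) % 3
    merged = merge_calls(sets["WXS_NORMAL"], sets["WXS_TUMOR"], sets["RNA_TUMOR"])
    rho = cross_source_af_correlation(sets, merged)
    af_n = cohort_allele_frequency(sets["WXS_NORMAL"].genotypes).to_numpy()
    af_r = cohort_allele_frequency(sets["RNA_TUMOR"].genotypes).to_numpy()
    oracle = np.corrcoef(stats.rankdata(af_n), stats.rankdata(af_r))[0, 1]
    assert rho.loc["WXS_NORMAL", "RNA_TUMOR"] == pytest.approx(oracle, abs=1e-10)
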