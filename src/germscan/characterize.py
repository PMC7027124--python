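"""Post-discovery characterization of prognostic variants.

Covers: the direction-concordance index and its comparison to the empirical
expectation; Spearman (and AF-controlled partial Spearman) correlation of
hazard ratios across cancers; minor-allele risk enrichment; the effect-size
vs allele-frequency correlation; genotype-correlation ("LD") pruning; genomic
region classification against a transcript model; the variant-pair
independence test; and the somatic driver-mutation association scan.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import UNKNOWN, DirectionIndex, GenotypeMatrix
from .survival import bh_fdr, cox_fit

__all__ = [
    "direction_index_stats",
    "partial_spearman",
    "hr_pair_correlation",
    "minor_allele_risk_test",
    "effect_size_af_correlation",
    "ld_prune",
    "read_bed12",
    "classify_region",
    "pair_hr_table",
    "pair_independence_test",
    "driver_association_scan",
]


# ---------------------------------------------------------------------------
# Direction concordance


def direction_index_stats(
    results: pd.DataFrame, min_cancers: int = 3, p_threshold: float = 0.05
) -> tuple[list[DirectionIndex], float, float]:
    """Direction-concordance index per variant plus the test against chance.

    For each variant associated with outcome (p < ``p_threshold``) in at
    least ``min_cancers`` cancers, the index is
    ``max(n_poor, n_favorable) / (n_poor + n_favorable)`` (1 = perfectly
    concordant).  The expected index under the observed direction imbalance
    is the same ratio over *all* qualifying associations pooled.  Returns
    (indices, expected_index, p) where p comes from a one-sample Wilcoxon
    comparison of the per-variant indices against the expected value.
    """
    sig = results[results["p"] < p_threshold]
    indices: list[DirectionIndex] = []
    for vid, grp in sig.groupby("variant_id"):
        n_poor = int((grp["log_hr"] > 0).sum())
        n_fav = int((grp["log_hr"] < 0).sum())
        if n_poor + n_fav >= min_cancers:
            indices.append(DirectionIndex(vid, n_poor, n_fav))
    if not indices:
        return [], float("nan"), float("nan")
    total_poor = sum(d.n_poor for d in indices)
    total_fav = sum(d.n_favorable for d in indices)
    expected = max(total_poor, total_fav) / (total_poor + total_fav)
    vals = np.array([d.index for d in indices])
    diffs = vals - expected
    if np.all(diffs == 0) or len(diffs) < 1:
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
    return indices, float(expected), p


# ---------------------------------------------------------------------------
# Hazard-ratio correlation across cancers


def partial_spearman(x, y, z) -> float:
    """First-order partial Spearman correlation of x and y controlling z:
    rank-transform all three, then r12.3 = (r12 - r13 r23)/sqrt((1-r13^2)(1-r23^2))."""
    rx, ry, rz = (stats.rankdata(np.asarray(v, dtype=float)) for v in (x, y, z))
    r12 = np.corrcoef(rx, ry)[0, 1]
    r13 = np.corrcoef(rx, rz)[0, 1]
    r23 = np.corrcoef(ry, rz)[0, 1]
    return float((r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2)))


def hr_pair_correlation(
    results: pd.DataFrame,
    direction: str = "poor",
    min_cancers: int = 3,
    p_threshold: float = 0.05,
    allele_frequency: pd.Series | None = None,
) -> tuple[float, float]:
    """Spearman correlation over all within-variant pairs of hazard ratios.

    Considers variants significant (p < threshold) in ``min_cancers`` or more
    cancers in the requested direction; each unordered pair of that variant's
    hazard ratios contributes one (HR1, HR2) point, ordered by stratum label.
    When ``allele_frequency`` is given, the AF-controlled partial Spearman
    correlation is returned instead.
    """
    if direction not in ("poor", "favorable"):
        raise ValueError("direction must be 'poor' or 'favorable'")
    sign = 1 if direction == "poor" else -1
    sig = results[(results["p"] < p_threshold) & (sign * results["log_hr"] > 0)]
    hr1, hr2, afs = [], [], []
    for vid, grp in sig.groupby("variant_id"):
        if len(grp) < min_cancers:
            continue
        grp = grp.sort_values("stratum")
        hrs = np.exp(grp["log_hr"].to_numpy())
        for i, j in combinations(range(len(hrs)), 2):
            hr1.append(hrs[i])
            hr2.append(hrs[j])
            if allele_frequency is not None:
                afs.append(float(allele_frequency[vid]))
    if len(hr1) < 3:
        raise ValueError("too few hazard-ratio pairs for a correlation")
    if allele_frequency is not None:
        rho = partial_spearman(hr1, hr2, afs)
        # t approximation with one controlled variable
        n = len(hr1)
        t = rho * np.sqrt((n - 3) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 3))
        return rho, p
    r = stats.spearmanr(hr1, hr2)
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# GWAS-style characteristics


def minor_allele_risk_test(hits: pd.DataFrame, af_column: str = "population_af"):
    """One-sided Fisher test that the minor allele is enriched among
    poor-outcome associations.

    ``hits`` needs an allele-frequency column (alternate-allele frequency)
    and ``log_hr``.  Minor = AF < 0.5; poor = HR > 1.  Returns (p, table)
    with table rows (minor, major) x columns (poor, favorable).
    """
    af = hits[af_column].to_numpy(dtype=float)
    poor = hits["log_hr"].to_numpy() > 0
    minor = af < 0.5
    table = np.array(
        [
            [int((minor & poor).sum()), int((minor & ~poor).sum())],
            [int((~minor & poor).sum()), int((~minor & ~poor).sum())],
        ]
    )
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return p, table


def effect_size_af_correlation(
    hits: pd.DataFrame, af_column: str = "population_af"
) -> tuple[float, float]:
    """Spearman correlation between effect size |ln HR| and allele frequency.

    Returns (nan, nan) when either vector is constant (correlation undefined).
    """
    effect = np.abs(hits["log_hr"].to_numpy(dtype=float))
    af = hits[af_column].to_numpy(dtype=float)
    if len(hits) < 3 or np.ptp(af) == 0 or np.ptp(effect) == 0:
        return float("nan"), float("nan")
    r = stats.spearmanr(effect, af)
    return float(r.statistic), float(r.pvalue)


def _pairwise_r2(genotypes: GenotypeMatrix, variant_ids: Sequence[str]) -> np.ndarray:
    cols = []
    for vid in variant_ids:
        d = genotypes.dosage(vid).astype(float)
        d[d == UNKNOWN] = np.nan
        cols.append(d)
    mat = np.column_stack(cols)
    k = mat.shape[1]
    r2 = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = mat[:, [i, j]]
            ok = ~np.isnan(pair).any(axis=1)
            x, y = pair[ok, 0], pair[ok, 1]
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(
    variant_ids: Sequence[str],
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    r2_threshold: float = 0.8,
) -> list[str]:
    """Collapse clusters of linked variants (pairwise genotype r^2 above the
    threshold, transitively) to the first variant by genomic position.

    The result is independent of the input ordering.
    """
    vids = sorted(
        set(variant_ids),
        key=lambda v: (str(annotations.loc[v, "chrom"]), int(annotations.loc[v, "pos"]), v),
    )
    if len(vids) <= 1:
        return list(vids)
    r2 = _pairwise_r2(genotypes, vids)
    parent = list(range(len(vids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(vids)):
        for j in range(i + 1, len(vids)):
            if r2[i, j] > r2_threshold:
                parent[find(j)] = find(i)
    kept = {}
    for i, vid in enumerate(vids):  # vids already in genomic order
        root = find(i)
        kept.setdefault(root, vid)
    return [v for v in vids if v in kept.values()]


# ---------------------------------------------------------------------------
# Genomic region classification


def read_bed12(path) -> pd.DataFrame:
    """Transcript model from a BED12 file (0-based half-open converted to the
    1-based inclusive coordinates used internally)."""
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "item_rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    bed = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    rows = []
    for r in bed.itertuples():
        sizes = [int(s) for s in str(r.block_sizes).rstrip(",").split(",")]
        starts = [int(s) for s in str(r.block_starts).rstrip(",").split(",")]
        exon_starts = [r.start + s + 1 for s in starts]  # 1-based
        exon_ends = [r.start + s + sz for s, sz in zip(starts, sizes)]
        rows.append(
            {
                "transcript_id": r.name,
                "chrom": str(r.chrom),
                "strand": r.strand,
                "tx_start": int(r.start) + 1,
                "tx_end": int(r.end),
                "cds_start": int(r.thick_start) + 1,
                "cds_end": int(r.thick_end),
                "exon_starts": exon_starts,
                "exon_ends": exon_ends,
            }
        )
    return pd.DataFrame(rows)


def classify_region(
    chrom: str, pos: int, transcripts: pd.DataFrame, window: int = 1000
) -> set[str]:
    """Genomic region labels of a position against a transcript model.

    A position may pick up multiple labels from different transcripts (each
    transcript contributes at most one).  Labels: upstream, 5'UTR, exonic,
    intronic, 3'UTR, downstream, intergenic.  The upstream/downstream window
    is strand-aware and defaults to 1 kb.
    """
    labels: set[str] = set()
    for t in transcripts[transcripts["chrom"] == str(chrom)].itertuples():
        if t.tx_start <= pos <= t.tx_end:
            in_exon = any(s <= pos <= e for s, e in zip(t.exon_starts, t.exon_ends))
            if not in_exon:
                labels.add("intronic")
            elif t.cds_start > t.cds_end:  # non-coding transcript
                labels.add("exonic")
            elif pos < t.cds_start:
                labels.add("5'UTR" if t.strand == "+" else "3'UTR")
            elif pos > t.cds_end:
                labels.add("3'UTR" if t.strand == "+" else "5'UTR")
            else:
                labels.add("exonic")
        elif t.tx_start - window <= pos < t.tx_start:
            labels.add("upstream" if t.strand == "+" else "downstream")
        elif t.tx_end < pos <= t.tx_end + window:
            labels.add("downstream" if t.strand == "+" else "upstream")
    return labels or {"intergenic"}


# ---------------------------------------------------------------------------
# Variant-pair independence


def pair_hr_table(
    poor_variants: Sequence[str],
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-pair hazard ratios for the 3-group construction within one cohort.

    For each pair of poor-outcome variants, patients homozygous for either
    alternate allele (dosage 2) or with an UNKNOWN call are excluded; the
    remaining patients form group 1 (reference/reference), group 2
    (heterozygous for exactly one) and group 3 (heterozygous for both).  Two
    covariate-adjusted Cox fits give HR(2 vs 1) and HR(3 vs 1).  Pairs with
    any empty group, or a failed fit, are skipped.
    """
    times = cohort["time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    rows = []
    for v1, v2 in combinations(sorted(poor_variants), 2):
        d1 = genotypes.dosage(v1).astype(int)
        d2 = genotypes.dosage(v2).astype(int)
        ok = (d1 != UNKNOWN) & (d2 != UNKNOWN) & (d1 < 2) & (d2 < 2)
        g1 = ok & (d1 == 0) & (d2 == 0)
        g2 = ok & ((d1 + d2) == 1)
        g3 = ok & (d1 == 1) & (d2 == 1)
        if g1.sum() == 0 or g2.sum() == 0 or g3.sum() == 0:
            continue
        hrs = {}
        failed = False
        for label, grp in (("hr_2v1", g2), ("hr_3v1", g3)):
            sel = g1 | grp
            X = cohort.loc[sel, list(covariates)].copy()
            X = X.loc[:, X.nunique() > 1]
            X["group"] = grp[sel].astype(float)
            try:
                res = cox_fit(X, times[sel], events[sel])
            except (ValueError, np.linalg.LinAlgError):
                failed = True
                break
            if not res.converged:
                failed = True
                break
            hrs[label] = np.exp(res.term("group")["log_hr"])
        if failed:
            continue
        rows.append({"variant_1": v1, "variant_2": v2, **hrs})
    return pd.DataFrame(rows, columns=["variant_1", "variant_2", "hr_2v1", "hr_3v1"])


def pair_independence_test(pair_table: pd.DataFrame) -> float:
    """One-sided paired Wilcoxon signed-rank p for HR(both het) > HR(one het)."""
    if len(pair_table) < 1:
        raise ValueError("no testable variant pairs")
    return float(
        stats.wilcoxon(
            pair_table["hr_3v1"], pair_table["hr_2v1"], alternative="greater"
        ).pvalue
    )


# ---------------------------------------------------------------------------
# Driver-mutation association


def driver_association_scan(
    genotypes: GenotypeMatrix,
    driver_table: pd.DataFrame,
    prognostic_ids: Sequence[str],
    tested_ids: Sequence[str] | None = None,
    min_mutated: int = 5,
    fdr_threshold: float = 0.10,
) -> dict:
    """Risk-allele carriage vs somatic driver mutation, per pair and globally.

    Per (variant, driver gene) with at least ``min_mutated`` mutated patients:
    a one-sided Fisher test for carriers being enriched for the mutation,
    BH-adjusted over all tested pairs.  Globally: a one-sided Fisher test of
    whether prognostic variants are more often associated (any pair FDR <
    threshold) with a driver mutation than the other tested variants.

    Returns a dict with ``pairs`` (per-pair table), ``enrichment_or`` and
    ``enrichment_p``.
    """
    if tested_ids is None:
        tested_ids = list(genotypes.variants)
    driver_table = driver_table.reindex(genotypes.patients)
    eligible_drivers = [
        g for g in driver_table.columns if driver_table[g].sum() >= min_mutated
    ]
    rows = []
    for vid in tested_ids:
        dos = genotypes.dosage(vid)
        carrier = (dos == 1) | (dos == 2)
        known = dos != UNKNOWN
        for gene in eligible_drivers:
            mut = driver_table[gene].to_numpy(dtype=bool)
            a = int((carrier & mut & known).sum())
            b = int((carrier & ~mut & known).sum())
            c = int((~carrier & mut & known).sum())
            d = int((~carrier & ~mut & known).sum())
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
            rows.append({"variant_id": vid, "driver_gene": gene, "p": p})
    pairs = pd.DataFrame(rows, columns=["variant_id", "driver_gene", "p"])
    if len(pairs):
        pairs["fdr"] = bh_fdr(pairs["p"].to_numpy())
    else:
        pairs["fdr"] = []
    associated = set(pairs.loc[pairs["fdr"] < fdr_threshold, "variant_id"])
    prog = set(prognostic_ids)
    other = set(tested_ids) - prog
    table = np.array(
        [
            [len(prog & associated), len(prog - associated)],
            [len(other & associated), len(other - associated)],
        ]
    )
    orat, p = stats.fisher_exact(table, alternative="greater")
    return {
        "pairs": pairs,
        "enrichment_table": table,
        "enrichment_or": float(orat),
        "enrichment_p": float(p),
    }
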