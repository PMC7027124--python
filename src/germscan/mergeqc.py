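"""Merge the three per-source call sets, mask low-depth calls, compute
cross-source concordance and cohort allele frequencies, and apply the three
discovery filters (population AF, per-cancer carrier count, per-cancer
concordance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    UNKNOWN,
    SOURCES,
    GenotypeMatrix,
    MergedCallSet,
    QcThresholds,
    SourceCallSet,
)

__all__ = [
    "mask_low_depth",
    "merge_calls",
    "concordance_percent",
    "cohort_allele_frequency",
    "qc_filter",
    "cross_source_af_correlation",
    "QcReport",
]


def mask_low_depth(calls: SourceCallSet, min_depth: int = 10) -> SourceCallSet:
    """Set calls covered by fewer than ``min_depth`` reads to UNKNOWN."""
    values = calls.genotypes.values.copy()
    values[calls.depth < min_depth] = UNKNOWN
    return SourceCallSet(
        source=calls.source,
        genotypes=GenotypeMatrix(
            values, calls.genotypes.patients.copy(), calls.genotypes.variants.copy()
        ),
        depth=calls.depth.copy(),
    )


def _check_aligned(*mats: GenotypeMatrix) -> None:
    first = mats[0]
    for m in mats[1:]:
        if not (m.patients.equals(first.patients) and m.variants.equals(first.variants)):
            raise ValueError("call sets must share patient and variant indices")


def merge_calls(
    normal: SourceCallSet, tumor: SourceCallSet, rna: SourceCallSet
) -> MergedCallSet:
    """Precedence merge: per entry the first known call among normal exome,
    tumor exome, tumor RNA; UNKNOWN when all three are unknown."""
    _check_aligned(normal.genotypes, tumor.genotypes, rna.genotypes)
    stack = np.stack(
        [normal.genotypes.values, tumor.genotypes.values, rna.genotypes.values]
    )
    known = stack != UNKNOWN
    # index of the first known source (argmax finds first True); UNKNOWN if none
    first = known.argmax(axis=0)
    any_known = known.any(axis=0)
    merged = np.take_along_axis(stack, first[None], axis=0)[0]
    merged = np.where(any_known, merged, UNKNOWN).astype(np.int8)
    provenance = np.where(any_known, np.array(SOURCES)[first], "UNKNOWN")
    genotypes = GenotypeMatrix(
        merged, normal.genotypes.patients.copy(), normal.genotypes.variants.copy()
    )
    return MergedCallSet(
        genotypes=genotypes,
        source_provenance=provenance,
        cohort_af=cohort_allele_frequency(genotypes),
        concordance_pct=concordance_percent(normal, tumor, rna),
    )


def concordance_percent(
    normal: SourceCallSet,
    tumor: SourceCallSet,
    rna: SourceCallSet,
    patients: pd.Index | None = None,
) -> pd.Series:
    """Per-variant cross-source concordance as a percentage of patients.

    A patient is concordant for a variant iff all three sources carry the
    same *known* genotype; any UNKNOWN makes the patient discordant.  The
    denominator is the total number of patients considered.
    """
    _check_aligned(normal.genotypes, tumor.genotypes, rna.genotypes)
    idx = normal.genotypes.patients
    if patients is not None:
        sel = idx.get_indexer(patients)
        if (sel < 0).any():
            raise ValueError("requested patients missing from call sets")
    else:
        sel = np.arange(len(idx))
    if len(sel) == 0:
        raise ValueError("concordance undefined over zero patients")
    a = normal.genotypes.values[sel]
    b = tumor.genotypes.values[sel]
    c = rna.genotypes.values[sel]
    concordant = (a == b) & (b == c) & (a != UNKNOWN)
    pct = concordant.sum(axis=0) / len(sel) * 100.0
    return pd.Series(pct, index=normal.genotypes.variants, name="concordance_pct")


def cohort_allele_frequency(genotypes: GenotypeMatrix) -> pd.Series:
    """Alternate-allele frequency per variant over non-UNKNOWN calls:
    sum(dosage) / (2 * called patients).  NaN when every call is UNKNOWN."""
    values = genotypes.values
    known = values != UNKNOWN
    n_called = known.sum(axis=0)
    alt = np.where(known, values, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return pd.Series(af, index=genotypes.variants, name="cohort_af")


@dataclass
class QcReport:
    """Per-cancer surviving variants plus per-filter exclusion counts."""

    survivors: dict[str, list[str]]
    exclusions: dict[str, dict[str, int]] = field(default_factory=dict)
    detail: pd.DataFrame | None = None


def qc_filter(
    merged: MergedCallSet,
    annotations: pd.DataFrame,
    thresholds: QcThresholds,
    cancer_of_patient: pd.Series,
    per_cancer_concordance: dict[str, pd.Series] | None = None,
) -> QcReport:
    """Apply the three discovery filters per (variant, cancer).

    A variant survives in a cancer iff population AF > ``min_population_af``
    (strict), carrier count within the cancer (merged dosage >= 1) is at
    least ``min_carriers``, and cross-source concordance within the cancer is
    strictly greater than ``min_concordance_pct``.

    ``per_cancer_concordance`` maps cancer code -> per-variant concordance
    computed over that cancer's patients (from :func:`concordance_percent`);
    when omitted, the merged set's cohort-wide concordance is used for every
    cancer.
    """
    variants = merged.genotypes.variants
    missing = variants.difference(annotations.index)
    if len(missing):
        raise ValueError(f"annotations missing for {len(missing)} variants")
    pop_af = annotations.loc[variants, "population_af"].to_numpy(dtype=float)
    pass_af = pop_af > thresholds.min_population_af

    cancer_of_patient = cancer_of_patient.reindex(merged.genotypes.patients)
    survivors: dict[str, list[str]] = {}
    exclusions: dict[str, dict[str, int]] = {}
    rows = []
    for cancer in sorted(cancer_of_patient.dropna().unique()):
        mask = (cancer_of_patient == cancer).to_numpy()
        sub = merged.genotypes.values[mask]
        carriers = ((sub == 1) | (sub == 2)).sum(axis=0)
        pass_carriers = carriers >= thresholds.min_carriers
        if per_cancer_concordance is not None:
            conc = per_cancer_concordance[cancer].reindex(variants).to_numpy(dtype=float)
        else:
            conc = merged.concordance_pct.reindex(variants).to_numpy(dtype=float)
        pass_conc = conc > thresholds.min_concordance_pct
        keep = pass_af & pass_carriers & pass_conc
        survivors[cancer] = list(variants[keep])
        exclusions[cancer] = {
            "population_af": int((~pass_af).sum()),
            "carriers": int((~pass_carriers).sum()),
            "concordance": int((~pass_conc).sum()),
        }
        rows.append(
            pd.DataFrame(
                {
                    "variant_id": variants,
                    "cancer": cancer,
                    "population_af": pop_af,
                    "carriers": carriers,
                    "concordance_pct": conc,
                    "pass_population_af": pass_af,
                    "pass_carriers": pass_carriers,
                    "pass_concordance": pass_conc,
                    "pass": keep,
                }
            )
        )
    detail = pd.concat(rows, ignore_index=True) if rows else None
    return QcReport(survivors=survivors, exclusions=exclusions, detail=detail)


def cross_source_af_correlation(
    call_sets: dict[str, SourceCallSet], merged: MergedCallSet
) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-variant allele frequencies across
    the three sources and the merged set."""
    afs = {
        source: cohort_allele_frequency(call_sets[source].genotypes)
        for source in SOURCES
    }
    afs["MERGED"] = merged.cohort_af
    table = pd.DataFrame(afs)
    labels = list(table.columns)
    rho = np.ones((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = table.iloc[:, [i, j]].dropna()
            r = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=labels, columns=labels)
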