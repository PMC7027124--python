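"""The six discovery analyses.

Analyses 1 and 4 scan each QC-passing variant for association with outcome
within each cancer (Cox model controlling the cancer's selected clinical
covariates), with BH FDR applied within each cancer.  Analyses 2 and 5 filter
the per-cancer results for variants recurrently associated (p < 0.05) with a
single hazard-ratio direction in enough cancers.  Analyses 3 and 6 pool
pre-specified groups of cancers, fitting interaction designs that control for
cancer membership and for each member cancer's covariates within that cancer
only.  Analyses 4-6 restrict to deleterious variants (CADD > 25).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import UNKNOWN, GenotypeMatrix, GroupSpec, ScanConfig, ScanHit
from .survival import bh_fdr, cox_fit

__all__ = [
    "per_cancer_scan",
    "recurrence_filter",
    "build_group_design",
    "group_scan",
    "hr_sensitivity_correlation",
]

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "variant_id",
    "stratum",
    "log_hr",
    "se",
    "p",
    "fdr",
    "n",
    "n_events",
    "converged",
]


def _variant_column(genotypes: GenotypeMatrix, variant_id: str, coding: str) -> np.ndarray:
    dos = genotypes.dosage(variant_id).astype(float)
    dos[genotypes.dosage(variant_id) == UNKNOWN] = np.nan
    if coding == "dominant":
        dos = np.where(np.isnan(dos), np.nan, (dos >= 1).astype(float))
    return dos


def _fit_variant(design: pd.DataFrame, times, events, variant_col: np.ndarray):
    """Cox fit of covariates + variant, dropping patients with UNKNOWN calls
    at this variant only.  Returns the variant-term row or None."""
    keep = ~np.isnan(variant_col)
    times, events = times[keep], events[keep]
    if events.sum() == 0:
        return None
    vcol = variant_col[keep]
    if np.ptp(vcol) == 0:
        return None
    Z = design.to_numpy(dtype=float)[keep] if len(design.columns) else None
    if Z is not None and Z.size:
        nonconst = np.ptp(Z, axis=0) > 0  # covariates constant in subset drop out
        X = np.column_stack([Z[:, nonconst], vcol])
        terms = [c for c, ok in zip(design.columns, nonconst) if ok] + ["variant"]
    else:
        X = vcol[:, None]
        terms = ["variant"]
    try:
        res = cox_fit(X, times, events, terms=terms)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not res.converged:
        return None
    t = res.term("variant")
    return {
        "log_hr": t["log_hr"],
        "se": t["se"],
        "p": t["p"],
        "n": res.n,
        "n_events": res.n_events,
    }


def _finish_family(rows: list[dict], stratum: str, analysis_id: int, fdr_threshold: float):
    """BH within one family (one cancer or one group); return results + hits."""
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS), []
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["stratum"] = stratum
    df["converged"] = True
    hits = [
        ScanHit(
            variant_id=r.variant_id,
            stratum=stratum,
            log_hr=r.log_hr,
            se=r.se,
            p=r.p,
            fdr=r.fdr,
            analysis_id=analysis_id,
            n=int(r.n),
            n_events=int(r.n_events),
        )
        for r in df.itertuples()
        if r.fdr < fdr_threshold
    ]
    return df[RESULT_COLUMNS], hits


def _apply_cadd(
    variant_ids: Sequence[str], annotations: pd.DataFrame | None, config: ScanConfig
) -> list[str]:
    if annotations is None:
        raise ValueError("CADD filtering requires an annotation table")
    cadd = annotations["cadd_score"].reindex(variant_ids)
    return [v for v in variant_ids if cadd[v] > config.cadd_threshold]


def per_cancer_scan(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    eligible: Mapping[str, Sequence[str]],
    covariates_per_cancer: Mapping[str, Sequence[str]],
    config: ScanConfig | None = None,
    annotations: pd.DataFrame | None = None,
    cadd_filter: bool = False,
) -> tuple[pd.DataFrame, list[ScanHit]]:
    """Analyses 1 (all QC-passing variants) and 4 (CADD > 25 subset).

    One Cox fit per (variant, cancer) controlling the cancer's selected
    covariates; BH within each cancer over the variants tested there; hits
    are FDR < ``config.fdr_threshold``.  Non-converged fits are logged and
    excluded from the BH family.
    """
    config = config or ScanConfig()
    analysis_id = 4 if cadd_filter else 1
    if not cohort.index.equals(genotypes.patients):
        raise ValueError("cohort and genotypes must index the same patients")
    all_results, all_hits = [], []
    for cancer in sorted(eligible):
        variant_ids = list(eligible[cancer])
        if cadd_filter:
            variant_ids = _apply_cadd(variant_ids, annotations, config)
        mask = (cohort["cancer"] == cancer).to_numpy()
        if mask.sum() == 0 or not variant_ids:
            continue
        sub = cohort.loc[mask]
        times = sub["time"].to_numpy(dtype=float)
        events = sub["event"].to_numpy(dtype=int)
        covs = list(covariates_per_cancer.get(cancer, []))
        design = sub[covs] if covs else pd.DataFrame(index=sub.index)
        rows = []
        for vid in variant_ids:
            col = _variant_column(genotypes, vid, config.genotype_coding)[mask]
            fit = _fit_variant(design, times, events, col)
            if fit is None:
                log.info("fit skipped (non-converged/degenerate): %s in %s", vid, cancer)
                continue
            fit["variant_id"] = vid
            rows.append(fit)
        res, hits = _finish_family(rows, cancer, analysis_id, config.fdr_threshold)
        all_results.append(res)
        all_hits.extend(hits)
    results = (
        pd.concat(all_results, ignore_index=True)
        if all_results
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    return results, all_hits


def recurrence_filter(
    results: pd.DataFrame, min_cancers: int = 7, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Analyses 2 and 5: variants recurrently associated (p < threshold) with
    one shared hazard-ratio direction in at least ``min_cancers`` cancers.

    ``results`` is the full per-cancer result table from
    :func:`per_cancer_scan` (not just the FDR hits).
    """
    sig = results[results["p"] < p_threshold]
    rows = []
    for vid, grp in sig.groupby("variant_id"):
        n_poor = int((grp["log_hr"] > 0).sum())
        n_fav = int((grp["log_hr"] < 0).sum())
        best = max(n_poor, n_fav)
        if best >= min_cancers:
            rows.append(
                {
                    "variant_id": vid,
                    "direction": "poor" if n_poor >= n_fav else "favorable",
                    "n_cancers": best,
                    "cancers": ",".join(sorted(grp.loc[
                        grp["log_hr"] > 0 if n_poor >= n_fav else grp["log_hr"] < 0,
                        "stratum",
                    ])),
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "direction", "n_cancers", "cancers"])


def build_group_design(group: GroupSpec, cohort: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the pooled interaction model.

    Columns: cancer-membership dummies for every member cancer beyond the
    lexicographically first (the reference), plus one interaction column
    ``<cancer>:<covariate>`` per covariate selected in that cancer -- zero
    for patients outside the cancer -- to which the caller appends the
    variant dosage column.
    """
    members = sorted(group.cancers)
    present = [c for c in members if (cohort["cancer"] == c).any()]
    for c in members:
        if c not in present:
            log.warning("group %s: cancer %s has no patients; dropped", group.group_id, c)
    if not present:
        raise ValueError(f"group {group.group_id} has no patients")
    sub = cohort[cohort["cancer"].isin(present)]
    design = pd.DataFrame(index=sub.index)
    for c in present[1:]:
        design[f"{c}_status"] = (sub["cancer"] == c).astype(float)
    for c in present:
        indicator = (sub["cancer"] == c).astype(float)
        for cov in group.covariates.get(c, []):
            design[f"{c}:{cov}"] = indicator * sub[cov].astype(float)
    return design


def group_scan(
    groups: Sequence[GroupSpec],
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    config: ScanConfig | None = None,
    candidate_variants: Mapping[str, Sequence[str]] | None = None,
    annotations: pd.DataFrame | None = None,
    cadd_filter: bool = False,
) -> tuple[pd.DataFrame, list[ScanHit]]:
    """Analyses 3 (pooled groups) and 6 (CADD > 25 subset).

    Per group, variants carried by at least ``config.group_min_carriers``
    patients pooled across the member cancers are fitted on the interaction
    design; BH within group.  A variant hit in several overlapping groups is
    reported once, from the group containing the most patients.
    """
    config = config or ScanConfig()
    analysis_id = 6 if cadd_filter else 3
    if not cohort.index.equals(genotypes.patients):
        raise ValueError("cohort and genotypes must index the same patients")
    all_results, hits_by_variant = [], {}
    group_sizes = {}
    for group in groups:
        members = [c for c in group.cancers if (cohort["cancer"] == c).any()]
        mask = cohort["cancer"].isin(members).to_numpy()
        if mask.sum() == 0:
            continue
        group_sizes[group.group_id] = int(mask.sum())
        if candidate_variants is not None:
            pool = sorted(
                set().union(*(candidate_variants.get(c, []) for c in members))
            )
        else:
            pool = list(genotypes.variants)
        if cadd_filter:
            pool = _apply_cadd(pool, annotations, config)
        sub_values = genotypes.values[mask]
        design = build_group_design(group, cohort)
        times = cohort.loc[mask, "time"].to_numpy(dtype=float)
        events = cohort.loc[mask, "event"].to_numpy(dtype=int)
        rows = []
        for vid in pool:
            j = genotypes.variants.get_loc(vid)
            dos = sub_values[:, j]
            carriers = int(((dos == 1) | (dos == 2)).sum())
            if carriers < config.group_min_carriers:
                continue
            col = dos.astype(float)
            col[dos == UNKNOWN] = np.nan
            if config.genotype_coding == "dominant":
                col = np.where(np.isnan(col), np.nan, (col >= 1).astype(float))
            fit = _fit_variant(design, times, events, col)
            if fit is None:
                log.info("group fit skipped: %s in %s", vid, group.group_id)
                continue
            fit["variant_id"] = vid
            rows.append(fit)
        res, hits = _finish_family(rows, group.group_id, analysis_id, config.fdr_threshold)
        all_results.append(res)
        for h in hits:
            prev = hits_by_variant.get(h.variant_id)
            if prev is None or group_sizes[h.stratum] > group_sizes[prev.stratum]:
                hits_by_variant[h.variant_id] = h
    results = (
        pd.concat(all_results, ignore_index=True)
        if all_results
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    return results, list(hits_by_variant.values())


def hr_sensitivity_correlation(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation of hazard ratios between two scan runs (e.g. with
    and without an extra covariate block such as race composition), matched
    on (variant, stratum)."""
    merged = results_a.merge(
        results_b, on=["variant_id", "stratum"], suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 shared fits for a sensitivity correlation")
    r = stats.spearmanr(merged["log_hr_a"], merged["log_hr_b"])
    return float(r.statistic), float(r.pvalue)
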