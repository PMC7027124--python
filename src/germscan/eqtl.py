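"""cis-eQTL triage of prognostic variants.

A prognostic variant is a plausible cis-eQTL mechanism when (a) carriers of
the alternate allele show a shifted expression of the proximate gene
(two-group rank-sum test) and (b) the gene's expression itself predicts
outcome in a covariate-adjusted Cox model, with the direction chain
self-consistent: a risk variant whose carriers over-express the gene must
see that over-expression associated with risk (expression HR > 1), and
symmetrically for the other three sign combinations.  Because both tests
must agree, the triage uses a relaxed p < 0.10 cut-off for hypothesis
generation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import UNKNOWN, EqtlCandidate, GenotypeMatrix
from .survival import cox_fit

__all__ = ["carrier_expression_test", "concordant_eqtl_scan"]


def carrier_expression_test(dosage, expression) -> tuple[float, int]:
    """Rank-sum test of expression between carriers (dosage >= 1) and
    non-carriers; returns (p, direction) with direction +1 when carriers are
    higher (median difference), -1 when lower.

    Returns (nan, 0) when either group is empty (test undefined).
    """
    dosage = np.asarray(dosage)
    expression = np.asarray(expression, dtype=float)
    known = dosage != UNKNOWN
    carrier = known & (dosage >= 1)
    noncarrier = known & (dosage == 0)
    if carrier.sum() == 0 or noncarrier.sum() == 0:
        return float("nan"), 0
    xc, xn = expression[carrier], expression[noncarrier]
    p = float(stats.mannwhitneyu(xc, xn, alternative="two-sided").pvalue)
    diff = float(np.median(xc) - np.median(xn))
    if diff == 0:
        diff = float(np.mean(xc) - np.mean(xn))
    return p, (1 if diff > 0 else -1 if diff < 0 else 0)


def concordant_eqtl_scan(
    hits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    annotations: pd.DataFrame,
    covariates_per_cancer: Mapping[str, Sequence[str]] | None = None,
    p_threshold: float = 0.10,
) -> tuple[list[EqtlCandidate], list[EqtlCandidate]]:
    """Evaluate each prognostic hit for a concordant cis-expression mechanism.

    ``hits`` needs columns variant_id, stratum (cancer code) and log_hr; the
    proximate gene comes from the annotation table and its expression (gene x
    patient) is z-scored within the cancer so the Cox hazard ratio is per SD.
    Returns (retained, evaluated): retained candidates have both p-values
    below the threshold and a self-consistent direction chain.
    """
    covariates_per_cancer = covariates_per_cancer or {}
    evaluated: list[EqtlCandidate] = []
    retained: list[EqtlCandidate] = []
    for h in hits.itertuples():
        gene = annotations.loc[h.variant_id, "gene_id"]
        if gene not in expression.index:
            continue
        cancer = h.stratum
        mask = (cohort["cancer"] == cancer).to_numpy()
        patients = cohort.index[mask]
        dos = genotypes.dosage(h.variant_id)[mask]
        expr = expression.loc[gene, patients].to_numpy(dtype=float)
        sd = expr.std(ddof=1)
        if sd == 0:
            continue
        z = (expr - expr.mean()) / sd

        p_expr, direction = carrier_expression_test(dos, z)
        if direction == 0 or not np.isfinite(p_expr):
            continue

        covs = [c for c in covariates_per_cancer.get(cancer, []) if cohort.loc[mask, c].nunique() > 1]
        X = cohort.loc[mask, covs].copy() if covs else pd.DataFrame(index=patients)
        X["expression"] = z
        times = cohort.loc[mask, "time"].to_numpy(dtype=float)
        events = cohort.loc[mask, "event"].to_numpy(dtype=int)
        try:
            res = cox_fit(X, times, events)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not res.converged:
            continue
        t = res.term("expression")
        # chain: variant direction must equal (expression shift) x (expression effect)
        concordant = np.sign(h.log_hr) == direction * np.sign(t["log_hr"])
        cand = EqtlCandidate(
            variant_id=h.variant_id,
            gene_id=gene,
            expression_p=p_expr,
            expression_direction=direction,
            expression_log_hr=t["log_hr"],
            expression_cox_p=t["p"],
            outcome_log_hr=float(h.log_hr),
            concordant=bool(concordant),
        )
        evaluated.append(cand)
        if concordant and p_expr < p_threshold and t["p"] < p_threshold:
            retained.append(cand)
    return retained, evaluated
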