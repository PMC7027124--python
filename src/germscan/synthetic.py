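"""Synthetic cohort generation with planted, recorded ground truth.

Emulates the statistical structure the discovery pipeline assumes: Hardy-
Weinberg germline genotypes at annotated population allele frequencies, three
correlated-but-corruptible call sets (normal exome, tumor exome, tumor RNA)
with per-position read depths, Weibull proportional-hazards outcomes with
planted per-variant log hazard ratios and covariate effects, independent
administrative censoring, cis-eQTL expression shifts, and variant-driver
somatic-mutation associations.

Every generator draws from a named child stream of one master seed, so adding
a generator never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    UNKNOWN,
    SOURCES,
    EffectPlan,
    GenotypeMatrix,
    SourceCallSet,
    VariantRecord,
)

__all__ = [
    "child_rng",
    "generate_variants",
    "generate_baseline_cohort",
    "generate_genotypes",
    "simulate_outcomes",
    "corrupt_to_call_sets",
    "simulate_expression",
    "simulate_driver_mutations",
]


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child stream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def generate_variants(
    n_variants: int,
    af_range: tuple[float, float] = (0.05, 0.5),
    cadd_high_fraction: float = 0.1,
    seed: int = 0,
    chrom: str = "1",
    spacing: int = 1000,
) -> list[VariantRecord]:
    """Annotation records for ``n_variants`` bi-allelic SNVs on one chromosome.

    Population AFs are uniform on ``af_range``; a ``cadd_high_fraction`` of
    variants get CADD scores above 25 (deleterious), the rest below. Each
    variant is assigned its own gene id (``gene_<variant index>``).
    """
    rng = child_rng(seed, "variants")
    afs = rng.uniform(*af_range, size=n_variants)
    high = rng.random(n_variants) < cadd_high_fraction
    cadd = np.where(high, rng.uniform(25.5, 40.0, n_variants), rng.uniform(0.0, 20.0, n_variants))
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n_variants):
        ref, alt = rng.choice(4, size=2, replace=False)
        out.append(
            VariantRecord(
                variant_id=f"v{i:05d}",
                chrom=chrom,
                pos=(i + 1) * spacing,
                ref=str(bases[ref]),
                alt=str(bases[alt]),
                population_af=float(afs[i]),
                cadd_score=float(cadd[i]),
                gene_id=f"gene_{i:05d}",
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return out


def generate_baseline_cohort(
    n_patients: int,
    cancer_codes: Sequence[str],
    covariate_spec: Mapping[str, Mapping],
    seed: int = 0,
    cancer_proportions: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Clinical table without outcomes: cancer code plus covariates.

    ``covariate_spec`` maps covariate name -> distribution spec, one of
    ``{"dist": "normal", "mean": m, "sd": s}``, ``{"dist": "binary", "p": p}``,
    ``{"dist": "uniform", "low": a, "high": b}`` or
    ``{"dist": "constant", "value": v}``. Covariates are drawn independently.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = child_rng(seed, "cohort")
    if cancer_proportions is None:
        cancer_proportions = [1.0 / len(cancer_codes)] * len(cancer_codes)
    p = np.asarray(cancer_proportions, dtype=float)
    p = p / p.sum()
    cancers = rng.choice(list(cancer_codes), size=n_patients, p=p)
    table = pd.DataFrame(
        {"cancer": cancers},
        index=pd.Index([f"P{i:05d}" for i in range(n_patients)], name="patient_id"),
    )
    for name, spec in covariate_spec.items():
        dist = spec.get("dist")
        if dist == "normal":
            table[name] = rng.normal(spec.get("mean", 0.0), spec.get("sd", 1.0), n_patients)
        elif dist == "binary":
            table[name] = (rng.random(n_patients) < spec["p"]).astype(float)
        elif dist == "uniform":
            table[name] = rng.uniform(spec.get("low", 0.0), spec.get("high", 1.0), n_patients)
        elif dist == "constant":
            table[name] = float(spec["value"])
        else:
            raise ValueError(f"unknown distribution {dist!r} for covariate {name!r}")
    return table


def generate_genotypes(
    variants: Sequence[VariantRecord], n_patients: int, seed: int = 0
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages: P(2) = q^2, P(1) = 2pq, P(0) = p^2, q = population AF."""
    afs = np.array([v.population_af for v in variants])
    if ((afs <= 0) | (afs >= 1)).any():
        raise ValueError("population_af must lie strictly in (0, 1) to draw genotypes")
    rng = child_rng(seed, "genotypes")
    u = rng.random((n_patients, len(variants)))
    q = afs[None, :]
    # cumulative HWE classes: hom-ref p^2, then het 2pq, then hom-alt q^2
    p_hom_ref = (1 - q) ** 2
    p_het = 2 * q * (1 - q)
    values = np.where(u < p_hom_ref, 0, np.where(u < p_hom_ref + p_het, 1, 2)).astype(np.int8)
    return GenotypeMatrix(
        values,
        pd.Index([f"P{i:05d}" for i in range(n_patients)], name="patient_id"),
        pd.Index([v.variant_id for v in variants], name="variant_id"),
    )


def _calibrate_censor_horizon(event_times: np.ndarray, censoring_rate: float) -> float:
    """Administrative-censoring horizon c such that uniform C ~ U(0, c) censors
    the requested fraction in expectation; solved by bisection.

    Expected censored fraction at horizon c is mean_i min(T_i / c, 1),
    decreasing in c.
    """

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(event_times / c, 1.0)))

    lo = float(np.min(event_times)) * 1e-3 + 1e-12
    hi = float(np.max(event_times)) * 2 + 1e-12
    while frac(hi) > censoring_rate:
        hi *= 2
        if hi > 1e18:  # pragma: no cover - pathological inputs
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_outcomes(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    plan: EffectPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach Weibull proportional-hazards outcomes to a baseline cohort.

    The linear predictor is the sum of planted covariate effects times the
    covariate values plus planted variant effects times dosages (UNKNOWN
    dosages contribute 0).  With baseline shape k and scale lam, event times
    are ``lam * (-log U / exp(eta)) ** (1/k)``, which makes every planted
    log hazard ratio exact under proportional hazards.  Censoring is
    independent uniform administrative censoring calibrated by bisection to
    the requested expected censoring fraction.
    """
    if not cohort.index.equals(genotypes.patients):
        raise ValueError("cohort and genotype matrix must index the same patients")
    n = len(cohort)
    eta = np.zeros(n)
    for cov, beta in plan.covariate_effects.items():
        if cov not in cohort.columns:
            raise ValueError(f"planted covariate {cov!r} missing from cohort")
        eta += beta * cohort[cov].to_numpy(dtype=float)
    for vid, beta in plan.variant_effects.items():
        dos = genotypes.dosage(vid).astype(float)
        dos[dos == UNKNOWN] = 0.0
        eta += beta * dos
    rng = child_rng(seed, "outcomes")
    u = rng.random(n)
    event_times = plan.baseline_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / plan.baseline_shape)

    out = cohort.copy()
    if plan.censoring_rate <= 0:
        out["time"] = event_times
        out["event"] = 1
        return out
    horizon = _calibrate_censor_horizon(event_times, plan.censoring_rate)
    censor_times = rng.uniform(0, horizon, n)
    out["time"] = np.minimum(event_times, censor_times)
    out["event"] = (event_times <= censor_times).astype(int)
    return out


def corrupt_to_call_sets(
    truth: GenotypeMatrix,
    discordance_rate: float = 0.02,
    depth_means: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, SourceCallSet]:
    """Derive the three per-source call sets from the planted truth.

    Each source independently flips each entry with probability
    ``discordance_rate`` to one of the two other genotype classes (uniformly).
    Depths are Poisson with a per-source mean; the defaults reflect typical
    coverage (normal exome 60x, tumor exome 80x, tumor RNA 30x).
    """
    if not 0.0 <= discordance_rate <= 1.0:
        raise ValueError("discordance_rate must lie in [0, 1]")
    if depth_means is None:
        depth_means = {"WXS_NORMAL": 60.0, "WXS_TUMOR": 80.0, "RNA_TUMOR": 30.0}
    out: dict[str, SourceCallSet] = {}
    for source in SOURCES:
        rng = child_rng(seed, f"corrupt:{source}")
        values = truth.values.copy()
        flip = rng.random(values.shape) < discordance_rate
        # uniformly one of the two other classes: offset 1 or 2 mod 3
        offset = rng.integers(1, 3, size=values.shape)
        values = np.where(flip, (values + offset) % 3, values).astype(np.int8)
        depth = rng.poisson(depth_means[source], size=values.shape)
        out[source] = SourceCallSet(
            source=source,
            genotypes=GenotypeMatrix(values, truth.patients.copy(), truth.variants.copy()),
            depth=depth,
        )
    return out


def simulate_expression(
    genotypes: GenotypeMatrix,
    plan: EffectPlan,
    gene_ids: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x patient expression: standard-normal baseline plus planted cis shifts.

    Carriers (dosage >= 1) of each planted eQTL variant have the target gene
    shifted by the planted amount, in SD units of the baseline.
    """
    rng = child_rng(seed, "expression")
    expr = pd.DataFrame(
        rng.normal(size=(len(gene_ids), genotypes.n_patients)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=genotypes.patients,
    )
    for vid, (gene, shift) in plan.eqtl_effects.items():
        if gene not in expr.index:
            raise ValueError(f"eQTL target gene {gene!r} not in expression matrix")
        carriers = genotypes.dosage(vid) >= 1
        expr.loc[gene, carriers] = expr.loc[gene, carriers] + shift
    return expr


def simulate_driver_mutations(
    genotypes: GenotypeMatrix,
    plan: EffectPlan,
    driver_genes: Sequence[str],
    background_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient x driver-gene binary somatic-mutation table.

    Baseline mutation probability is ``background_rate``; for carriers of a
    variant planted against a driver gene the mutation odds are multiplied by
    the planted odds ratio.
    """
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must lie in [0, 1]")
    rng = child_rng(seed, "drivers")
    probs = np.full((genotypes.n_patients, len(driver_genes)), background_rate)
    gene_pos = {g: j for j, g in enumerate(driver_genes)}
    for vid, (gene, oratio) in plan.driver_assoc.items():
        if gene not in gene_pos:
            raise ValueError(f"planted driver gene {gene!r} not in driver gene list")
        carriers = genotypes.dosage(vid) >= 1
        if background_rate in (0.0, 1.0):
            continue  # degenerate baseline: odds multiplication cannot move it
        odds = background_rate / (1 - background_rate) * oratio
        probs[carriers, gene_pos[gene]] = odds / (1 + odds)
    table = (rng.random(probs.shape) < probs).astype(int)
    return pd.DataFrame(
        table, index=genotypes.patients, columns=pd.Index(driver_genes, name="driver_gene")
    )
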