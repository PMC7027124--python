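"""Core containers shared across the pipeline.

Genotypes are stored as alternate-allele dosages in ``{0, 1, 2}`` with
``UNKNOWN`` (= -1) marking calls that were masked (low depth) or never made.
All matrices are patients x variants and keep their pandas index labels so
that merge, QC and survival stages can align on patient/variant identity
rather than on array position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel dosage for a missing / masked genotype call
UNKNOWN: int = -1

#: call-set sources in merge-precedence order (normal exome wins)
SOURCES = ("WXS_NORMAL", "WXS_TUMOR", "RNA_TUMOR")


@dataclass
class GenotypeMatrix:
    """Patients x variants alternate-allele dosage matrix.

    ``values`` is an int8 array with entries in {0, 1, 2, UNKNOWN}.
    """

    values: np.ndarray
    patients: pd.Index
    variants: pd.Index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.patients = pd.Index(self.patients, name="patient_id")
        self.variants = pd.Index(self.variants, name="variant_id")
        if self.values.shape != (len(self.patients), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.patients)} patients x {len(self.variants)} variants"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.variants)

    def dosage(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant (UNKNOWN entries kept as -1)."""
        j = self.variants.get_loc(variant_id)
        return self.values[:, j]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy(), self.patients.copy(), self.variants.copy())

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.patients.equals(other.patients)
            and self.variants.equals(other.variants)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SourceCallSet:
    """One sequencing source's calls plus per-entry read depth."""

    source: str
    genotypes: GenotypeMatrix
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        self.depth = np.asarray(self.depth)
        if self.depth.shape != self.genotypes.values.shape:
            raise ValueError("depth matrix shape does not match genotype matrix")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class MergedCallSet:
    """Result of precedence-merging the three per-source call sets."""

    genotypes: GenotypeMatrix
    #: per-entry source used for the merged call ("UNKNOWN" if none known)
    source_provenance: np.ndarray
    #: per-variant alternate-allele frequency over non-UNKNOWN entries (NaN if none)
    cohort_af: pd.Series
    #: per-variant cross-source concordance, percent of patients in [0, 100]
    concordance_pct: pd.Series


@dataclass
class VariantRecord:
    """Annotation for one bi-allelic variant."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    population_af: float
    cadd_score: float = 0.0
    gene_id: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must lie in [0, 1]")
        if self.cadd_score < 0:
            raise ValueError("cadd_score must be >= 0")


def annotation_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Annotation table indexed by variant_id, one row per VariantRecord."""
    df = pd.DataFrame([asdict(v) for v in variants]).set_index("variant_id")
    return df


@dataclass
class EffectPlan:
    """Planted ground truth for a synthetic cohort.

    Hazard effects are log hazard ratios; eQTL effects are expression shifts
    in units of the per-gene SD applied to carriers; driver associations are
    odds ratios for somatic mutation given risk-allele carriage.
    """

    variant_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    eqtl_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    driver_assoc: dict[str, tuple[str, float]] = field(default_factory=dict)
    baseline_shape: float = 1.0
    baseline_scale: float = 365.0
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        for vid, (_, oratio) in self.driver_assoc.items():
            if oratio <= 0:
                raise ValueError(f"driver odds ratio for {vid} must be > 0")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline shape/scale must be > 0")

    def to_json(self) -> str:
        payload = {
            "variant_effects": self.variant_effects,
            "covariate_effects": self.covariate_effects,
            "eqtl_effects": {k: list(v) for k, v in self.eqtl_effects.items()},
            "driver_assoc": {k: list(v) for k, v in self.driver_assoc.items()},
            "baseline_shape": self.baseline_shape,
            "baseline_scale": self.baseline_scale,
            "censoring_rate": self.censoring_rate,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EffectPlan":
        d = json.loads(text)
        return cls(
            variant_effects=d.get("variant_effects", {}),
            covariate_effects=d.get("covariate_effects", {}),
            eqtl_effects={k: tuple(v) for k, v in d.get("eqtl_effects", {}).items()},
            driver_assoc={k: tuple(v) for k, v in d.get("driver_assoc", {}).items()},
            baseline_shape=d.get("baseline_shape", 1.0),
            baseline_scale=d.get("baseline_scale", 365.0),
            censoring_rate=d.get("censoring_rate", 0.3),
        )


@dataclass
class QcThresholds:
    """Discovery filters applied per (variant, cancer).

    Population AF and concordance are strict inequalities; the carrier count
    is "found in more than 14 patients", i.e. at least ``min_carriers``.
    """

    min_depth: int = 10
    min_population_af: float = 0.05
    min_carriers: int = 15
    min_concordance_pct: float = 90.0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_carriers < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_population_af <= 1.0:
            raise ValueError("min_population_af must lie in [0, 1]")
        if not 0.0 <= self.min_concordance_pct <= 100.0:
            raise ValueError("min_concordance_pct must lie in [0, 100]")


@dataclass
class ScanConfig:
    """Thresholds governing the six discovery analyses."""

    fdr_threshold: float = 0.10
    per_cancer_p: float = 0.05
    recurrence_min_cancers: int = 7
    recurrence_min_cancers_cadd: int = 5
    cadd_threshold: float = 25.0
    genotype_coding: str = "additive"  # or "dominant"
    group_min_carriers: int = 15

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if not 0.0 < self.per_cancer_p <= 1.0:
            raise ValueError("per_cancer_p must lie in (0, 1]")
        if self.genotype_coding not in ("additive", "dominant"):
            raise ValueError("genotype_coding must be 'additive' or 'dominant'")


@dataclass
class GroupSpec:
    """A pooled patient group: member cancers plus their selected covariates."""

    group_id: str
    cancers: list[str]
    covariates: Mapping[str, Sequence[str]]  # cancer code -> covariate names

    def __post_init__(self) -> None:
        if len(self.cancers) < 1:
            raise ValueError("a group needs at least one member cancer")
        for cancer in self.covariates:
            if cancer not in self.cancers:
                raise ValueError(f"covariates given for non-member cancer {cancer!r}")


@dataclass
class CoxResult:
    """One fitted Cox model: per-term estimates on the log-hazard scale."""

    terms: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {
            "log_hr": float(self.log_hr[i]),
            "hr": float(np.exp(self.log_hr[i])),
            "se": float(self.se[i]),
            "p": float(self.p[i]),
        }


@dataclass
class ScanHit:
    """One significant (variant, stratum) association from a discovery scan."""

    variant_id: str
    stratum: str  # cancer code or group id
    log_hr: float
    se: float
    p: float
    fdr: float
    analysis_id: int
    n: int = 0
    n_events: int = 0

    @property
    def direction(self) -> str:
        return "poor" if self.log_hr > 0 else "favorable"

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))


@dataclass
class AucSeries:
    """Time-dependent AUC for the clinical (C) vs clinical+variant (C+GV) model."""

    variant_id: str
    cancer: str
    eval_times: np.ndarray
    auc_c: np.ndarray
    auc_cgv: np.ndarray
    improvement_p: float = float("nan")

    @property
    def delta(self) -> np.ndarray:
        return self.auc_cgv - self.auc_c

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.delta))

    @property
    def se_delta(self) -> float:
        d = self.delta
        if len(d) < 2:
            return float("nan")
        return float(np.std(d, ddof=1) / np.sqrt(len(d)))


@dataclass
class DirectionIndex:
    """Direction-concordance summary for one variant across cancers."""

    variant_id: str
    n_poor: int
    n_favorable: int

    @property
    def index(self) -> float:
        total = self.n_poor + self.n_favorable
        if total == 0:
            raise ValueError("index undefined with no qualifying associations")
        return max(self.n_poor, self.n_favorable) / total


@dataclass
class EqtlCandidate:
    """A prognostic variant whose cis-expression signal chains consistently."""

    variant_id: str
    gene_id: str
    expression_p: float
    expression_direction: int  # +1 carriers higher, -1 carriers lower
    expression_log_hr: float
    expression_cox_p: float
    outcome_log_hr: float
    concordant: bool
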