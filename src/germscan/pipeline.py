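"""Pipeline orchestration: simulate -> merge-qc -> covariates -> scan ->
characterize -> evaluate-auc -> eqtl -> power -> report, driven by one YAML
config and a master seed.

Each stage reads its inputs from, and writes its outputs to, a workspace
directory, so any downstream stage can be rerun in isolation from serialized
upstream outputs.  Every output TSV carries the config hash and seed in
``# key=value`` header lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .datatypes import (
    EffectPlan,
    GenotypeMatrix,
    GroupSpec,
    QcThresholds,
    ScanConfig,
    SourceCallSet,
    SOURCES,
)
from . import characterize as chz
from . import eqtl as eq
from . import mergeqc as mq
from . import prediction as pred
from . import synthetic as syn
from .discovery import group_scan, per_cancer_scan, recurrence_filter
from .survival import cox_power, lasso_select_covariates, scan_alpha

__all__ = ["RunConfig", "load_config", "run", "STAGES"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration failed validation."""


class RunConfig:
    """Validated pipeline configuration.

    Exactly one of a ``simulate`` block or an ``inputs`` block (paths to
    VCFs and TSVs) must be present.
    """

    def __init__(self, raw: Mapping[str, Any]):
        self.raw = dict(raw)
        self.seed = int(raw.get("seed", 0))
        has_sim = "simulate" in raw
        has_inputs = "inputs" in raw
        if has_sim == has_inputs:
            raise ConfigError(
                "config must contain exactly one of 'simulate' or 'inputs'"
            )
        self.simulate = raw.get("simulate")
        self.inputs = raw.get("inputs")
        if self.inputs is not None:
            for key in ("vcf_normal", "vcf_tumor", "vcf_rna", "clinical", "annotation"):
                if key not in self.inputs:
                    raise ConfigError(f"inputs block missing required field '{key}'")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"inputs.{key}: file not found: {self.inputs[key]}")
        try:
            self.qc = QcThresholds(**raw.get("qc", {}))
            self.scan = ScanConfig(**raw.get("scan", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid qc/scan block: {exc}") from exc
        self.groups = [
            GroupSpec(
                group_id=g["group_id"],
                cancers=list(g["cancers"]),
                covariates=g.get("covariates", {}),
            )
            for g in raw.get("groups", [])
        ]
        self.analyses = list(raw.get("analyses", [1, 2, 3, 4, 5, 6]))
        self.power = dict(raw.get("power", {}))

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def meta(self) -> dict[str, str]:
        return {"config_hash": self.config_hash, "seed": str(self.seed)}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Workspace helpers


def _load_clinical(outdir: Path) -> pd.DataFrame:
    return gio.read_tsv(outdir / "clinical.tsv")


def _load_annotation(outdir: Path) -> pd.DataFrame:
    return gio.read_tsv(outdir / "annotation.tsv")


def _load_merged(outdir: Path) -> GenotypeMatrix:
    df = gio.read_tsv(outdir / "merged_genotypes.tsv")
    return GenotypeMatrix(df.to_numpy(dtype=np.int8), df.index, df.columns)


def _load_survivors(outdir: Path) -> dict[str, list[str]]:
    return json.loads((outdir / "qc_survivors.json").read_text())


def _load_covariates(outdir: Path) -> dict[str, list[str]]:
    return json.loads((outdir / "covariates.json").read_text())


def _require(outdir: Path, names: list[str], stage: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage '{stage}': missing upstream outputs {missing} in {outdir}"
        )


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate a synthetic cohort and serialize every input layer."""
    if cfg.simulate is None:
        raise ConfigError("stage 'simulate' requires a simulate block")
    s = cfg.simulate
    seed = cfg.seed
    variants = syn.generate_variants(
        n_variants=int(s.get("n_variants", 200)),
        af_range=tuple(s.get("af_range", (0.05, 0.5))),
        cadd_high_fraction=float(s.get("cadd_high_fraction", 0.1)),
        seed=seed,
    )
    ann = pd.DataFrame(
        [vars(v) for v in variants]
    ).set_index("variant_id")
    cancers = s.get("cancers", {"X": 0.5, "Y": 0.5})
    if isinstance(cancers, dict):
        codes, props = list(cancers), list(cancers.values())
    else:
        codes, props = list(cancers), None
    cohort = syn.generate_baseline_cohort(
        int(s.get("n_patients", 600)),
        codes,
        s.get("covariates", {"age": {"dist": "normal", "mean": 60, "sd": 10}}),
        seed=seed,
        cancer_proportions=props,
    )
    truth = EffectPlan(
        variant_effects={k: float(v) for k, v in s.get("effects", {}).get("variant_effects", {}).items()},
        covariate_effects={k: float(v) for k, v in s.get("effects", {}).get("covariate_effects", {}).items()},
        eqtl_effects={k: tuple(v) for k, v in s.get("effects", {}).get("eqtl_effects", {}).items()},
        driver_assoc={k: tuple(v) for k, v in s.get("effects", {}).get("driver_assoc", {}).items()},
        baseline_shape=float(s.get("effects", {}).get("baseline_shape", 1.0)),
        baseline_scale=float(s.get("effects", {}).get("baseline_scale", 365.0)),
        censoring_rate=float(s.get("effects", {}).get("censoring_rate", 0.3)),
    )
    genotypes = syn.generate_genotypes(variants, len(cohort), seed=seed)
    cohort = syn.simulate_outcomes(cohort, genotypes, truth, seed=seed)
    call_sets = syn.corrupt_to_call_sets(
        genotypes,
        discordance_rate=float(s.get("discordance_rate", 0.02)),
        depth_means=s.get("depth_means"),
        seed=seed,
    )
    gene_ids = list(ann["gene_id"])
    expression = syn.simulate_expression(genotypes, truth, gene_ids, seed=seed)
    n_drivers = int(s.get("n_driver_genes", 10))
    driver_genes = [f"driver_{i}" for i in range(n_drivers)]
    for _, (g, _o) in truth.driver_assoc.items():
        if g not in driver_genes:
            driver_genes.append(g)
    drivers = syn.simulate_driver_mutations(
        genotypes,
        truth,
        driver_genes,
        background_rate=float(s.get("background_mutation_rate", 0.1)),
        seed=seed,
    )

    outdir.mkdir(parents=True, exist_ok=True)
    meta = cfg.meta()
    gio.write_vcf(outdir / "wxs_normal.vcf", call_sets["WXS_NORMAL"], ann)
    gio.write_vcf(outdir / "wxs_tumor.vcf", call_sets["WXS_TUMOR"], ann)
    gio.write_vcf(outdir / "rna_tumor.vcf", call_sets["RNA_TUMOR"], ann)
    gio.write_tsv(cohort, outdir / "clinical.tsv", meta)
    gio.write_tsv(ann, outdir / "annotation.tsv", meta)
    gio.write_tsv(expression, outdir / "expression.tsv", meta)
    gio.write_tsv(drivers, outdir / "drivers.tsv", meta)
    gio.write_truth(truth, outdir / "truth.json")
    # planted-truth genotypes for oracle comparisons
    gio.write_tsv(genotypes.to_frame(), outdir / "truth_genotypes.tsv", meta)
    # simple one-transcript-per-gene model around each variant for region calls
    _write_gene_model(outdir, ann)


def _write_gene_model(outdir: Path, ann: pd.DataFrame) -> None:
    """BED12 with one transcript per annotated gene spanning its variant."""
    rows = []
    for vid, r in ann.iterrows():
        pos = int(r["pos"])
        start0 = max(pos - 300, 0)  # BED 0-based
        end = pos + 700
        rows.append(
            f"{r['chrom']}\t{start0}\t{end}\t{r['gene_id']}\t0\t{r['strand']}"
            f"\t{start0 + 100}\t{end - 100}\t0\t1\t{end - start0}\t0"
        )
    (outdir / "gene_model.bed").write_text("\n".join(rows) + "\n")


def stage_merge_qc(cfg: RunConfig, outdir: Path) -> None:
    """Mask low-depth calls, merge the three sources, compute per-cancer
    concordance, and apply the discovery filters."""
    if cfg.inputs is not None:
        paths = {
            "WXS_NORMAL": cfg.inputs["vcf_normal"],
            "WXS_TUMOR": cfg.inputs["vcf_tumor"],
            "RNA_TUMOR": cfg.inputs["vcf_rna"],
        }
        clinical = gio.read_tsv(cfg.inputs["clinical"])
        ann = gio.read_tsv(cfg.inputs["annotation"])
    else:
        _require(outdir, ["wxs_normal.vcf", "clinical.tsv", "annotation.tsv"], "merge-qc")
        paths = {
            "WXS_NORMAL": outdir / "wxs_normal.vcf",
            "WXS_TUMOR": outdir / "wxs_tumor.vcf",
            "RNA_TUMOR": outdir / "rna_tumor.vcf",
        }
        clinical = _load_clinical(outdir)
        ann = _load_annotation(outdir)
    patients = list(clinical.index)
    masked: dict[str, SourceCallSet] = {}
    for source in SOURCES:
        cs = gio.read_vcf(paths[source], source, patients=patients)
        masked[source] = mq.mask_low_depth(cs, cfg.qc.min_depth)
    merged = mq.merge_calls(masked["WXS_NORMAL"], masked["WXS_TUMOR"], masked["RNA_TUMOR"])
    cancer_of_patient = clinical["cancer"]
    per_cancer_conc = {
        cancer: mq.concordance_percent(
            masked["WXS_NORMAL"], masked["WXS_TUMOR"], masked["RNA_TUMOR"],
            patients=clinical.index[cancer_of_patient == cancer],
        )
        for cancer in sorted(cancer_of_patient.unique())
    }
    report = mq.qc_filter(merged, ann, cfg.qc, cancer_of_patient, per_cancer_conc)
    af_corr = mq.cross_source_af_correlation(masked, merged)

    meta = cfg.meta()
    gio.write_tsv(merged.genotypes.to_frame(), outdir / "merged_genotypes.tsv", meta)
    qc_summary = pd.DataFrame(
        {"concordance_pct": merged.concordance_pct, "cohort_af": merged.cohort_af}
    )
    gio.write_tsv(qc_summary, outdir / "qc_summary.tsv", meta)
    if report.detail is not None:
        gio.write_tsv(report.detail, outdir / "qc_report.tsv", meta, index=False)
    gio.write_tsv(af_corr, outdir / "af_correlation.tsv", meta)
    (outdir / "qc_survivors.json").write_text(
        json.dumps(report.survivors, indent=2, sort_keys=True)
    )
    (outdir / "qc_exclusions.json").write_text(
        json.dumps(report.exclusions, indent=2, sort_keys=True)
    )


def stage_covariates(cfg: RunConfig, outdir: Path) -> None:
    """Lasso-select the clinical covariates to control per cancer."""
    _require(outdir, ["clinical.tsv"], "covariates")
    clinical = _load_clinical(outdir)
    candidates = [
        c for c in clinical.columns if c not in ("cancer", "time", "event")
    ]
    selected: dict[str, list[str]] = {}
    for cancer in sorted(clinical["cancer"].unique()):
        sub = clinical[clinical["cancer"] == cancer]
        if sub["event"].sum() < 2:
            selected[cancer] = []
            continue
        selected[cancer] = lasso_select_covariates(
            sub[candidates],
            sub["time"].to_numpy(),
            sub["event"].to_numpy(),
            seed=cfg.seed,
        )
    (outdir / "covariates.json").write_text(json.dumps(selected, indent=2, sort_keys=True))


def stage_scan(cfg: RunConfig, outdir: Path) -> None:
    """Run the requested discovery analyses and serialize results + hits."""
    _require(
        outdir,
        ["merged_genotypes.tsv", "qc_survivors.json", "covariates.json", "clinical.tsv"],
        "scan",
    )
    genotypes = _load_merged(outdir)
    clinical = _load_clinical(outdir)
    ann = _load_annotation(outdir)
    survivors = _load_survivors(outdir)
    covariates = _load_covariates(outdir)
    meta = cfg.meta()

    groups = cfg.groups or _default_groups(clinical, covariates)
    for g in groups:
        g.covariates = {c: covariates.get(c, []) for c in g.cancers}

    def _save(results, hits, k):
        gio.write_tsv(results, outdir / f"analysis{k}_results.tsv", meta, index=False)
        hits_df = pd.DataFrame(
            [
                {
                    "variant_id": h.variant_id,
                    "stratum": h.stratum,
                    "log_hr": h.log_hr,
                    "hr": h.hr,
                    "se": h.se,
                    "p": h.p,
                    "fdr": h.fdr,
                    "direction": h.direction,
                    "n": h.n,
                    "n_events": h.n_events,
                }
            for h in hits],
            columns=["variant_id", "stratum", "log_hr", "hr", "se", "p", "fdr",
                     "direction", "n", "n_events"],
        )
        gio.write_tsv(hits_df, outdir / f"analysis{k}_hits.tsv", meta, index=False)

    if 1 in cfg.analyses or 2 in cfg.analyses:
        res1, hits1 = per_cancer_scan(
            genotypes, clinical, survivors, covariates, cfg.scan
        )
        _save(res1, hits1, 1)
        if 2 in cfg.analyses:
            rec = recurrence_filter(res1, cfg.scan.recurrence_min_cancers, cfg.scan.per_cancer_p)
            gio.write_tsv(rec, outdir / "analysis2_recurrent.tsv", meta, index=False)
    if 3 in cfg.analyses and groups:
        res3, hits3 = group_scan(
            groups, genotypes, clinical, cfg.scan, candidate_variants=survivors
        )
        _save(res3, hits3, 3)
    if 4 in cfg.analyses or 5 in cfg.analyses:
        res4, hits4 = per_cancer_scan(
            genotypes, clinical, survivors, covariates, cfg.scan,
            annotations=ann, cadd_filter=True,
        )
        _save(res4, hits4, 4)
        if 5 in cfg.analyses:
            rec5 = recurrence_filter(
                res4, cfg.scan.recurrence_min_cancers_cadd, cfg.scan.per_cancer_p
            )
            gio.write_tsv(rec5, outdir / "analysis5_recurrent.tsv", meta, index=False)
    if 6 in cfg.analyses and groups:
        res6, hits6 = group_scan(
            groups, genotypes, clinical, cfg.scan, candidate_variants=survivors,
            annotations=ann, cadd_filter=True,
        )
        _save(res6, hits6, 6)


def _default_groups(clinical: pd.DataFrame, covariates) -> list[GroupSpec]:
    cancers = sorted(clinical["cancer"].unique())
    if len(cancers) < 2:
        return []
    return [GroupSpec(group_id="all", cancers=cancers, covariates={})]


def stage_characterize(cfg: RunConfig, outdir: Path) -> None:
    """Direction concordance, HR correlations, GWAS-style characteristics,
    pair independence, and driver-mutation association for analysis-1 hits."""
    _require(outdir, ["analysis1_results.tsv", "analysis1_hits.tsv"], "characterize")
    results = gio.read_tsv(outdir / "analysis1_results.tsv", index_col=None)
    hits = gio.read_tsv(outdir / "analysis1_hits.tsv", index_col=None)
    genotypes = _load_merged(outdir)
    ann = _load_annotation(outdir)
    clinical = _load_clinical(outdir)
    covariates = _load_covariates(outdir)
    qc_summary = gio.read_tsv(outdir / "qc_summary.tsv")
    meta = cfg.meta()
    summary: dict[str, Any] = {}

    indices, expected, p = chz.direction_index_stats(results)
    summary["direction_index"] = {
        "n_variants": len(indices),
        "expected_index": expected,
        "mean_index": float(np.mean([d.index for d in indices])) if indices else None,
        "wilcoxon_p": p,
    }
    for direction in ("poor", "favorable"):
        try:
            rho, pv = chz.hr_pair_correlation(results, direction=direction)
            summary[f"hr_correlation_{direction}"] = {"rho": rho, "p": pv}
        except ValueError:
            summary[f"hr_correlation_{direction}"] = None

    if len(hits):
        hits_af = hits.merge(
            ann[["population_af"]], left_on="variant_id", right_index=True
        )
        pruned = chz.ld_prune(list(hits_af["variant_id"].unique()), genotypes, ann)
        hits_pruned = hits_af[hits_af["variant_id"].isin(pruned)]
        p_minor, table = chz.minor_allele_risk_test(hits_pruned)
        rho_af, p_af = chz.effect_size_af_correlation(hits_pruned)
        summary["minor_allele"] = {"p": p_minor, "table": table.tolist()}
        summary["effect_size_af"] = {"rho": rho_af, "p": p_af}
        # genomic regions
        bed = outdir / "gene_model.bed"
        if bed.exists():
            transcripts = chz.read_bed12(bed)
            region_rows = []
            for vid in pruned:
                labels = chz.classify_region(
                    str(ann.loc[vid, "chrom"]), int(ann.loc[vid, "pos"]), transcripts
                )
                region_rows.append({"variant_id": vid, "regions": ";".join(sorted(labels))})
            gio.write_tsv(
                pd.DataFrame(region_rows), outdir / "regions.tsv", meta, index=False
            )
        # pair independence: pooled over cancers, poor-direction hits only
        tables = []
        for cancer, grp in hits_pruned[hits_pruned["log_hr"] > 0].groupby("stratum"):
            vids = list(grp["variant_id"].unique())
            if len(vids) < 2:
                continue
            mask = clinical["cancer"] == cancer
            sub_g = GenotypeMatrix(
                genotypes.values[mask.to_numpy()], clinical.index[mask], genotypes.variants
            )
            tables.append(
                chz.pair_hr_table(vids, sub_g, clinical[mask], covariates.get(cancer, []))
            )
        pair_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        if len(pair_table):
            gio.write_tsv(pair_table, outdir / "pair_independence.tsv", meta, index=False)
            summary["pair_independence"] = {
                "n_pairs": len(pair_table),
                "p": chz.pair_independence_test(pair_table),
            }
    drivers_path = outdir / "drivers.tsv"
    if drivers_path.exists() and len(hits):
        drivers = gio.read_tsv(drivers_path)
        tested = sorted(set(results["variant_id"]))
        poor_hits = sorted(set(hits.loc[hits["log_hr"] > 0, "variant_id"]))
        scan = chz.driver_association_scan(genotypes, drivers, poor_hits, tested)
        gio.write_tsv(scan["pairs"], outdir / "driver_pairs.tsv", meta, index=False)
        summary["driver_association"] = {
            "enrichment_or": scan["enrichment_or"],
            "enrichment_p": scan["enrichment_p"],
        }
    (outdir / "characterization.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )


def stage_evaluate_auc(cfg: RunConfig, outdir: Path) -> None:
    """ΔAUC series (C vs C+GV) for every analysis-1 hit."""
    _require(outdir, ["analysis1_hits.tsv", "clinical.tsv"], "evaluate-auc")
    hits = gio.read_tsv(outdir / "analysis1_hits.tsv", index_col=None)
    genotypes = _load_merged(outdir)
    clinical = _load_clinical(outdir)
    covariates = _load_covariates(outdir)
    meta = cfg.meta()
    rows, detail = [], []
    for h in hits.itertuples():
        mask = (clinical["cancer"] == h.stratum).to_numpy()
        dos = genotypes.dosage(h.variant_id)[mask]
        try:
            series = pred.delta_auc_series(
                clinical[mask], covariates.get(h.stratum, []), dos,
                variant_id=h.variant_id, cancer=h.stratum,
            )
        except ValueError:
            continue
        rows.append(
            {
                "variant_id": h.variant_id,
                "cancer": h.stratum,
                "mean_delta_auc": series.mean_delta,
                "se_delta_auc": series.se_delta,
                "improvement_p": series.improvement_p,
                "n_times": len(series.eval_times),
            }
        )
        for t, ac, ag in zip(series.eval_times, series.auc_c, series.auc_cgv):
            detail.append(
                {"variant_id": h.variant_id, "cancer": h.stratum, "time": t,
                 "auc_c": ac, "auc_cgv": ag, "delta": ag - ac}
            )
    gio.write_tsv(pd.DataFrame(rows), outdir / "auc_summary.tsv", meta, index=False)
    gio.write_tsv(pd.DataFrame(detail), outdir / "auc_detail.tsv", meta, index=False)


def stage_eqtl(cfg: RunConfig, outdir: Path) -> None:
    """cis-eQTL triage of analysis-1 hits against the expression matrix."""
    _require(outdir, ["analysis1_hits.tsv", "expression.tsv"], "eqtl")
    hits = gio.read_tsv(outdir / "analysis1_hits.tsv", index_col=None)
    genotypes = _load_merged(outdir)
    clinical = _load_clinical(outdir)
    ann = _load_annotation(outdir)
    covariates = _load_covariates(outdir)
    expression = gio.read_tsv(outdir / "expression.tsv")
    retained, evaluated = eq.concordant_eqtl_scan(
        hits, genotypes, expression, clinical, ann, covariates
    )
    df = pd.DataFrame([vars(c) for c in evaluated])
    df["retained"] = [c in retained for c in evaluated]
    gio.write_tsv(df, outdir / "eqtl_candidates.tsv", cfg.meta(), index=False)


def stage_power(cfg: RunConfig, outdir: Path) -> None:
    """Analytic per-cancer power over the hazard-ratio grid.

    Samples up to ``power.max_variants`` QC-passing variants per cancer
    (seeded) and reports, per hazard ratio, the fraction with > 80% power at
    the scan-wide significance level.
    """
    _require(outdir, ["qc_survivors.json", "merged_genotypes.tsv"], "power")
    survivors = _load_survivors(outdir)
    genotypes = _load_merged(outdir)
    clinical = _load_clinical(outdir)
    hr_grid = list(cfg.power.get("hazard_ratios", [2, 3, 4, 5, 10, 15, 20]))
    max_variants = int(cfg.power.get("max_variants", 10_000))
    rng = syn.child_rng(cfg.seed, "power-sampling")
    rows = []
    for cancer, vids in sorted(survivors.items()):
        if not vids:
            continue
        vids = list(vids)
        if len(vids) > max_variants:
            vids = list(rng.choice(vids, size=max_variants, replace=False))
        alpha = scan_alpha(len(survivors[cancer]))
        mask = (clinical["cancer"] == cancer).to_numpy()
        sub = clinical[mask]
        event_rate = float(sub["event"].mean())
        n = int(mask.sum())
        for vid in vids:
            dos = genotypes.dosage(vid)[mask]
            known = dos != -1
            if known.sum() == 0:
                continue
            exposed = float(((dos >= 1) & known).sum() / known.sum())
            if not 0 < exposed < 1:
                continue
            for hr in hr_grid:
                rows.append(
                    {
                        "cancer": cancer,
                        "variant_id": vid,
                        "hr": hr,
                        "power": cox_power(n, event_rate, exposed, hr, alpha),
                    }
                )
    table = pd.DataFrame(rows)
    gio.write_tsv(table, outdir / "power.tsv", cfg.meta(), index=False)
    if len(table):
        frac = (
            table.assign(above=table["power"] > 0.8)
            .groupby(["cancer", "hr"])["above"]
            .mean()
            .reset_index()
            .rename(columns={"above": "fraction_above_80pct"})
        )
    else:
        frac = pd.DataFrame(columns=["cancer", "hr", "fraction_above_80pct"])
    gio.write_tsv(frac, outdir / "power_summary.tsv", cfg.meta(), index=False)


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    """Aggregate per-analysis hit counts and headline statistics."""
    report: dict[str, Any] = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    for k in (1, 3, 4, 6):
        path = outdir / f"analysis{k}_hits.tsv"
        if path.exists():
            report[f"analysis{k}_hits"] = int(len(gio.read_tsv(path, index_col=None)))
    for k in (2, 5):
        path = outdir / f"analysis{k}_recurrent.tsv"
        if path.exists():
            report[f"analysis{k}_recurrent"] = int(len(gio.read_tsv(path, index_col=None)))
    char_path = outdir / "characterization.json"
    if char_path.exists():
        report["characterization"] = json.loads(char_path.read_text())
    auc_path = outdir / "auc_summary.tsv"
    if auc_path.exists():
        auc = gio.read_tsv(auc_path, index_col=None)
        if len(auc):
            report["auc"] = {
                "n_variants": int(len(auc)),
                "mean_delta_auc": float(auc["mean_delta_auc"].mean()),
                "n_significant_improvement": int((auc["improvement_p"] < 0.05).sum()),
            }
    eqtl_path = outdir / "eqtl_candidates.tsv"
    if eqtl_path.exists():
        cand = gio.read_tsv(eqtl_path, index_col=None)
        report["eqtl"] = {
            "n_evaluated": int(len(cand)),
            "n_retained": int(cand["retained"].sum()) if len(cand) else 0,
        }
    power_path = outdir / "power_summary.tsv"
    if power_path.exists():
        frac = gio.read_tsv(power_path, index_col=None)
        report["power_fraction_above_80pct"] = {
            f"HR={r.hr:g}": float(r.fraction_above_80pct)
            for r in frac.groupby("hr")["fraction_above_80pct"].mean().reset_index().itertuples()
        }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float)
    )


STAGES = {
    "simulate": stage_simulate,
    "merge-qc": stage_merge_qc,
    "covariates": stage_covariates,
    "scan": stage_scan,
    "characterize": stage_characterize,
    "evaluate-auc": stage_evaluate_auc,
    "eqtl": stage_eqtl,
    "power": stage_power,
    "report": stage_report,
}


def run(cfg: RunConfig, outdir, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in dependency order; returns the workspace."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = list(STAGES)
    if cfg.simulate is None:
        order.remove("simulate")
    if stages is not None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in order if s in stages]
    for name in order:
        log.info("stage %s", name)
        STAGES[name](cfg, outdir)
    return outdir
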