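"""On-disk formats: per-source VCFs (FORMAT GT and DP), clinical / annotation /
expression / driver TSVs, and the planted-truth JSON.

VCFs are written uncompressed with one sample column per patient and read
back through cyvcf2; multi-allelic records are split into bi-allelic variants
on read, with dosage counted per alternate allele.  TSV outputs may carry
``# key=value`` header lines (config hash, seed) which readers skip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import UNKNOWN, EffectPlan, GenotypeMatrix, SourceCallSet

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_tsv",
    "read_tsv",
    "write_truth",
    "read_truth",
]

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", UNKNOWN: "./."}


def write_vcf(path, calls: SourceCallSet, annotations: pd.DataFrame) -> None:
    """Write one source's calls as an uncompressed VCF with GT and DP."""
    path = Path(path)
    gm = calls.genotypes
    ann = annotations.loc[gm.variants]
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=germscan:{calls.source}\n")
        for chrom in dict.fromkeys(ann["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.patients)
            + "\n"
        )
        for j, vid in enumerate(gm.variants):
            row = ann.iloc[j]
            samples = "\t".join(
                f"{_GT_STRING[int(g)]}:{int(d)}"
                for g, d in zip(gm.values[:, j], calls.depth[:, j])
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT:DP\t{samples}\n"
            )


def read_vcf(
    path, source: str, patients: Sequence[str] | None = None
) -> SourceCallSet:
    """Read a per-source VCF into a SourceCallSet.

    ``patients`` fixes the patient universe: samples absent from the file
    become all-UNKNOWN with depth 0 (a missing assay, not an error).
    Multi-allelic records are split; each alternate allele becomes its own
    variant with id ``<id>`` or ``<id>_<k>`` and per-allele dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    file_samples = list(vcf.samples)
    ids, columns, depths = [], [], []
    for v in vcf:
        dp = v.format("DP")
        dp = (
            dp[:, 0].astype(int)
            if dp is not None
            else np.zeros(len(file_samples), dtype=int)
        )
        genos = v.genotypes  # [allele1, allele2, phased] per sample
        for k, _alt in enumerate(v.ALT, start=1):
            dos = np.empty(len(file_samples), dtype=np.int8)
            for s, g in enumerate(genos):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    dos[s] = UNKNOWN
                else:
                    dos[s] = sum(1 for a in alleles if a == k)
            vid = v.ID if (v.ID and len(v.ALT) == 1) else f"{v.ID or v.POS}_{k}"
            ids.append(vid)
            columns.append(dos)
            depths.append(dp.copy())
    values = (
        np.column_stack(columns) if columns else np.empty((len(file_samples), 0), np.int8)
    )
    depth = (
        np.column_stack(depths) if depths else np.empty((len(file_samples), 0), int)
    )
    gm = GenotypeMatrix(values, pd.Index(file_samples), pd.Index(ids))
    if patients is not None:
        idx = pd.Index(patients, name="patient_id")
        pos = pd.Index(file_samples).get_indexer(idx)
        full_values = np.full((len(idx), len(ids)), UNKNOWN, dtype=np.int8)
        full_depth = np.zeros((len(idx), len(ids)), dtype=int)
        present = pos >= 0
        full_values[present] = values[pos[present]]
        full_depth[present] = depth[pos[present]]
        gm = GenotypeMatrix(full_values, idx, pd.Index(ids))
        depth = full_depth
    return SourceCallSet(source=source, genotypes=gm, depth=depth)


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, str] | None = None, index: bool = True) -> None:
    """TSV with optional ``# key=value`` provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_truth(plan: EffectPlan, path) -> None:
    Path(path).write_text(plan.to_json() + "\n")


def read_truth(path) -> EffectPlan:
    return EffectPlan.from_json(Path(path).read_text())
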