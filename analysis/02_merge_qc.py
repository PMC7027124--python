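"""Merge the three per-source call sets (normal exome > tumor exome > tumor
RNA), mask calls under 10 reads, and apply the three discovery filters:
population AF > 5%, >= 15 carriers per cancer, > 90% cross-source
concordance per cancer.  Reports survivor counts and the cross-source
allele-frequency agreement."""

import json

import pandas as pd

from common import CONFIG, OUTDIR
from germscan.pipeline import run


def main() -> None:
    run(CONFIG, OUTDIR, stages=["merge-qc"])
    survivors = json.loads((OUTDIR / "qc_survivors.json").read_text())
    exclusions = json.loads((OUTDIR / "qc_exclusions.json").read_text())
    for cancer in sorted(survivors):
        print(
            f"{cancer}: {len(survivors[cancer])} variants pass QC "
            f"(excluded by filter: {exclusions[cancer]})"
        )
    af = pd.read_csv(OUTDIR / "af_correlation.tsv", sep="\t", comment="#", index_col=0)
    print("\ncross-source allele-frequency Spearman rho:")
    print(af.round(4).to_string())


if __name__ == "__main__":
    main()
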