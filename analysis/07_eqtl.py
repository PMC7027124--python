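"""Triage analysis-1 hits for cis-eQTL mechanisms: carrier-status expression
shift (rank-sum) plus covariate-adjusted expression-outcome Cox, retained
only when both p < 0.10 and the direction chain is self-consistent."""

import pandas as pd

from common import CONFIG, OUTDIR
from germscan.pipeline import run


def main() -> None:
    run(CONFIG, OUTDIR, stages=["eqtl"])
    cand = pd.read_csv(OUTDIR / "eqtl_candidates.tsv", sep="\t", comment="#")
    print(f"{len(cand)} hit/gene pairs evaluated; {int(cand['retained'].sum())} retained")
    kept = cand[cand["retained"]]
    if len(kept):
        print(kept[["variant_id", "gene_id", "expression_p", "expression_direction",
                    "expression_log_hr", "expression_cox_p"]].to_string(index=False))


if __name__ == "__main__":
    main()
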