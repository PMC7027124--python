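"""Analytic power of the per-cancer scans: for each QC-passing variant, the
Schoenfeld-formula power at the scan-wide significance level (0.10 / number
of variants tested in the cancer), across hazard ratios 2-20; reports the
fraction of variants with > 80% power, then assembles the final report."""

import json

import pandas as pd

from common import CONFIG, OUTDIR
from germscan.pipeline import run


def main() -> None:
    run(CONFIG, OUTDIR, stages=["power", "report"])
    frac = pd.read_csv(OUTDIR / "power_summary.tsv", sep="\t", comment="#")
    table = frac.pivot(index="cancer", columns="hr", values="fraction_above_80pct")
    print("fraction of variants with > 80% power:")
    print(table.round(3).to_string())
    report = json.loads((OUTDIR / "report.json").read_text())
    print(f"\nfull report written to {OUTDIR / 'report.json'}")
    print(json.dumps(report, indent=1, default=float)[:800])


if __name__ == "__main__":
    main()
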