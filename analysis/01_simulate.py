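"""Generate the demo cohort: three cancers, 900 patients, 300 variants with
four planted prognostic effects, three corrupted call sets, expression with
one planted cis-eQTL and a driver-mutation table with one planted
association.  Writes VCFs/TSVs and the planted-truth JSON under
results/demo/."""

import json

from common import CONFIG, OUTDIR, PLANTED
from germscan.pipeline import run


def main() -> None:
    run(CONFIG, OUTDIR, stages=["simulate"])
    truth = json.loads((OUTDIR / "truth.json").read_text())
    print(f"wrote demo cohort to {OUTDIR}")
    print(f"planted prognostic variants: {PLANTED}")
    print(f"planted log hazard ratios : {truth['variant_effects']}")
    print(f"planted eQTL              : {truth['eqtl_effects']}")
    print(f"planted driver association: {truth['driver_assoc']}")


if __name__ == "__main__":
    main()
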