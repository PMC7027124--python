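"""Select the clinical covariates to control per cancer by cross-validated
Lasso-Cox.  Age and high stage carry planted effects; the race component is
noise and should usually be dropped."""

import json

from common import CONFIG, OUTDIR
from germscan.pipeline import run


def main() -> None:
    run(CONFIG, OUTDIR, stages=["covariates"])
    selected = json.loads((OUTDIR / "covariates.json").read_text())
    for cancer, covs in sorted(selected.items()):
        print(f"{cancer}: selected {covs or '(none)'}")


if __name__ == "__main__":
    main()
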