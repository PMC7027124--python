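"""Characterize the analysis-1 hits: direction-concordance index vs its
empirical expectation, hazard-ratio correlations across cancers,
minor-allele risk enrichment, effect-size vs allele frequency, genomic
regions, pair-independence of co-carried risk variants, and association
with somatic driver mutations."""

import json

from common import CONFIG, OUTDIR
from germscan.pipeline import run


def main() -> None:
    run(CONFIG, OUTDIR, stages=["characterize"])
    s = json.loads((OUTDIR / "characterization.json").read_text())
    di = s["direction_index"]
    print(
        f"direction concordance: {di['n_variants']} variants, "
        f"mean index {di['mean_index']:.3f} vs expected {di['expected_index']:.3f} "
        f"(p={di['wilcoxon_p']:.3g})"
    )
    if s.get("minor_allele"):
        print(f"minor-allele risk enrichment: one-sided Fisher p={s['minor_allele']['p']:.3g}")
    if s.get("effect_size_af"):
        print(
            f"effect size vs AF: Spearman rho={s['effect_size_af']['rho']:.3f} "
            f"(p={s['effect_size_af']['p']:.3g})"
        )
    if s.get("pair_independence"):
        pi = s["pair_independence"]
        print(
            f"pair independence: {pi['n_pairs']} pairs, one-sided signed-rank "
            f"p={pi['p']:.3g} for HR(both het) > HR(one het)"
        )
    if s.get("driver_association"):
        da = s["driver_association"]
        print(
            f"driver-mutation association: enrichment OR={da['enrichment_or']:.3g}, "
            f"p={da['enrichment_p']:.3g}"
        )


if __name__ == "__main__":
    main()
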