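"""Shared demo-cohort configuration for the numbered analysis scripts.

Three synthetic cancers of ~300 patients each, 300 common variants, four
planted prognostic variants (log HRs ±ln 3 and ln 4), one planted cis-eQTL
and one planted driver-gene association — the conditions every script in
this directory analyses.  All scripts write into results/demo/.
"""

from pathlib import Path

from germscan.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
OUTDIR = ROOT / "results" / "demo"

CONFIG = RunConfig(
    {
        "seed": 20260920,
        "simulate": {
            "n_patients": 900,
            "n_variants": 300,
            "cancers": {"BRX": 0.34, "LUX": 0.33, "KDX": 0.33},
            "covariates": {
                "age": {"dist": "normal", "mean": 60, "sd": 10},
                "stage_high": {"dist": "binary", "p": 0.4},
                "race_pc1": {"dist": "normal", "mean": 0, "sd": 1},
            },
            "effects": {
                "covariate_effects": {"age": 0.03, "stage_high": 0.6},
                "variant_effects": {
                    "v00010": 1.3862943611198906,  # ln 4, poor outcome
                    "v00050": 1.0986122886681098,  # ln 3, poor outcome
                    "v00120": -1.0986122886681098,  # ln 3 protective
                    "v00200": 1.3862943611198906,  # ln 4, poor outcome
                },
                "eqtl_effects": {"v00010": ["gene_00010", 1.5]},
                "driver_assoc": {"v00010": ["driver_0", 5.0]},
                "censoring_rate": 0.3,
            },
            "discordance_rate": 0.02,
        },
        "groups": [{"group_id": "g_all", "cancers": ["BRX", "LUX", "KDX"]}],
    }
)

PLANTED = ["v00010", "v00050", "v00120", "v00200"]
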