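#!/usr/bin/env python
"""Generate the three synthetic input classes with planted ground truth.

Writes, under results/data/:
  spots.tsv           long-format spot map, one pair planted at OR 2.17
  expression.tsv      z-scored gene x patient expression (one prognostic gene)
  clinical.tsv        survival times (days) and event indicators
  panel.tsv           co-culture fold-change panel (chain indirect = 0.4)
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import stromalink as sl
from stromalink.coloc import write_spot_matrix_long
from stromalink.crosstalk import write_panel

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path(__file__).resolve().parent.parent / "results" / "data"
out.mkdir(parents=True, exist_ok=True)

spot_cfg = sl.SpotSimConfig(
    n_spots=20000, grid_shape=(200, 100),
    pair_target_or={("tumor", "myCAF"): 2.17}, seed=args.seed,
)
write_spot_matrix_long(sl.gen_spot_map(spot_cfg), out / "spots.tsv")

surv_cfg = sl.SurvivalSimConfig(seed=args.seed + 7, signal_genes={"g0000": 1.0})
cohort = sl.gen_survival_cohort(surv_cfg)
cohort.expression.to_csv(out / "expression.tsv", sep="\t")
pd.DataFrame(
    {
        "patient_id": cohort.patients,
        "time_days": cohort.time.values,
        "event": cohort.event.values,
        "endpoint": cohort.endpoint,
    }
).to_csv(out / "clinical.tsv", sep="\t", index=False)

panel_cfg = sl.CoCultureSimConfig(seed=args.seed + 21)
panel = sl.gen_coculture_panel(panel_cfg)
write_panel(panel, out / "panel.tsv")

truth = {
    "spot_planted_or": 2.17,
    "survival_planted_log_hazard": {"g0000": 1.0},
    "event_fraction": float(cohort.event.mean()),
    "panel_population_slope": panel.truth["population_slope"],
    "panel_indirect": panel.truth["indirect"],
}
(out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
print(f"wrote synthetic inputs to {out}")
print(json.dumps(truth, indent=2))
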