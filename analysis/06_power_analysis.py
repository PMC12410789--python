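#!/usr/bin/env python
"""Post-hoc power of the multivariable mutation-LNM logistic model design.

A fixed-effects multiple-regression F test with 9 predictors (the most
frequently mutated genes), 201 patients, Cohen's f2 = 0.15 and alpha = 0.05
— the one printed quantity of the study that is recomputable without any
external data.  Writes results/power.json.
"""

import json
from pathlib import Path

import stromalink as sl

q = sl.PowerQuery(f2=0.15, alpha=0.05, n_total=201, n_predictors=9)
power = sl.ftest_power(q)
root = Path(__file__).resolve().parent.parent / "results"
root.mkdir(exist_ok=True)
(root / "power.json").write_text(json.dumps({
    "f2": q.f2, "alpha": q.alpha, "n_total": q.n_total, "n_predictors": q.n_predictors,
    "power": power,
}, indent=2))
print(f"power = {power:.4f} (df1={q.n_predictors}, df2={q.n_total - q.n_predictors - 1}, "
      f"lambda={q.f2 * q.n_total:.2f})")
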