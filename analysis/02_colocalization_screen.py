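#!/usr/bin/env python
"""Pairwise cell-type colocalization screen on the simulated spot map.

Presence is called at one estimated cell per spot, types below 4% prevalence
are dropped, and every remaining pair is scored by a (Haldane-Anscombe
corrected when needed) odds ratio with Fisher exact p and BH-FDR across the
screen.  Writes results/coloc_screen.tsv and reports the top pair, which
should recover the planted tumor-myCAF odds ratio of 2.17.
"""

from pathlib import Path

import stromalink as sl
from stromalink.coloc import read_spot_matrix_long, write_coloc_results

root = Path(__file__).resolve().parent.parent / "results"
m = read_spot_matrix_long(root / "data" / "spots.tsv")
p = sl.filter_prevalence(sl.call_presence(m, threshold=1.0), min_prevalence=0.04)
results = sl.coloc_screen(p, ci_level=0.95)
write_coloc_results(results, root / "coloc_screen.tsv")

top = results[0]
print(f"{len(results)} pairs screened over {p.n_spots} pooled spots")
print(
    f"top pair: {top.type_a}-{top.type_b}  OR={top.or_result.or_value:.3f} "
    f"(95% CI {top.or_result.ci_low:.3f}-{top.or_result.ci_high:.3f}), FDR={top.fdr:.2e}"
)
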