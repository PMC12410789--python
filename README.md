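# stromalink

Statistical machinery for three linked questions about the tumor
microenvironment in oral squamous cell carcinoma (OSCC), where
myofibroblastic cancer-associated fibroblasts (myCAFs) at the invasive tumor
front are suspected drivers of lymph-node metastasis:

1. **Do two cell types co-occupy the same spatial-transcriptomics spots more
   often than chance?**  From deconvolved per-spot cell-type counts, presence
   is thresholded, rare types (< 4% of spots) are dropped, and every pair is
   scored with an odds ratio from the 2×2 co-occupancy table,
   OR = ad/bc, with the Haldane-Anscombe correction (+0.5 to every cell)
   when a cell is zero, a Woolf logit confidence interval, a two-sided Fisher
   exact p, and Benjamini-Hochberg FDR across the screen.
2. **Can a prognostic gene signature be built reproducibly from survival
   cohorts?**  Expression is normalized (per-million scaling → log2(x+1) →
   per-gene Z-scores) and an L1-penalized Cox model (penalizer 0.02, Breslow
   ties) is refit on 1,000 random 90% patient subsamples; genes selected in
   > 90% of fits whose averaged coefficient |β̄| > 10⁻² form the signature.
   Patients are scored by risk = Σ β̄_g z_g and split at the median, and the
   split is validated with a 10,000-resample bootstrap: per-resample
   log-rank p-values plus averaged Kaplan-Meier curves with percentile
   bands on a common time grid, truncated one year past the last event.
3. **Does fibroblast ECM remodeling drive tumor-cell CD44 through integrin /
   syndecan receptors?**  On co-culture fold-change panels, a three-level
   hierarchical Bayesian regression (pair-specific slopes β_pair ~
   N(β_gene, σ_pair), gene slopes β_gene ~ N(μ_β, σ_gene)) estimates a
   population-level ECM→CD44 slope with highest-density intervals, and a
   product-of-coefficients mediation analysis (X = first principal component
   of the ECM fold changes, indirect effect β_xz·β_zy) quantifies the
   receptor-mediated pathway with pair-level bootstrap intervals.

Every stage is exercised end-to-end on synthetic data with planted ground
truth (module `stromalink.simulate`): spot maps with exact planted odds
ratios (bivariate Bernoulli solved from margins + OR), proportional-hazards
expression cohorts with planted log-hazard coefficients, and linear-chain
X→M→Y fold-change panels.

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_colocalization_screen.py
python analysis/03_signature_selection.py --seed 1
python analysis/04_bootstrap_km_validation.py --seed 1
python analysis/05_crosstalk_models.py --seed 1
python analysis/06_power_analysis.py
```

which prints (abridged):

```
top pair: myCAF-tumor  OR=2.235 (95% CI 2.102-2.377), FDR=7.47e-146
planted gene g0000: frequency 1.000, averaged coefficient +1.046 (truth +1.0)
original log-rank p = 1.89e-29; 100.0% of 2000 resamples significant at 0.05
population slope mu_beta: posterior mean 0.690, 95% HDI [0.383, 1.050] (planted 0.632)
indirect effect via ITG: 0.285 (95% bootstrap CI -2.986 to 2.806; planted 0.40)
power = 0.9827 (df1=9, df2=191, lambda=30.15)
```

Reading the numbers: the screen recovers the planted tumor-myCAF odds ratio
(2.17) from 20,000 spots; stability selection finds the planted prognostic
gene in every subsample with its coefficient recovered to ~5%; the
median-score split separates survival overwhelmingly (and in every bootstrap
resample); the hierarchical posterior covers the planted population slope;
mediation point estimates land near the planted indirect effect of 0.4 but —
with only six fibroblast×tumor pairs — their bootstrap intervals are very
wide, an honest picture of what such panel sizes support.  The last line is
the analytic power of a 9-predictor, 201-patient regression F test at
f² = 0.15 (≈ 0.98).

All simulation steps accept `--seed`; tables land under `results/`.

A `stromalink` command-line interface wraps the same five stages
(`simulate`, `coloc`, `signature`, `validate`, `crosstalk`); run
`stromalink --help`.

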