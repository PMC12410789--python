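# Methods

This note documents the models the package implements, the choices made
where the underlying analyses left details open, and what the synthetic-data
experiments do and do not demonstrate.

## Colocalization screen

Spots from a deconvolved spatial-transcriptomics slide carry a non-negative
estimated cell count per cell type.  A type is called *present* in a spot
when its count reaches a threshold, default **1.0 estimated cells** — one
whole estimated cell is the least arbitrary occupancy cutoff for fractional
deconvolution masses; the threshold is recorded in the `PresenceMatrix` and
freely configurable.  Cell types present in strictly less than
`min_prevalence` (default 4%) of the pooled spots are removed before
testing; the filter is strict ("less than"), so a type at exactly the
threshold is kept.  When several samples are supplied the screen pools their
spots; a per-sample screen is simply the same functions applied per sample.

For each unordered pair the 2×2 co-occupancy table (both / first only /
second only / neither) yields:

* **odds ratio** ad/bc.  If any cell is zero, 0.5 is added to *all four*
  cells (Haldane-Anscombe) before the OR and interval are computed — the
  symmetric form of the correction — and the result is flagged.
* **confidence interval**: Woolf logit interval
  exp(log OR ± z·√(1/a′+1/b′+1/c′+1/d′)) on the possibly-corrected cells.
  The source analyses never name their interval method; Woolf is the
  conventional large-sample choice and is declared rather than guessed.
* **p-value**: two-sided Fisher exact test on the *uncorrected* counts,
  summing hypergeometric probabilities of tables at most as probable as the
  observed one (ties within 1e-7 relative tolerance).
* **FDR**: Benjamini-Hochberg step-up across all pairs of the screen.
  Adjusted p-values are reported (not reject flags); note that BH adjusted
  values are *not* idempotent under re-adjustment — only the dominance
  property holds.

The screen is purely co-occupancy based: no neighborhood or
spatial-adjacency statistics are computed, matching the original design.

## Synthetic spot maps

`gen_spot_map` places spots on a grid and samples presence per type.  For a
pair with a planted odds ratio ψ and margins (p₁, p₂), the joint cell
probabilities come from the Plackett construction: p₁₁ solves
ψ = p₁₁p₀₀/(p₁₀p₀₁) on [max(0, p₁+p₂−1), min(p₁, p₂)], so the planted OR is
exact, not approximate.  Planted dependence is pairwise only and the
dependent pairs must form a matching (a type may appear in at most one);
all other types are independent Bernoulli draws.  Present types receive
1 + Poisson(1.5) estimated cells, absent types a Uniform[0, 1) mass, so
presence calling at threshold 1.0 inverts the generator exactly.  Default
margins (8%-45% across eight microenvironment cell types) are in the range
deconvolution typically reports for tumor sections.

## Survival cohorts and the stability-selection signature

`gen_survival_cohort` draws per-gene standard-normal expression (optionally
equicorrelated), then event times as exponential with hazard
h₀·exp(Σ β_g z_g) and independent exponential censoring.  Defaults
(h₀ = 1/1500 per day, censoring rate 1/1200 per day) give a baseline median
survival near 2.8 years and roughly 45% observed events, the regime of
overall-survival follow-up in head-and-neck registry cohorts.

Normalization follows the per-million → log2(x+1) → per-gene Z-score chain.
When gene lengths are supplied the per-million scaling is true TPM;
otherwise it is counts-per-million and documented as such (the chain is
routinely applied to re-normalize already-quantified data, where lengths are
unavailable).  Z-scores use the population standard deviation (divide by n);
constant genes map to zero and are flagged.

Stability selection fits an L1-penalized Cox model on a fresh random 90%
patient subsample in each of 1,000 iterations.  The held-out 10% is not
used for tuning: all hyperparameters are fixed (penalizer 0.02,
l1_ratio 1.0, Breslow ties), and the iterations exist solely to measure
selection frequency and average coefficients.  Two numerical points matter:

* **Penalty scale.**  The fits use glmnet-style coordinate descent
  (`CoxnetSurvivalAnalysis`), whose `alpha` multiplies the penalty against
  the *mean* partial log-likelihood.  The smooth elastic-net penalty of
  lifelines' `CoxPHFitter` multiplies `penalizer · n` against the *summed*
  log-likelihood — the same scale — so `alpha = penalizer` transfers the
  published setting.  Coordinate descent is used because it returns exact
  zeros, making "selected in an iteration" well defined; a coefficient is
  counted as selected when |β| > 1e-8.
* **Averaging.**  A retained gene's weight is its coefficient averaged over
  *all* iterations, zeros included, and the 10⁻² magnitude gate applies to
  that mean.  The alternative reading (average over selected iterations
  only) is available via `average_selected_only=True`.

Genes pass when selection frequency > 0.90 *and* |mean coefficient| > 10⁻².
A property worth understanding: with ~180 events and standardized
predictors, the LASSO entry condition |∂ℓ/∂β_g|/n > 0.02 sits well below
the sampling noise of a null gene's score statistic (≈ √events/n ≈ 0.03),
so genes with moderate spurious marginal association enter in nearly every
90% subsample and survive both gates.  At these dimensions the procedure
reliably ranks a strong true predictor first but is *not* a false-positive
filter; an empty signature on pure noise would require a penalty several
times larger.  This is a property of the published settings themselves, not
of the implementation, and the tests assert it honestly.

Risk scores are Σ β̄_g z_g; the cohort median is the cutoff, scores strictly
above it are "high", ties go to "low" (deterministic partition).  Missing
signature genes contribute zero (their z-scale mean) up to a 20% missing
limit.  Subsampling uses a dedicated random stream per iteration derived
from (seed, iteration), so results are independent of patient order and of
execution order.

## Kaplan-Meier bootstrap validation

`km_estimate` and `logrank` wrap lifelines (product-limit with events
before censorings at tied times; standard 1-df log-rank).
`bootstrap_km_validate` draws `n_boot` resamples with replacement at the
original size, one random stream per resample index.  Each resample is
re-split at *its own* median score (the original-cohort median is available
via `recompute_median=False`), log-rank tested, and its per-group curves
are evaluated on the union grid of observed times by right-continuous
previous-value interpolation (linear interpolation behind a flag).  Because
every resampled observation is one of the original observations, the inner
loop tallies events and risk sets by rank-encoded bincounts — verified
against lifelines on arbitrary resamples — which keeps 10,000 resamples in
seconds.  The grid is truncated at the last *event* time of the original
cohort plus 365 days.  Pointwise means and equal-tailed percentile bands
(not simultaneous bands) are reported per group; the mean of step functions
is already non-increasing, but a pool-adjacent-violators projection is
applied as a guard with the raw means retained for audit.  Resamples with
an empty group or no events are redrawn and counted; more than 10% redraws
aborts.  An identity-resampling hook replaces every draw with the original
cohort, in which mode the averaged curves must equal the original
Kaplan-Meier curves to machine precision.

## Hierarchical ECM→CD44 slope model

Data: per fibroblast×tumor pair, fold changes of each ECM gene (fibroblast
side) and one CD44 fold change (tumor side).  Model, on standardized (or,
for recovery studies, centered) data:

    cd44[g,p] ~ Normal(α + β_pair[g,p] · ecm[g,p], σ)
    β_pair[g,p] ~ Normal(β_gene[g], σ_pair)
    β_gene[g]  ~ Normal(μ_β, σ_gene)

Priors (undeclared in the original analysis, so chosen weakly informative
for standardized data and declared here): μ_β ~ N(0,1), α ~ N(0,1),
σ, σ_gene, σ_pair ~ Half-Normal(1).

The posterior is sampled with a package-authored Gibbs sampler: all
location parameters have conjugate Normal full conditionals; the gene-slope
update *collapses* the pair slopes analytically
(y ~ N(α + β_gene·x, σ² + σ_pair²x²)), which removes the funnel that makes
the naive centered scheme mix slowly; the three scale parameters are
updated by stepping-out slice sampling on the log scale, floored at 1e-6 so
that noiseless (zero-residual) panels remain proper.  Defaults: 4 chains ×
(1,000 warmup + 1,000 draws); split-chain R-hat and bulk/tail effective
sample sizes are computed with ArviZ for every parameter, and a fit is
flagged unconverged when R-hat(μ_β) > 1.01.  With no data (`prior_only`)
the posterior is exactly the prior and is sampled ancestrally.

**A structural caution.**  Each pair contributes a single CD44 measurement,
shared across all G genes of that pair, while the model assumes independent
residuals per (gene, pair).  Pair-level outcome noise is therefore
undercounted in the μ_β posterior by roughly a factor of G.  The posterior
is calibrated only in the regime where gene-level slope heterogeneity
(σ_gene/√G) dominates pair-shared noise (σ_shared/√P) — which the real
panels suggest (gene slopes spreading widely around the mean) — and the
synthetic defaults live in that regime.  Outside it, HDIs are too narrow;
this limitation is inherited from the original analysis design, not
introduced by the implementation.

`hdi` is the narrowest contiguous interval containing the requested mass
(sliding window over sorted draws).

## Co-culture panel generator

The generator plants a linear chain on the centered per-pair mean ECM fold
change u: mediator M = slope_xz·u + ε, outcome Y = slope_zy·M +
direct_xy·u + ε, so the true indirect effect is slope_xz·slope_zy and the
total exposure→outcome ("chain") slope is slope_xz·slope_zy + direct_xy.
Observed mediator gene-set summaries are the latent mediator plus noise at
half the panel noise.

Gene- and pair-specific slopes cannot be planted additively: with one
shared CD44 value per pair, additive per-gene noise produces per-gene
regression slopes that are all equal up to O(1/G) dilution.  Heterogeneity
is therefore planted through lognormal gene- (and gene×pair-) specific
*coupling strengths* of each ECM gene to the shared pair-level program,
dispersed so the per-gene slopes spread by about `gene_slope_sd` (and
`pair_slope_sd` below the gene level) around the population value.  Because
slopes scale as the reciprocal coupling, the expected population-mean slope
differs from the chain slope by a dispersion (Jensen) factor; the exact
value is computed by a fixed-seed Monte Carlo quadrature over the coupling
distribution and recorded in `panel.truth["population_slope"]` — the
quantity recovery and coverage studies compare against.  With all
dispersions zero the generator reduces to the exact noiseless chain, and
the planted values are recovered exactly.

Defaults — 6 pairs, 17 ECM genes, slope_xz 0.8, slope_zy 0.5 (indirect
0.4), fold-change noise sd 0.05, gene/pair slope sds 0.30/0.15 — emulate a
small deeply-sequenced co-culture panel with substantial gene-level
heterogeneity, the regime sketched above.  What passing tests show: the
sampler recovers planted population slopes, with honest interval coverage,
*under these conditions*; they do not show that the model is calibrated for
panels dominated by pair-level measurement noise, nor anything about
unmodeled confounding between co-culture conditions.

## Mediation analysis

X is the first principal component of the pairs×genes ECM fold-change
matrix, expressed on the mean-fold-change scale: the raw PC score is
rescaled by regressing the centered per-pair mean fold change on it, which
anchors the sign (X correlates positively with the mean) and gives X
interpretable units — in the rank-one equal-loading case X *is* the
centered mean fold change.  β_xz is the least-squares slope of M ~ X;
β_zy comes from Y ~ M + X, adjusting for the direct path (standard
product-of-coefficients practice; the unadjusted Y ~ M model is available
via `adjust_direct=False`, and is substituted automatically when M and X
are numerically collinear, as in noiseless chains).  The indirect effect is
β_xz·β_zy.  Note the estimate is *equivariant*, not invariant, under
negating the ECM data: X flips with its anchor, so the indirect effect
changes sign with unchanged magnitude.

Uncertainty: the whole chain (centering, PCA, both regressions) is repeated
on `n_boot` (default 5,000) pair-level bootstrap resamples; the interval is
the 2.5-97.5 percentile range.  Resamples with zero ECM variance (all
draws from one pair) are redrawn and counted.  With very few pairs the
intervals are extremely wide; that is the honest answer at such panel
sizes.

## Degenerate inputs and tie rules (summary)

* Contingency cells must be non-negative integers; an all-zero table is
  rejected; any zero cell triggers the symmetric 0.5 correction.
* Prevalence filtering that removes every cell type is an error, not an
  empty screen.
* Constant genes z-score to zero and are flagged; all-identical risk scores
  produce an empty high group with a warning.
* Median ties go to the low-risk group.
* Non-convergent penalized-Cox iterations are retried with a larger
  iteration budget, then recorded as all-zero; more than 5% failures aborts.
* Scale parameters in the Gibbs sampler are floored at 1e-6; slice
  sampling is bounded on [1e-6, 1e6].

## Problem sizes

Simulation studies use 50,000 spots for planted-OR recovery (≈2% Monte
Carlo error on the OR), 2,000-spot replicates for null FDR calibration,
400-patient / 50-gene cohorts for signature recovery, 1,000-10,000
bootstrap resamples for the Kaplan-Meier protocol, and 20 replicate panels
for posterior-coverage studies — sizes at which the measured quantities'
Monte Carlo error is small relative to the tolerances being checked.
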