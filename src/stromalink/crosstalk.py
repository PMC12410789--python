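"""Fibroblast-to-tumor ECM-CD44 crosstalk models for co-culture panels.

Two complementary views of the same fold-change panel (per fibroblast x
tumor cell-line pair: ECM gene fold changes in the fibroblasts, mediator
gene-set fold changes and the CD44 fold change in the tumor cells):

* a three-level partial-pooling regression of CD44 change on each ECM
  gene's change, with pair-specific slopes shrunk toward gene-specific
  slopes, themselves shrunk toward a population mean slope ``mu_beta``; and
* a product-of-coefficients mediation analysis X -> M -> Y where X is the
  first principal component of the ECM fold changes (expressed on the
  mean-fold-change scale), M a mediator gene-set summary, and Y the CD44
  change, with a pair-level bootstrap for the indirect effect.

The hierarchical posterior is sampled with a Gibbs sampler: every location
parameter has a conjugate Normal full conditional, and the three Half-Normal
scale parameters are updated by univariate slice sampling on the log scale.
Convergence is monitored with split-chain R-hat and effective sample sizes
computed by ArviZ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .stats import percentile_bootstrap_ci

__all__ = [
    "CoCulturePanel",
    "HierPriors",
    "MCMCSettings",
    "HierPosterior",
    "MediationResult",
    "fit_hierarchical_slopes",
    "hdi",
    "mediation_indirect",
    "read_panel",
    "write_panel",
]


@dataclass
class CoCulturePanel:
    """Per-pair fold changes: ECM genes (fibroblast side), mediator gene-set
    summaries and CD44 (tumor side).  Fold changes are on the log scale."""

    ecm_fc: pd.DataFrame  # genes x pairs
    mediator_fc: pd.DataFrame  # mediator sets x pairs
    cd44_fc: pd.Series  # per pair
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = self.ecm_fc.columns
        if not (self.mediator_fc.columns.equals(pairs) and self.cd44_fc.index.equals(pairs)):
            self.mediator_fc = self.mediator_fc[pairs]
            self.cd44_fc = self.cd44_fc[pairs]
        for name, vals in (
            ("ecm_fc", self.ecm_fc.values),
            ("mediator_fc", self.mediator_fc.values),
            ("cd44_fc", self.cd44_fc.values),
        ):
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} contains non-finite fold changes")

    @property
    def pairs(self) -> list[str]:
        return list(self.ecm_fc.columns)

    @property
    def ecm_genes(self) -> list[str]:
        return list(self.ecm_fc.index)


@dataclass(frozen=True)
class HierPriors:
    """Weakly informative priors on standardized data."""

    mu_beta_sd: float = 1.0
    sigma_gene_scale: float = 1.0  # Half-Normal scale
    sigma_pair_scale: float = 1.0
    sigma_scale: float = 1.0
    intercept_sd: float = 1.0


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000


@dataclass
class HierPosterior:
    """Posterior draws (chains x draws [x ...]) and per-parameter diagnostics."""

    samples: dict[str, np.ndarray]
    diagnostics: pd.DataFrame
    genes: list[str]
    pairs: list[str]
    converged: bool

    def mu_beta(self) -> np.ndarray:
        return self.samples["mu_beta"].reshape(-1)


@dataclass
class MediationResult:
    beta_xz: float
    beta_zy: float
    indirect: float
    boot_mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    direct_adjusted: bool = True
    n_redrawn: int = 0


_LOG_SIGMA_MIN = np.log(1e-6)  # floor keeps degenerate (zero-residual) fits proper
_LOG_SIGMA_MAX = np.log(1e6)


def _slice_sample_log_scale(log_s: float, loglik, rng, width: float = 1.0) -> float:
    """One stepping-out slice-sampling update of a scalar on the log scale."""
    log_s = float(np.clip(log_s, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))
    y = loglik(log_s) - rng.exponential(1.0)
    lo = log_s - width * rng.random()
    hi = lo + width
    while lo > _LOG_SIGMA_MIN and loglik(lo) > y:
        lo -= width
    while hi < _LOG_SIGMA_MAX and loglik(hi) > y:
        hi += width
    lo = max(lo, _LOG_SIGMA_MIN)
    hi = min(hi, _LOG_SIGMA_MAX)
    while True:
        prop = rng.uniform(lo, hi)
        if loglik(prop) > y:
            return prop
        if prop < log_s:
            lo = prop
        else:
            hi = prop


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def fit_hierarchical_slopes(
    panel: CoCulturePanel,
    priors: HierPriors = HierPriors(),
    mcmc: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    standardize: bool = True,
    prior_only: bool = False,
) -> HierPosterior:
    """Three-level partial-pooling slope model.

        cd44[g,p] ~ Normal(alpha + beta_pair[g,p] * ecm[g,p], sigma)
        beta_pair[g,p] ~ Normal(beta_gene[g], sigma_pair)
        beta_gene[g] ~ Normal(mu_beta, sigma_gene)

    With ``standardize`` (default, matching how the co-culture analysis is
    reported) predictors and outcome are z-scored before fitting; with
    ``standardize=False`` the ECM predictors are only centered per gene and
    the outcome centered, preserving the slope scale — the mode used for
    parameter-recovery studies on simulated panels.

    ``prior_only`` drops every likelihood contribution (a prior-predictive
    check: the posterior must then reproduce the declared priors).
    """
    genes, pairs = panel.ecm_genes, panel.pairs
    G, P = len(genes), len(pairs)
    if G < 2 or P < 2:
        raise ValueError("need at least 2 ECM genes and 2 pairs")

    x = panel.ecm_fc.to_numpy(float)  # G x P
    y = np.broadcast_to(panel.cd44_fc.to_numpy(float), (G, P)).copy()
    if standardize:
        x = np.apply_along_axis(_standardize, 1, x)
        y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    else:
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean()

    n_obs = x.size
    n_iter = mcmc.n_warmup + mcmc.n_draws
    store = {
        "mu_beta": np.empty((mcmc.n_chains, mcmc.n_draws)),
        "sigma_gene": np.empty((mcmc.n_chains, mcmc.n_draws)),
        "sigma_pair": np.empty((mcmc.n_chains, mcmc.n_draws)),
        "sigma": np.empty((mcmc.n_chains, mcmc.n_draws)),
        "alpha": np.empty((mcmc.n_chains, mcmc.n_draws)),
        "beta_gene": np.empty((mcmc.n_chains, mcmc.n_draws, G)),
        "beta_pair": np.empty((mcmc.n_chains, mcmc.n_draws, G, P)),
    }

    if prior_only:
        # with no data the posterior is exactly the joint prior; sample it
        # ancestrally instead of running the Gibbs chain
        for chain in range(mcmc.n_chains):
            rng = np.random.default_rng([seed, chain])
            D = mcmc.n_draws
            sig = np.abs(rng.normal(0, priors.sigma_scale, D))
            sig_g = np.abs(rng.normal(0, priors.sigma_gene_scale, D))
            sig_p = np.abs(rng.normal(0, priors.sigma_pair_scale, D))
            mu = rng.normal(0, priors.mu_beta_sd, D)
            bg = mu[:, None] + sig_g[:, None] * rng.standard_normal((D, G))
            bgp = bg[:, :, None] + sig_p[:, None, None] * rng.standard_normal((D, G, P))
            store["mu_beta"][chain] = mu
            store["sigma"][chain] = sig
            store["sigma_gene"][chain] = sig_g
            store["sigma_pair"][chain] = sig_p
            store["alpha"][chain] = rng.normal(0, priors.intercept_sd, D)
            store["beta_gene"][chain] = bg
            store["beta_pair"][chain] = bgp
        return _finalize_posterior(store, genes, pairs)

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([seed, chain])
        # overdispersed but sane initial values
        mu = rng.normal(0, 0.5)
        beta_g = np.full(G, mu) + rng.normal(0, 0.1, G)
        beta_gp = np.tile(beta_g[:, None], (1, P)) + rng.normal(0, 0.1, (G, P))
        alpha = rng.normal(0, 0.1)
        log_sig = np.log(rng.uniform(0.5, 1.5, 3))  # sigma, sigma_gene, sigma_pair

        for it in range(n_iter):
            sigma, sigma_gene, sigma_pair = np.exp(log_sig)
            # beta_gene | y with beta_pair marginalized out (collapsed update:
            # y[g,p] ~ N(alpha + beta_gene[g]*x, sigma^2 + sigma_pair^2 * x^2)),
            # which avoids the slow funnel of the fully centered scheme
            marg_var = sigma**2 + sigma_pair**2 * x**2
            prec_g = (x**2 / marg_var).sum(axis=1) + 1.0 / sigma_gene**2
            mean_g = (
                (x * (y - alpha) / marg_var).sum(axis=1) + mu / sigma_gene**2
            ) / prec_g
            beta_g = mean_g + rng.standard_normal(G) / np.sqrt(prec_g)
            # beta_pair | beta_gene, y   (one observation per (g, p))
            prec = x**2 / sigma**2 + 1.0 / sigma_pair**2
            mean = (x * (y - alpha) / sigma**2 + beta_g[:, None] / sigma_pair**2) / prec
            beta_gp = mean + rng.standard_normal((G, P)) / np.sqrt(prec)
            # mu_beta | rest
            prec_mu = G / sigma_gene**2 + 1.0 / priors.mu_beta_sd**2
            mean_mu = (beta_g.sum() / sigma_gene**2) / prec_mu
            mu = mean_mu + rng.standard_normal() / np.sqrt(prec_mu)
            # alpha | rest
            resid0 = y - beta_gp * x
            prec_a = n_obs / sigma**2 + 1.0 / priors.intercept_sd**2
            mean_a = resid0.sum() / sigma**2 / prec_a
            alpha = mean_a + rng.standard_normal() / np.sqrt(prec_a)
            # scales | rest  (Half-Normal priors; slice sampling on log scale)
            ss_obs = float(((resid0 - alpha) ** 2).sum())
            ss_pair = float(((beta_gp - beta_g[:, None]) ** 2).sum())
            ss_gene = float(((beta_g - mu) ** 2).sum())
            for j, (ss, count, scale) in enumerate(
                [
                    (ss_obs, n_obs, priors.sigma_scale),
                    (ss_gene, G, priors.sigma_gene_scale),
                    (ss_pair, G * P, priors.sigma_pair_scale),
                ]
            ):
                def logp(ls, ss=ss, count=count, scale=scale):
                    s = np.exp(ls)
                    return (
                        -count * ls
                        - ss / (2 * s**2)
                        - s**2 / (2 * scale**2)
                        + ls  # Jacobian of the log transform
                    )

                log_sig[j] = _slice_sample_log_scale(log_sig[j], logp, rng)

            if it >= mcmc.n_warmup:
                d = it - mcmc.n_warmup
                store["mu_beta"][chain, d] = mu
                store["sigma"][chain, d] = np.exp(log_sig[0])
                store["sigma_gene"][chain, d] = np.exp(log_sig[1])
                store["sigma_pair"][chain, d] = np.exp(log_sig[2])
                store["alpha"][chain, d] = alpha
                store["beta_gene"][chain, d] = beta_g
                store["beta_pair"][chain, d] = beta_gp

    return _finalize_posterior(store, genes, pairs)


def _finalize_posterior(store, genes, pairs) -> HierPosterior:
    idata = az.from_dict(posterior=store)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summ = az.summary(idata, kind="diagnostics")
    diagnostics = summ[["ess_bulk", "ess_tail", "r_hat"]]
    rhat_mu = float(diagnostics.loc["mu_beta", "r_hat"])
    converged = bool(rhat_mu <= 1.01)
    if not converged:
        warnings.warn(f"mu_beta split R-hat {rhat_mu:.3f} exceeds 1.01", stacklevel=3)
    return HierPosterior(
        samples=store,
        diagnostics=diagnostics,
        genes=genes,
        pairs=pairs,
        converged=converged,
    )


def hdi(samples, prob: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the narrowest contiguous interval holding
    ``prob`` of the empirical distribution (sliding window over sorted
    draws)."""
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if not 0 < prob < 1:
        raise ValueError("prob must lie in (0, 1)")
    n = x.size
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def _pc1_predictor(ecm: np.ndarray) -> np.ndarray:
    """First-PC score of a pairs x genes fold-change matrix, rescaled onto
    the mean-fold-change scale and sign-anchored to correlate positively
    with the per-pair mean.

    The rescaling regresses the centered per-pair mean fold change on the
    raw PC score, so that when the matrix is rank one with equal loadings
    the predictor equals the centered mean exactly.
    """
    centered = ecm - ecm.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("ECM fold-change matrix has zero variance; PCA is degenerate")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    score = u[:, 0] * s[0]
    m = centered.mean(axis=1)
    denom = float(score @ score)
    coef = float(m @ score) / denom
    if coef == 0:
        # orthogonal to the mean: fall back to a positive-loading-sum anchor
        sign = 1.0 if vt[0].sum() >= 0 else -1.0
        return sign * score
    return coef * score


def _ols_slope(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[1:]


def mediation_indirect(
    panel: CoCulturePanel,
    mediator: str,
    n_boot: int = 5000,
    seed: int = 0,
    adjust_direct: bool = True,
) -> MediationResult:
    """Product-of-coefficients mediation X -> M -> Y with a pair bootstrap.

    X is the first principal component of the per-pair ECM fold changes,
    M the named mediator gene-set summary, Y the CD44 fold change.
    ``beta_xz`` comes from M ~ X and ``beta_zy`` from Y ~ M + X (the direct
    path is dropped automatically when M and X are numerically collinear, or
    when ``adjust_direct=False``).  The interval is the percentile interval
    of the bootstrap indirect effects; resamples with zero X variance are
    redrawn and counted.
    """
    if mediator not in panel.mediator_fc.index:
        raise KeyError(f"unknown mediator set {mediator!r}")
    ecm = panel.ecm_fc.to_numpy(float).T  # pairs x genes
    M = panel.mediator_fc.loc[mediator].to_numpy(float)
    Y = panel.cd44_fc.to_numpy(float)
    n = ecm.shape[0]
    if n < 3:
        raise ValueError("mediation needs at least 3 pairs")

    def chain(ecm_s, M_s, Y_s) -> tuple[float, float]:
        X = _pc1_predictor(ecm_s)
        bxz = float(_ols_slope(M_s, X[:, None])[0])
        r = np.corrcoef(M_s, X)[0, 1] if M_s.std() > 0 and X.std() > 0 else 1.0
        if adjust_direct and abs(r) < 1 - 1e-10:
            bzy = float(_ols_slope(Y_s, np.column_stack([M_s, X]))[0])
        else:
            bzy = float(_ols_slope(Y_s, M_s[:, None])[0])
        return bxz, bzy

    beta_xz, beta_zy = chain(ecm, M, Y)
    indirect = beta_xz * beta_zy

    boots = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            rng = np.random.default_rng([seed, b + n_redrawn * n_boot])
            idx = rng.integers(0, n, size=n)
            sub = ecm[idx]
            if np.any(sub - sub.mean(axis=0, keepdims=True)):
                break
            n_redrawn += 1
            if n_redrawn > 10 * n_boot:
                raise RuntimeError("bootstrap cannot find resamples with ECM variance")
        bxz, bzy = chain(sub, M[idx], Y[idx])
        boots[b] = bxz * bzy

    lo, hi = percentile_bootstrap_ci(boots, 0.95)
    return MediationResult(
        beta_xz=beta_xz,
        beta_zy=beta_zy,
        indirect=indirect,
        boot_mean=float(boots.mean()),
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        direct_adjusted=adjust_direct,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# File formats


def read_panel(path, gene_sets: dict[str, list[str]] | None = None) -> CoCulturePanel:
    """Panel TSV with columns pair_id, gene, compartment, fold_change.

    Compartment is one of ``ecm``, ``mediator``, ``cd44``.  When raw
    mediator-gene fold changes are provided instead of set summaries,
    ``gene_sets`` maps mediator-set names to gene lists and each set is
    summarized as the mean of the standardized member fold changes.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "gene", "compartment", "fold_change"}
    if not required <= set(df.columns):
        raise ValueError(f"panel table needs columns {sorted(required)}")
    ecm = df[df.compartment == "ecm"].pivot(index="gene", columns="pair_id", values="fold_change")
    med_rows = df[df.compartment == "mediator"]
    med = med_rows.pivot(index="gene", columns="pair_id", values="fold_change")
    if gene_sets:
        summaries = {}
        for name, members in gene_sets.items():
            sub = med.loc[[g for g in members if g in med.index]]
            z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0).replace(0, 1), axis=0)
            summaries[name] = z.mean(axis=0)
        med = pd.DataFrame(summaries).T
    cd44 = df[df.compartment == "cd44"].set_index("pair_id")["fold_change"]
    return CoCulturePanel(ecm_fc=ecm, mediator_fc=med, cd44_fc=cd44.loc[ecm.columns])


def write_panel(panel: CoCulturePanel, path) -> None:
    rows = []
    for gene, row in panel.ecm_fc.iterrows():
        for pair, v in row.items():
            rows.append((pair, gene, "ecm", v))
    for mset, row in panel.mediator_fc.iterrows():
        for pair, v in row.items():
            rows.append((pair, mset, "mediator", v))
    for pair, v in panel.cd44_fc.items():
        rows.append((pair, "CD44", "cd44", v))
    pd.DataFrame(rows, columns=["pair_id", "gene", "compartment", "fold_change"]).to_csv(
        path, sep="\t", index=False
    )
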