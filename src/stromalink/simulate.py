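"""Synthetic data with planted ground truth for every pipeline stage.

Three generators mirror the three input classes of the analysis:

* ``gen_spot_map`` — spatial spots whose per-cell-type presence follows a
  bivariate Bernoulli with exact target odds ratios (Plackett
  parameterization: joint cell probabilities solved from the two margins
  and the OR), dressed up as estimated cell counts;
* ``gen_survival_cohort`` — proportional-hazards expression cohorts with
  planted log-hazard coefficients and independent exponential censoring;
* ``gen_coculture_panel`` — linear-chain X -> M -> Y fold-change panels
  with hierarchical gene- and pair-level slope heterogeneity.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import SpotMatrix
from .crosstalk import CoCulturePanel
from .signature import SurvivalCohort, zscore_rows

__all__ = [
    "SpotSimConfig",
    "SurvivalSimConfig",
    "CoCultureSimConfig",
    "gen_spot_map",
    "gen_survival_cohort",
    "gen_coculture_panel",
    "joint_from_margins_and_or",
]


def joint_from_margins_and_or(p1: float, p2: float, psi: float) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of the bivariate Bernoulli
    with margins ``p1``, ``p2`` and odds ratio ``psi`` (Plackett).

    For ``psi != 1`` the both-present probability is the root of
    ``psi = p11*p00 / (p10*p01)`` lying in
    [max(0, p1+p2-1), min(p1, p2)]; infeasible combinations raise.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("margins must lie strictly in (0, 1)")
    if psi <= 0:
        raise ValueError("target odds ratio must be positive")
    if psi == 1.0:
        p11 = p1 * p2
    else:
        s = 1 + (p1 + p2) * (psi - 1)
        disc = s * s - 4 * psi * (psi - 1) * p1 * p2
        if disc < 0:
            raise ValueError(f"no joint distribution with margins ({p1}, {p2}) and OR {psi}")
        p11 = (s - np.sqrt(disc)) / (2 * (psi - 1))
    p10, p01 = p1 - p11, p2 - p11
    p00 = 1 - p11 - p10 - p01
    eps = 1e-12
    if min(p11, p10, p01, p00) < -eps:
        raise ValueError(
            f"margins ({p1}, {p2}) and OR {psi} give a negative cell probability"
        )
    return float(p11), float(max(p10, 0)), float(max(p01, 0)), float(max(p00, 0))


@dataclass(frozen=True)
class SpotSimConfig:
    """Spatial spot map with planted pairwise colocalization structure.

    Cell types named in ``pair_target_or`` are sampled jointly from the
    bivariate Bernoulli with the requested odds ratio; every other type is
    independent.  A type may belong to at most one dependent pair (planted
    structure is pairwise by design).  Present types receive a shifted
    Poisson estimated count (>= 1), absent types a value in [0, 1).
    """

    n_spots: int = 2000
    cell_types: tuple[str, ...] = (
        "tumor", "myCAF", "iCAF", "endothelial", "Tcell", "Bcell", "myeloid", "mast",
    )
    marginal_presence: dict[str, float] = field(
        default_factory=lambda: {
            "tumor": 0.45, "myCAF": 0.30, "iCAF": 0.25, "endothelial": 0.20,
            "Tcell": 0.25, "Bcell": 0.15, "myeloid": 0.20, "mast": 0.08,
        }
    )
    pair_target_or: dict[tuple[str, str], float] = field(default_factory=dict)
    grid_shape: tuple[int, int] = (50, 40)
    count_poisson_mean: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if self.n_spots > rows * cols:
            raise ValueError("n_spots exceeds grid capacity")
        for t in self.cell_types:
            p = self.marginal_presence.get(t)
            if p is None or not 0 < p < 1:
                raise ValueError(f"marginal presence for {t!r} must lie in (0, 1)")
        seen: set[str] = set()
        for (ta, tb), psi in self.pair_target_or.items():
            if ta not in self.cell_types or tb not in self.cell_types:
                raise ValueError(f"pair ({ta}, {tb}) names an unknown cell type")
            if psi <= 0:
                raise ValueError("target odds ratios must be positive")
            if psi != 1.0:
                if ta in seen or tb in seen:
                    raise ValueError(
                        f"cell type in pair ({ta}, {tb}) already belongs to a dependent "
                        "pair; planted structure must be a matching"
                    )
                seen.update((ta, tb))
            # feasibility check up front, with a clear diagnostic
            joint_from_margins_and_or(
                self.marginal_presence[ta], self.marginal_presence[tb], psi
            )


def gen_spot_map(cfg: SpotSimConfig, sample_id: str = "sim") -> SpotMatrix:
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    yy, xx = np.divmod(np.arange(cfg.n_spots), cols)

    presence = pd.DataFrame(
        False, index=range(cfg.n_spots), columns=list(cfg.cell_types)
    )
    dependent: set[str] = set()
    for (ta, tb), psi in cfg.pair_target_or.items():
        if psi == 1.0:
            continue
        p11, p10, p01, p00 = joint_from_margins_and_or(
            cfg.marginal_presence[ta], cfg.marginal_presence[tb], psi
        )
        cells = rng.choice(4, size=cfg.n_spots, p=[p11, p10, p01, p00])
        presence[ta] = np.isin(cells, [0, 1])
        presence[tb] = np.isin(cells, [0, 2])
        dependent.update((ta, tb))
    for t in cfg.cell_types:
        if t not in dependent:
            presence[t] = rng.random(cfg.n_spots) < cfg.marginal_presence[t]

    pres = presence.to_numpy()
    counts = np.where(
        pres,
        1.0 + rng.poisson(cfg.count_poisson_mean, size=pres.shape),
        rng.random(pres.shape),
    )
    index = pd.MultiIndex.from_arrays(
        [[sample_id] * cfg.n_spots, [f"spot{i:05d}" for i in range(cfg.n_spots)]],
        names=["sample_id", "spot_id"],
    )
    return SpotMatrix(
        counts=pd.DataFrame(counts, index=index, columns=list(cfg.cell_types)),
        coords=pd.DataFrame({"x": xx, "y": yy}, index=index),
    )


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Proportional-hazards expression cohort.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum(coef * z))``; censoring is an independent
    exponential.  Defaults emulate an overall-survival cohort of a head and
    neck cancer registry: a baseline median around 2.8 years and roughly
    45% observed events.
    """

    n_patients: int = 400
    n_genes: int = 50
    signal_genes: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1 / 1500.0  # events per day
    censoring_rate: float = 1 / 1200.0  # per day
    expression_correlation: float = 0.0
    admin_censor_days: float | None = None
    endpoint: str = "OS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("hazard rates must be positive")
        if not 0 <= self.expression_correlation < 1:
            raise ValueError("expression_correlation must lie in [0, 1)")
        bad = set(self.signal_genes) - set(self.gene_names)
        if bad:
            raise ValueError(f"signal genes outside the gene set: {sorted(bad)}")

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


def gen_survival_cohort(cfg: SurvivalSimConfig) -> SurvivalCohort:
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names
    patients = [f"p{i:04d}" for i in range(cfg.n_patients)]

    z = rng.standard_normal((cfg.n_genes, cfg.n_patients))
    rho = cfg.expression_correlation
    if rho > 0:
        shared = rng.standard_normal(cfg.n_patients)
        z = np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * z
    expr = pd.DataFrame(z, index=genes, columns=patients)
    expr, _ = zscore_rows(expr)

    beta = np.zeros(cfg.n_genes)
    for g, b in cfg.signal_genes.items():
        beta[genes.index(g)] = b
    hazard = cfg.baseline_hazard * np.exp(beta @ expr.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_rate, cfg.n_patients)
    if cfg.admin_censor_days is not None:
        t_cens = np.minimum(t_cens, cfg.admin_censor_days)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # guard against zero durations

    return SurvivalCohort(
        expression=expr,
        time=pd.Series(time, index=patients, name="time_days"),
        event=pd.Series(event, index=patients, name="event"),
        endpoint=cfg.endpoint,
        values_kind="zscore",
    )


@dataclass(frozen=True)
class CoCultureSimConfig:
    """Linear-chain fold-change panel with hierarchical slope heterogeneity.

    Per pair, a latent ECM program level drives every ECM gene's fold
    change; the mediator gene-set summary follows ``slope_xz * X`` and CD44
    follows ``slope_zy * M + direct_xy * X`` (X being the realized centered
    per-pair mean ECM fold change), all with Gaussian noise, so the true
    indirect effect is ``slope_xz * slope_zy``.

    Gene- and pair-specific slopes: because each pair contributes a single
    CD44 value, additive per-gene noise cannot create genuinely different
    per-gene regression slopes — heterogeneity is therefore planted through
    lognormal gene- (and pair-) specific *coupling strengths* of each ECM
    gene to the shared program, dispersed so that the per-gene slopes of
    CD44 on ECM expression spread with standard deviation about
    ``gene_slope_sd`` (``pair_slope_sd`` below the gene level) around the
    population slope.  The exact expected population-mean slope implied by
    this mechanism (which differs from ``slope_xz*slope_zy + direct_xy`` by
    a small dispersion correction) is recorded in ``truth``.

    Defaults: 6 fibroblast x tumor pairs and 17 ECM core genes — the scale
    of the co-culture panels this generator emulates — with fold-change
    noise typical of deeply sequenced cell-line experiments.
    """

    n_pairs: int = 6
    n_ecm_genes: int = 17
    slope_xz: float = 0.8
    slope_zy: float = 0.5
    direct_xy: float = 0.0
    noise_sd: float = 0.05
    gene_slope_sd: float = 0.30
    pair_slope_sd: float = 0.15
    mediator_sets: tuple[str, ...] = ("ITG", "SDC")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_sd, self.gene_slope_sd, self.pair_slope_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_pairs < 2 or self.n_ecm_genes < 2:
            raise ValueError("need at least 2 pairs and 2 ECM genes")

    @property
    def chain_slope(self) -> float:
        """Total exposure-to-outcome slope of the generating chain."""
        return self.slope_xz * self.slope_zy + self.direct_xy

    @property
    def true_indirect(self) -> float:
        return self.slope_xz * self.slope_zy

    @property
    def _coupling_taus(self) -> tuple[float, float]:
        """Lognormal dispersions of the gene/pair coupling strengths chosen
        so per-gene slopes spread by about gene_slope_sd / pair_slope_sd."""
        b = abs(self.chain_slope)
        if b == 0:
            return 0.0, 0.0
        return self.gene_slope_sd / b, self.pair_slope_sd / b

    def population_slope(self) -> float:
        """Expected mean per-gene regression slope of CD44 on centered ECM
        expression under this configuration — the planted value the
        hierarchical model's mu_beta estimates.

        Computed by integrating the per-gene slope
        ``beta * cov(u, x_g) / var(x_g)`` over the coupling-strength
        distribution with a fixed-seed Monte Carlo quadrature; reduces to
        ``chain_slope`` exactly when all dispersions are zero.
        """
        tau_g, tau_p = self._coupling_taus
        beta = self.chain_slope
        if beta == 0:
            return 0.0
        if tau_g == 0 and tau_p == 0 and self.noise_sd == 0:
            return beta
        rng = np.random.default_rng(987654321)
        n_rep = 400
        G, P = self.n_ecm_genes, self.n_pairs
        s2 = self.noise_sd**2
        vals = np.empty(n_rep)
        for r in range(n_rep):
            lam = _coupling_matrix(rng, G, P, tau_g, tau_p)
            lam_bar = lam.mean(axis=0)  # per pair
            num = (lam_bar[None, :] * lam).mean(axis=1) + s2 / G
            den = (lam**2).mean(axis=1) + s2
            vals[r] = beta * (num / den).mean()
        return float(vals.mean())


def _coupling_matrix(rng, G: int, P: int, tau_g: float, tau_p: float) -> np.ndarray:
    """Gene x pair coupling strengths: lognormal with unit-mean reciprocal,
    so per-gene slopes (which scale as 1/coupling) average to the chain
    slope."""
    eta = rng.normal(0, tau_g, G)[:, None] + rng.normal(0, tau_p, (G, P))
    return np.exp(-(eta - (tau_g**2 + tau_p**2) / 2))


def gen_coculture_panel(cfg: CoCultureSimConfig) -> CoCulturePanel:
    rng = np.random.default_rng(cfg.seed)
    genes = [f"ECM{i:02d}" for i in range(cfg.n_ecm_genes)]
    pairs = [f"pair{i:02d}" for i in range(cfg.n_pairs)]
    G, P = cfg.n_ecm_genes, cfg.n_pairs

    tau_g, tau_p = cfg._coupling_taus
    lam = _coupling_matrix(rng, G, P, tau_g, tau_p)
    gene_offset = rng.normal(0, 0.5, G)
    mu_pair = rng.standard_normal(P)
    x = gene_offset[:, None] + lam * mu_pair[None, :] + rng.normal(0, cfg.noise_sd, (G, P))

    # realized exposure: centered per-pair mean fold change
    u = x.mean(axis=0) - x.mean()

    m_latent = cfg.slope_xz * u + rng.normal(0, cfg.noise_sd, P)
    mediator = {
        s: m_latent + rng.normal(0, cfg.noise_sd / 2, P) for s in cfg.mediator_sets
    }
    y = cfg.slope_zy * m_latent + cfg.direct_xy * u + rng.normal(0, cfg.noise_sd, P)

    return CoCulturePanel(
        ecm_fc=pd.DataFrame(x, index=genes, columns=pairs),
        mediator_fc=pd.DataFrame(mediator).T.set_axis(pairs, axis=1),
        cd44_fc=pd.Series(y, index=pairs, name="CD44"),
        truth={
            "population_slope": cfg.population_slope(),
            "chain_slope": cfg.chain_slope,
            "indirect": cfg.true_indirect,
        },
    )
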