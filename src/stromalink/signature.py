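"""Stability-selection LASSO-Cox prognostic gene signature.

The pipeline normalizes an expression matrix (per-million scaling, log2(x+1),
per-gene Z-scores), repeatedly fits an L1-penalized Cox proportional-hazards
model on random 90% patient subsamples, keeps genes selected in more than a
stated fraction of iterations whose averaged coefficient clears a magnitude
gate, and scores patients as the weighted sum of their standardized
expression, dichotomized at the cohort median.

The penalized fits use glmnet-style coordinate descent
(``sksurv.linear_model.CoxnetSurvivalAnalysis``), whose ``alpha`` is on the
same scale as the elastic-net ``penalizer`` of lifelines' ``CoxPHFitter``
(both penalize the mean partial log-likelihood), but returns exactly-zero
coefficients so that "selected in an iteration" is well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SurvivalCohort",
    "StabilitySettings",
    "SignatureModel",
    "RiskScoreResult",
    "normalize_expression",
    "zscore_rows",
    "stability_select",
    "risk_score",
    "stratify_median",
    "read_cohort",
    "write_risk_scores",
]

_NUMERICAL_ZERO = 1e-8


@dataclass
class SurvivalCohort:
    """Gene-by-patient expression with right-censored time-to-event outcomes.

    ``time`` is in days; ``event`` is 1 for an observed event and 0 for
    censoring.  ``values_kind`` records what the expression values are:
    ``"counts"`` (raw quantification), ``"normalized"`` (log scale), or
    ``"zscore"`` (per-gene standardized, ready for modelling).
    """

    expression: pd.DataFrame
    time: pd.Series
    event: pd.Series
    endpoint: str = "OS"
    values_kind: str = "counts"

    def __post_init__(self) -> None:
        patients = self.expression.columns
        if not (self.time.index.equals(patients) and self.event.index.equals(patients)):
            self.time = self.time.reindex(patients)
            self.event = self.event.reindex(patients)
        if self.time.isna().any() or self.event.isna().any():
            raise ValueError("every patient needs a survival time and event indicator")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicators must be 0/1")
        if self.expression.index.has_duplicates:
            raise ValueError("gene labels must be unique")

    @property
    def patients(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]


@dataclass(frozen=True)
class StabilitySettings:
    """Hyperparameters of the stability-selection procedure."""

    penalizer: float = 0.02
    l1_ratio: float = 1.0
    n_iterations: int = 1000
    holdout_fraction: float = 0.10
    freq_threshold: float = 0.90
    coef_threshold: float = 0.01
    seed: int = 0
    average_selected_only: bool = False
    max_failure_rate: float = 0.05


@dataclass
class SignatureModel:
    """Retained genes with averaged coefficients and selection frequencies."""

    genes: list[str]
    weights: dict[str, float]
    selection_frequency: dict[str, float]
    settings: StabilitySettings
    n_failed_iterations: int = 0
    all_frequencies: dict[str, float] = field(default_factory=dict)
    all_mean_coefficients: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "weights": self.weights,
            "selection_frequency": self.selection_frequency,
            "settings": asdict(self.settings),
            "n_failed_iterations": self.n_failed_iterations,
            "all_frequencies": self.all_frequencies,
            "all_mean_coefficients": self.all_mean_coefficients,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["settings"] = StabilitySettings(**payload["settings"])
        return cls(**payload)


@dataclass(frozen=True)
class RiskScoreResult:
    patient_id: str
    score: float
    group: str  # "high" or "low"
    cutoff: float


def normalize_expression(
    raw: pd.DataFrame, gene_lengths: pd.Series | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Per-million scaling -> log2(x+1) -> per-gene Z-score.

    With ``gene_lengths`` (in bases) the per-million scaling is true TPM
    (length-normalized); without lengths it is counts-per-million.  Returns
    the standardized matrix and the list of constant genes, whose rows are
    set to zero.
    """
    if (raw.values < 0).any():
        raise ValueError("expression counts must be non-negative")
    x = raw.astype(float)
    if gene_lengths is not None:
        lengths = gene_lengths.reindex(x.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length for TPM")
        x = x.div(lengths, axis=0)
    x = x.div(x.sum(axis=0), axis=1) * 1e6
    x = np.log2(x + 1.0)
    return zscore_rows(x)


def zscore_rows(x: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center and scale each row to mean 0, variance 1 (population sd).

    Constant rows become all-zero and are reported separately.
    """
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    constant = sd[sd == 0].index.tolist()
    sd = sd.replace(0.0, 1.0)
    z = x.sub(mu, axis=0).div(sd, axis=0)
    z.loc[constant] = 0.0
    return z, constant


def _fit_l1_cox(X: np.ndarray, y, penalizer: float, l1_ratio: float, max_iter: int):
    model = CoxnetSurvivalAnalysis(
        alphas=[penalizer],
        l1_ratio=l1_ratio,
        normalize=False,
        fit_baseline_model=False,
        max_iter=max_iter,
        tol=1e-7,
    )
    model.fit(X, y)
    return model.coef_[:, 0]


def stability_select(
    cohort: SurvivalCohort,
    candidates: list[str] | None = None,
    settings: StabilitySettings = StabilitySettings(),
) -> SignatureModel:
    """Stability selection over repeated leave-out subsamples.

    Each iteration fits an L1-penalized Cox model (Breslow ties) on a random
    (1 - holdout_fraction) patient subsample; a gene counts as chosen when
    its coefficient is numerically nonzero.  Genes chosen in more than
    ``freq_threshold`` of iterations whose averaged coefficient (zeros
    included by default) exceeds ``coef_threshold`` in magnitude form the
    signature.

    Subsamples are drawn by patient id from a dedicated random stream per
    iteration, so results do not depend on patient order.
    """
    if cohort.values_kind != "zscore":
        raise ValueError("stability selection expects per-gene z-scored expression")
    if candidates is None:
        candidates = list(cohort.expression.index)
    missing = set(candidates) - set(cohort.expression.index)
    if missing:
        raise KeyError(f"candidate genes not in expression matrix: {sorted(missing)[:5]}")
    if not 0 < settings.holdout_fraction < 1:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if settings.n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")

    patient_ids = np.array(sorted(cohort.patients))
    n = len(patient_ids)
    n_sub = int(round((1 - settings.holdout_fraction) * n))
    expr = cohort.expression.loc[candidates, patient_ids]
    time = cohort.time.loc[patient_ids].to_numpy(float)
    event = cohort.event.loc[patient_ids].to_numpy(bool)
    X_all = expr.to_numpy(float).T  # patients x genes

    n_genes = len(candidates)
    coefs = np.zeros((settings.n_iterations, n_genes))
    n_failed = 0
    for it in range(settings.n_iterations):
        rng = np.random.default_rng([settings.seed, it])
        idx = rng.choice(n, size=n_sub, replace=False)
        idx.sort()
        y = Surv.from_arrays(event[idx], time[idx])
        try:
            coefs[it] = _fit_l1_cox(
                X_all[idx], y, settings.penalizer, settings.l1_ratio, max_iter=100000
            )
        except (ArithmeticError, ValueError):
            try:
                coefs[it] = _fit_l1_cox(
                    X_all[idx], y, settings.penalizer, settings.l1_ratio, max_iter=1000000
                )
            except (ArithmeticError, ValueError):
                coefs[it] = 0.0
                n_failed += 1
    if n_failed > settings.max_failure_rate * settings.n_iterations:
        raise RuntimeError(
            f"{n_failed}/{settings.n_iterations} penalized Cox fits failed to converge"
        )

    selected = np.abs(coefs) > _NUMERICAL_ZERO
    freq = selected.mean(axis=0)
    if settings.average_selected_only:
        with np.errstate(invalid="ignore"):
            mean_coef = np.where(
                selected.any(axis=0),
                coefs.sum(axis=0) / np.maximum(selected.sum(axis=0), 1),
                0.0,
            )
    else:
        mean_coef = coefs.mean(axis=0)

    retained = (freq > settings.freq_threshold) & (np.abs(mean_coef) > settings.coef_threshold)
    order = np.argsort(-np.abs(mean_coef))
    genes = [candidates[i] for i in order if retained[i]]
    return SignatureModel(
        genes=genes,
        weights={candidates[i]: float(mean_coef[i]) for i in order if retained[i]},
        selection_frequency={candidates[i]: float(freq[i]) for i in order if retained[i]},
        settings=settings,
        n_failed_iterations=n_failed,
        all_frequencies={g: float(f) for g, f in zip(candidates, freq)},
        all_mean_coefficients={g: float(c) for g, c in zip(candidates, mean_coef)},
    )


def risk_score(model: SignatureModel, expression: pd.DataFrame) -> list[RiskScoreResult]:
    """Weighted sum of standardized expression; the cutoff is the cohort
    median and patients strictly above it form the high-risk group.

    Genes of the model missing from the matrix contribute 0 (their z-scale
    mean); more than 20% missing aborts.
    """
    genes = model.genes
    if not genes:
        raise ValueError("signature model is empty")
    present = [g for g in genes if g in expression.index]
    if len(present) < 0.8 * len(genes):
        raise ValueError(
            f"only {len(present)}/{len(genes)} signature genes present in expression matrix"
        )
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} signature genes missing; they contribute 0",
            stacklevel=2,
        )
    w = np.array([model.weights[g] for g in present])
    scores = pd.Series(w @ expression.loc[present].to_numpy(float), index=expression.columns)
    cutoff = float(scores.median())
    if scores.nunique() == 1:
        warnings.warn("all risk scores identical; high-risk group is empty", stacklevel=2)
    return [
        RiskScoreResult(
            patient_id=str(pid),
            score=float(s),
            group="high" if s > cutoff else "low",
            cutoff=cutoff,
        )
        for pid, s in scores.items()
    ]


def stratify_median(scores: list[RiskScoreResult]) -> tuple[list[str], list[str]]:
    """Partition patients into (high, low) risk groups at the median score.

    Scores equal to the median go to the low group, so the split is
    deterministic; an empty high group (all scores identical) is reported
    with a warning rather than silently passed on.
    """
    if len(scores) < 2:
        raise ValueError("need at least two patients to stratify")
    vals = np.array([s.score for s in scores])
    med = float(np.median(vals))
    high = [s.patient_id for s in scores if s.score > med]
    low = [s.patient_id for s in scores if s.score <= med]
    if not high:
        warnings.warn("median stratification produced an empty high-risk group", stacklevel=2)
    return high, low


# ---------------------------------------------------------------------------
# File formats


def read_cohort(expression_path, clinical_path, values_kind: str = "counts") -> SurvivalCohort:
    """Expression TSV (genes x patients) + clinical TSV
    (patient_id, time_days, event[, endpoint])."""
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    clin = pd.read_csv(clinical_path, sep="\t").set_index("patient_id")
    clin = clin.loc[expr.columns]
    endpoint = str(clin["endpoint"].iloc[0]) if "endpoint" in clin else "OS"
    return SurvivalCohort(
        expression=expr,
        time=clin["time_days"].astype(float),
        event=clin["event"].astype(int),
        endpoint=endpoint,
        values_kind=values_kind,
    )


def write_risk_scores(scores: list[RiskScoreResult], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in scores],
            "score": [s.score for s in scores],
            "group": [s.group for s in scores],
            "cutoff": [s.cutoff for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)
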