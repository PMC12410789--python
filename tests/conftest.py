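import warnings

import numpy as np
import pytest

import stromalink as sl

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def planted_cohort() -> sl.SurvivalCohort:
    """400 patients, 50 genes, one gene with log-hazard 1.0."""
    return sl.gen_survival_cohort(sl.SurvivalSimConfig(seed=3, signal_genes={"g0000": 1.0}))


@pytest.fixture(scope="session")
def planted_scores(planted_cohort) -> list[sl.RiskScoreResult]:
    """Risk scores driven by the planted gene (weight 1)."""
    vals = planted_cohort.expression.loc["g0000"]
    med = float(np.median(vals))
    return [
        sl.RiskScoreResult(pid, float(v), "high" if v > med else "low", med)
        for pid, v in vals.items()
    ]


@pytest.fixture(scope="session")
def noiseless_panel() -> sl.CoCulturePanel:
    """Deterministic linear chain M = 2X, Y = 3M."""
    return sl.gen_coculture_panel(
        sl.CoCultureSimConfig(
            noise_sd=0.0, gene_slope_sd=0.0, pair_slope_sd=0.0, slope_xz=2.0, slope_zy=3.0, seed=3
        )
    )
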