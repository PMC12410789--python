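"""Spot-level cell-type colocalization screen.

Deconvolved spatial-transcriptomics spots carry an estimated cell count per
cell type.  Presence is called by thresholding those counts, rare cell types
are dropped, and every remaining pair of types is tested for spatial
co-occupancy with a corrected odds ratio, a two-sided Fisher exact test, and
Benjamini-Hochberg FDR control across the screen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, OddsRatioResult, bh_fdr, fisher_exact, odds_ratio

__all__ = [
    "SpotMatrix",
    "PresenceMatrix",
    "ColocResult",
    "call_presence",
    "filter_prevalence",
    "pair_contingency",
    "coloc_screen",
    "coloc_results_frame",
    "read_spot_matrix_long",
    "read_spot_matrix_wide",
    "write_spot_matrix_long",
    "write_coloc_results",
]


@dataclass
class SpotMatrix:
    """Spots-by-cell-type estimated cell counts with spot coordinates.

    ``counts`` is indexed by (sample_id, spot_id) with one column per cell
    type; ``coords`` shares the index and has columns ``x`` and ``y``.
    """

    counts: pd.DataFrame
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("estimated cell counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("(sample_id, spot_id) pairs must be unique")
        if not self.counts.index.equals(self.coords.index):
            raise ValueError("counts and coords must share the same spot index")
        if self.counts.columns.has_duplicates:
            raise ValueError("cell-type labels must be unique")

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_spots(self) -> int:
        return len(self.counts)


@dataclass
class PresenceMatrix:
    """Boolean spot-by-cell-type occupancy derived by thresholding counts."""

    presence: pd.DataFrame
    threshold_used: float

    @property
    def cell_types(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_spots(self) -> int:
        return len(self.presence)


@dataclass
class ColocResult:
    """One unordered cell-type pair of the colocalization screen."""

    type_a: str
    type_b: str
    table: ContingencyTable2x2
    or_result: OddsRatioResult
    fdr: float = field(default=np.nan)


def call_presence(m: SpotMatrix, threshold: float = 1.0) -> PresenceMatrix:
    """Call a cell type present in a spot when its estimated count reaches
    ``threshold`` (default: one whole estimated cell)."""
    if threshold <= 0:
        raise ValueError("presence threshold must be positive")
    return PresenceMatrix(presence=m.counts >= threshold, threshold_used=float(threshold))


def filter_prevalence(p: PresenceMatrix, min_prevalence: float = 0.04) -> PresenceMatrix:
    """Drop cell types present in strictly less than ``min_prevalence`` of
    all (pooled) spots; types exactly at the threshold are retained."""
    if not 0 <= min_prevalence < 1:
        raise ValueError("min_prevalence must lie in [0, 1)")
    prev = p.presence.mean(axis=0)
    keep = prev[prev >= min_prevalence].index
    if len(keep) == 0:
        raise ValueError(
            f"prevalence filter at {min_prevalence:.3f} removed every cell type "
            f"(max prevalence {prev.max():.4f})"
        )
    return PresenceMatrix(presence=p.presence[keep], threshold_used=p.threshold_used)


def pair_contingency(p: PresenceMatrix, type_a: str, type_b: str) -> ContingencyTable2x2:
    """2x2 co-occupancy table over spots: a = both present, b = first only,
    c = second only, d = neither."""
    for t in (type_a, type_b):
        if t not in p.presence.columns:
            raise KeyError(f"unknown cell type {t!r}")
    pa = p.presence[type_a].to_numpy()
    pb = p.presence[type_b].to_numpy()
    a = int(np.sum(pa & pb))
    b = int(np.sum(pa & ~pb))
    c = int(np.sum(~pa & pb))
    d = int(np.sum(~pa & ~pb))
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def coloc_screen(p: PresenceMatrix, ci_level: float = 0.95) -> list[ColocResult]:
    """Corrected-OR colocalization test for every unordered pair of cell
    types, with BH-FDR across the whole screen.

    Results are sorted by FDR, then by decreasing |log OR|.  Spots from
    multiple samples are pooled: the tabulation only sees the pooled rows.
    """
    types = sorted(p.cell_types)
    if len(types) < 2:
        raise ValueError("need at least two cell types after prevalence filtering")
    results: list[ColocResult] = []
    for ta, tb in itertools.combinations(types, 2):
        table = pair_contingency(p, ta, tb)
        res = odds_ratio(table, ci_level=ci_level)
        results.append(ColocResult(type_a=ta, type_b=tb, table=table, or_result=res))
    fdrs = bh_fdr([r.or_result.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    results.sort(key=lambda r: (r.fdr, -abs(r.or_result.log_or)))
    return results


def coloc_results_frame(results: list[ColocResult]) -> pd.DataFrame:
    """Tabular view of a screen, one row per unordered pair."""
    rows = []
    for r in results:
        rows.append(
            {
                "type_a": r.type_a,
                "type_b": r.type_b,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "or": r.or_result.or_value,
                "log_or": r.or_result.log_or,
                "ci_low": r.or_result.ci_low,
                "ci_high": r.or_result.ci_high,
                "corrected": r.or_result.corrected,
                "p": r.or_result.p_value,
                "fdr": r.fdr,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File formats


def read_spot_matrix_long(path) -> SpotMatrix:
    """Long-format TSV: sample_id, spot_id, x, y, cell_type, estimated_cells."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "spot_id", "x", "y", "cell_type", "estimated_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format spot table is missing columns: {sorted(missing)}")
    counts = df.pivot_table(
        index=["sample_id", "spot_id"], columns="cell_type", values="estimated_cells"
    )
    if counts.isna().any().any():
        raise ValueError("every spot must report every cell type")
    counts.columns.name = None
    coords = (
        df.drop_duplicates(["sample_id", "spot_id"])
        .set_index(["sample_id", "spot_id"])[["x", "y"]]
        .reindex(counts.index)
    )
    return SpotMatrix(counts=counts, coords=coords)


def read_spot_matrix_wide(path, sample_id: str = "sample") -> SpotMatrix:
    """Wide-format CSV: spot_id, x, y, then one column per cell type."""
    df = pd.read_csv(path)
    if not {"spot_id", "x", "y"} <= set(df.columns):
        raise ValueError("wide-format spot table needs spot_id, x, y columns")
    df = df.assign(sample_id=df.get("sample_id", sample_id))
    df = df.set_index(["sample_id", "spot_id"])
    coords = df[["x", "y"]]
    counts = df.drop(columns=["x", "y"])
    return SpotMatrix(counts=counts, coords=coords)


def write_spot_matrix_long(m: SpotMatrix, path) -> None:
    long = (
        m.counts.stack()
        .rename("estimated_cells")
        .reset_index()
        .rename(columns={"level_2": "cell_type"})
    )
    long.columns = ["sample_id", "spot_id", "cell_type", "estimated_cells"]
    long = long.merge(m.coords.reset_index(), on=["sample_id", "spot_id"])
    long[["sample_id", "spot_id", "x", "y", "cell_type", "estimated_cells"]].to_csv(
        path, sep="\t", index=False
    )


def write_coloc_results(results: list[ColocResult], path) -> None:
    coloc_results_frame(results).to_csv(path, sep="\t", index=False)
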