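"""Joint in-silico / experimental screening report.

Joins the RED screening matrix, the relative-solubility table, the
fatty-acid class summaries and the experimental endpoints on solvent name
(inner join, unmatched names reported), then computes

* pairwise Pearson correlations of the antioxidant endpoints (TAC, DPPH
  IC50, FRAP EC50) against the compositional drivers (total sterols, total
  tocopherols, total phenols), on raw values with the endpoint's direction
  (higher-better vs lower-better) carried as explicit metadata rather than
  sign-flipped silently;
* Spearman rank concordance between the in-silico solvent orderings
  (aggregated RED, aggregated relative solubility) and the experimental
  yield ordering.

The study design is descriptive (six solvents): p-values are reported
unadjusted and labeled descriptive; every statistic carries its n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosmo import RelativeSolubilityTable
from .errors import (
    InsufficientOverlapError,
    InvalidInputError,
    UnknownIdentifierError,
)
from .hsp import ScreeningMatrix
from .quality import ClassSummary

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"

#: Direction of each experimental endpoint: IC50/EC50-type doses are
#: stronger when smaller.
ENDPOINT_DIRECTIONS: dict[str, str] = {
    "total_phenols": HIGHER_BETTER,
    "tac": HIGHER_BETTER,
    "dpph_ic50": LOWER_BETTER,
    "frap_ec50": LOWER_BETTER,
}

CORRELATION_ENDPOINTS = ("tac", "dpph_ic50", "frap_ec50")
CORRELATION_DRIVERS = ("total_sterols", "total_tocopherols", "total_phenols")

AGGREGATIONS = ("mean", "median", "worst")

__all__ = [
    "BioactivityTable",
    "ScreeningReport",
    "pearson_correlation",
    "spearman_concordance",
    "build_report",
    "ENDPOINT_DIRECTIONS",
    "LOWER_BETTER",
    "HIGHER_BETTER",
]


@dataclass
class BioactivityTable:
    """Per-sample experimental endpoints with direction metadata.

    `data` is indexed by sample (solvent) name; canonical columns are
    total_phenols, tac (mg GAE/g), dpph_ic50, frap_ec50 (µg/mL) plus any
    joined totals (total_sterols, total_tocopherols, mg/100 g) and
    extraction_yield (%).
    """

    data: pd.DataFrame
    directions: dict[str, str] = field(default_factory=lambda: dict(ENDPOINT_DIRECTIONS))

    def __post_init__(self) -> None:
        numeric = self.data.select_dtypes(include=[np.number])
        if (numeric.to_numpy() < 0).any():
            raise InvalidInputError("endpoints must be non-negative")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InvalidInputError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("zero variance in an input vector")
    return float(stats.pearsonr(x, y).statistic)


def spearman_concordance(
    rank_a: Mapping[str, float], rank_b: Mapping[str, float]
) -> float:
    """Spearman rho between two rankings of the same item set (average-rank ties)."""
    if set(rank_a) != set(rank_b):
        only_a = sorted(set(rank_a) - set(rank_b))
        only_b = sorted(set(rank_b) - set(rank_a))
        raise UnknownIdentifierError(
            f"item sets differ (only in a: {only_a}, only in b: {only_b})"
        )
    items = sorted(rank_a)
    a = [rank_a[i] for i in items]
    b = [rank_b[i] for i in items]
    return float(stats.spearmanr(a, b).statistic)


def _aggregate(values: np.ndarray, how: str) -> np.ndarray:
    """Collapse a solute × solvent grid to one score per solvent."""
    if how == "mean":
        return values.mean(axis=0)
    if how == "median":
        return np.median(values, axis=0)
    if how == "worst":
        return values.max(axis=0)
    raise InvalidInputError(f"unknown aggregation {how!r}; choose from {AGGREGATIONS}")


@dataclass
class ScreeningReport:
    """Assembled per-solvent table plus the derived statistics."""

    table: pd.DataFrame  # one row per joined solvent
    correlations: pd.DataFrame  # endpoint x driver: r, p, n, direction
    concordance: pd.DataFrame  # ranking pair: rho, n
    rankings: pd.DataFrame  # per-solvent ranks under each ordering
    unmatched: dict[str, list[str]]
    provenance: dict[str, str]
    aggregation: str

    def to_json_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "table": self.table.reset_index().to_dict(orient="records"),
            "correlations": self.correlations.reset_index(drop=True).to_dict(
                orient="records"
            ),
            "concordance": self.concordance.reset_index(drop=True).to_dict(
                orient="records"
            ),
            "rankings": self.rankings.reset_index().to_dict(orient="records"),
            "unmatched": self.unmatched,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.table.rename_axis("solvent").to_csv(path, float_format="%.12g")


def build_report(
    screen: ScreeningMatrix,
    rel_sol: RelativeSolubilityTable,
    quality: Sequence[ClassSummary],
    bioactivity: BioactivityTable,
    *,
    aggregation: str = "mean",
    reported_correlations: pd.DataFrame | None = None,
) -> ScreeningReport:
    """Join all screening layers on solvent name and derive the statistics.

    `reported_correlations` (columns endpoint, driver, r_reported), when
    given, is merged into the correlation table with the absolute difference
    against the recomputed coefficient — an informational comparison.
    """
    if aggregation not in AGGREGATIONS:
        raise InvalidInputError(
            f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}"
        )
    red_df = screen.to_frame()
    rel_df = rel_sol.to_frame()
    qual_df = pd.DataFrame(
        {
            s.sample: {
                "sfa": s.sfa,
                "mufa": s.mufa,
                "pufa": s.pufa,
                "pufa_sfa_ratio": s.pufa_sfa_ratio,
            }
            for s in quality
        }
    ).T
    bio_df = bioactivity.data

    sources = {
        "red": list(red_df.columns),
        "relative_solubility": list(rel_df.columns),
        "quality": list(qual_df.index),
        "bioactivity": list(bio_df.index),
    }
    joined = sorted(
        set(sources["red"])
        & set(sources["relative_solubility"])
        & set(sources["quality"])
        & set(sources["bioactivity"])
    )
    if len(joined) < 3:
        raise InsufficientOverlapError(
            f"only {len(joined)} solvents shared across inputs: {joined}"
        )
    unmatched = {
        src: sorted(set(names) - set(joined)) for src, names in sources.items()
    }

    # keep a stable, meaningful row order: bioactivity input order
    joined = [s for s in bio_df.index if s in joined]

    red_score = pd.Series(
        _aggregate(red_df[joined].to_numpy(), aggregation), index=joined
    )
    # relative solubilities are ≤ 0, larger = better: aggregate then negate so
    # that, like RED, a smaller aggregated score means a better solvent
    rel_score = pd.Series(
        -_aggregate(rel_df[joined].to_numpy(), aggregation), index=joined
    )

    table = pd.DataFrame(index=pd.Index(joined, name="solvent"))
    table[f"red_{aggregation}"] = red_score
    table[f"neg_relsol_{aggregation}"] = rel_score
    table = table.join(qual_df.loc[joined]).join(bio_df.loc[joined])

    # average-rank ties: the report must not depend on input row order
    rankings = pd.DataFrame(index=pd.Index(joined, name="solvent"))
    rankings["red_rank"] = stats.rankdata(red_score.to_numpy(), method="average")
    rankings["relsol_rank"] = stats.rankdata(rel_score.to_numpy(), method="average")
    if "extraction_yield" in table.columns:
        rankings["yield_rank"] = stats.rankdata(
            -table["extraction_yield"].to_numpy(), method="average"
        )

    n = len(joined)
    corr_rows = []
    for endpoint in CORRELATION_ENDPOINTS:
        for driver in CORRELATION_DRIVERS:
            if endpoint not in table.columns or driver not in table.columns:
                continue
            x = table[driver].to_numpy(dtype=float)
            y = table[endpoint].to_numpy(dtype=float)
            res = stats.pearsonr(x, y)
            corr_rows.append(
                {
                    "endpoint": endpoint,
                    "driver": driver,
                    "r": float(res.statistic),
                    "p_descriptive": float(res.pvalue),
                    "n": n,
                    "direction": bioactivity.directions.get(endpoint, HIGHER_BETTER),
                }
            )
    correlations = pd.DataFrame(corr_rows)
    if reported_correlations is not None and not correlations.empty:
        correlations = correlations.merge(
            reported_correlations, on=["endpoint", "driver"], how="left"
        )
        correlations["abs_difference"] = (
            correlations["r"] - correlations["r_reported"]
        ).abs()

    conc_rows = []
    pairs = [("red_rank", "relsol_rank")]
    if "yield_rank" in rankings.columns:
        pairs += [("red_rank", "yield_rank"), ("relsol_rank", "yield_rank")]
    for a, b in pairs:
        rho = spearman_concordance(rankings[a].to_dict(), rankings[b].to_dict())
        conc_rows.append({"ranking_a": a, "ranking_b": b, "rho": rho, "n": n})
    concordance = pd.DataFrame(conc_rows)

    provenance = {
        "red": "RED screening matrix (Hansen model)",
        "relative_solubility": "normalized log10 relative solubility",
        "quality": "fatty-acid class summaries",
        "bioactivity": "experimental endpoints and joined totals",
    }
    return ScreeningReport(
        table=table,
        correlations=correlations,
        concordance=concordance,
        rankings=rankings,
        unmatched=unmatched,
        provenance=provenance,
        aggregation=aggregation,
    )
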