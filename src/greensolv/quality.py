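"""Oil-composition analytics.

Fatty-acid profiles are percent-of-total tables keyed by the usual
C<carbons>:<double bonds> codes; the double-bond count alone classifies an
acid as saturated (0), monounsaturated (1) or polyunsaturated (≥ 2), and the
class sums ∑SFA/∑MUFA/∑PUFA with the nutritional PUFA/SFA ratio summarize a
profile.  Sterol and tocopherol contents (mg/100 g oil) are summed per
family; when a table carries a printed total it is treated as an annotation
to check against — recomputed totals are always reported and disagreements
flagged, never silently overwritten.  Extraction yield is crude-oil mass as
a percent of dry seed mass.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FattyAcidCodeError,
    InvalidInputError,
    UndefinedRatioError,
)

SFA = "SFA"
MUFA = "MUFA"
PUFA = "PUFA"

STEROL = "sterol"
TOCOPHEROL = "tocopherol"

#: Columns of 2-decimal percentages may miss 100 by rounding and minor
#: unlisted peaks; deviations inside this band warn rather than fail.
COMPOSITION_TOTAL_TOL = 3.0
#: mg/100 g band for printed family totals vs the recomputed component sum.
PRINTED_TOTAL_TOL = 2.0

_CODE_RE = re.compile(r"^C(\d+):(\d+)$")

__all__ = [
    "FattyAcidProfile",
    "ClassSummary",
    "ComponentTable",
    "ValidationReport",
    "classify_fatty_acid",
    "class_sums",
    "summary_table",
    "component_totals",
    "compare_totals",
    "compare_summary",
    "extraction_yield",
    "validate_profile",
    "profiles_from_wide",
    "read_composition_csv",
    "read_composition_long_csv",
    "truncate",
    "SFA",
    "MUFA",
    "PUFA",
    "STEROL",
    "TOCOPHEROL",
]


def classify_fatty_acid(code: str) -> str:
    """Class label for a Cx:y fatty-acid code: y=0 → SFA, y=1 → MUFA, y≥2 → PUFA."""
    m = _CODE_RE.match(code)
    if not m:
        raise FattyAcidCodeError(f"malformed fatty-acid code {code!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    if carbons < 2:
        raise FattyAcidCodeError(f"fatty-acid code {code!r} has fewer than 2 carbons")
    if double_bonds == 0:
        return SFA
    if double_bonds == 1:
        return MUFA
    return PUFA


@dataclass
class FattyAcidProfile:
    """Per-sample fatty-acid percentages keyed by Cx:y code."""

    sample: str
    entries: dict[str, float]

    def total(self) -> float:
        return float(sum(self.entries.values()))


@dataclass(frozen=True)
class ClassSummary:
    """Class sums of one profile, % of total fatty acids.

    ``pufa_sfa_ratio`` is None when the profile has no saturated fat; use
    :meth:`ratio` to fail loudly instead.
    """

    sample: str
    sfa: float
    mufa: float
    pufa: float
    pufa_sfa_ratio: float | None

    def ratio(self) -> float:
        if self.pufa_sfa_ratio is None:
            raise UndefinedRatioError(
                f"PUFA/SFA undefined for {self.sample!r}: SFA sum is 0"
            )
        return self.pufa_sfa_ratio


def class_sums(profile: FattyAcidProfile) -> ClassSummary:
    """Sum percentages by saturation class; ratio at full precision."""
    sums = {SFA: 0.0, MUFA: 0.0, PUFA: 0.0}
    for code, pct in profile.entries.items():
        pct = float(pct)
        if not math.isfinite(pct) or pct < 0:
            raise InvalidInputError(f"{profile.sample}: {code} has invalid value {pct!r}")
        sums[classify_fatty_acid(code)] += pct
    ratio = sums[PUFA] / sums[SFA] if sums[SFA] > 0 else None
    return ClassSummary(
        sample=profile.sample,
        sfa=sums[SFA],
        mufa=sums[MUFA],
        pufa=sums[PUFA],
        pufa_sfa_ratio=ratio,
    )


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate toward zero at `decimals` places (display convention of the
    packaged reference table's PUFA/SFA row, which is truncated, not rounded)."""
    factor = 10.0**decimals
    return math.trunc(x * factor + math.copysign(1e-9, x)) / factor


def summary_table(summaries: Sequence[ClassSummary], decimals: int = 2) -> pd.DataFrame:
    """Display table with rows SFA/MUFA/PUFA/PUFA:SFA, one column per sample.

    Class sums are rounded at `decimals` (exact for 2-decimal inputs); the
    ratio row is truncated at `decimals`, matching the convention of the
    packaged reference summary rows.
    """
    data = {}
    for s in summaries:
        data[s.sample] = [
            round(s.sfa, decimals),
            round(s.mufa, decimals),
            round(s.pufa, decimals),
            truncate(s.ratio(), decimals) if s.pufa_sfa_ratio is not None else np.nan,
        ]
    return pd.DataFrame(data, index=[SFA, MUFA, PUFA, "PUFA/SFA"])


def compare_summary(
    recomputed: pd.DataFrame, printed: pd.DataFrame, *, atol: float = 0.005
) -> pd.DataFrame:
    """Long-format comparison of a recomputed class-summary display table
    against printed summary-row annotations.

    Rows are (row, sample) pairs with recomputed, printed, discrepancy and a
    flag for disagreement beyond `atol` (default: equality at 2 decimals).
    Discrepancies are flagged, never corrected.
    """
    rows = []
    for row in recomputed.index:
        for sample in recomputed.columns:
            rec = float(recomputed.loc[row, sample])
            prt = float(printed.loc[row, sample]) if row in printed.index else np.nan
            rows.append(
                {
                    "row": row,
                    "sample": sample,
                    "recomputed": rec,
                    "printed": prt,
                    "discrepancy": rec - prt,
                    "flagged": bool(abs(rec - prt) > atol),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outcome of profile validation; `issues` lists offending entries."""

    sample: str
    valid: bool
    total: float
    issues: list[str] = field(default_factory=list)


def validate_profile(
    profile: FattyAcidProfile, *, total_tol: float = COMPOSITION_TOTAL_TOL
) -> ValidationReport:
    """Check code syntax, non-negativity and that percentages total near 100."""
    issues: list[str] = []
    total = 0.0
    for code, pct in profile.entries.items():
        if not _CODE_RE.match(code):
            issues.append(f"malformed code {code!r}")
            continue
        pct = float(pct)
        if not math.isfinite(pct):
            issues.append(f"{code}: non-finite value")
        elif pct < 0:
            issues.append(f"{code}: negative percentage {pct}")
        else:
            total += pct
    if total > 100.0 + total_tol:
        issues.append(f"total {total:.2f}% exceeds 100 + {total_tol}")
    elif total < 100.0 - total_tol and profile.entries:
        issues.append(f"total {total:.2f}% falls short of 100 - {total_tol}")
    return ValidationReport(
        sample=profile.sample, valid=not issues, total=total, issues=issues
    )


# ---------------------------------------------------------------------------
# sterol / tocopherol component tables


@dataclass
class ComponentTable:
    """Component × sample contents (mg/100 g oil) for one family, with the
    table's printed per-sample totals carried as annotations."""

    family: str
    data: pd.DataFrame  # component rows x sample columns
    printed_totals: pd.Series | None = None  # per-sample annotation

    def __post_init__(self) -> None:
        if self.family not in (STEROL, TOCOPHEROL):
            raise InvalidInputError(f"unknown component family {self.family!r}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise InvalidInputError("component contents must be >= 0")


def component_totals(table: ComponentTable, family: str | None = None) -> pd.Series:
    """Arithmetic per-sample sum of the family's components, mg/100 g."""
    if family is not None and family != table.family:
        raise InvalidInputError(
            f"table holds {table.family!r} components, not {family!r}"
        )
    return table.data.sum(axis=0).astype(float)


def compare_totals(
    table: ComponentTable, *, tol: float = PRINTED_TOTAL_TOL
) -> pd.DataFrame:
    """Recomputed vs printed totals with the discrepancy and a flag.

    The recomputed value is authoritative; a printed total further than
    `tol` mg/100 g away is flagged, never overwritten.
    """
    recomputed = component_totals(table)
    if table.printed_totals is None:
        raise InvalidInputError("table carries no printed totals to compare")
    printed = table.printed_totals.reindex(recomputed.index).astype(float)
    discrepancy = recomputed - printed
    return pd.DataFrame(
        {
            "recomputed": recomputed,
            "printed": printed,
            "discrepancy": discrepancy,
            "flagged": discrepancy.abs() > tol,
        }
    )


def extraction_yield(mass_oil: float, mass_seeds: float) -> float:
    """Crude-oil mass as percent of dry-seed mass."""
    if not math.isfinite(mass_seeds) or mass_seeds <= 0:
        raise InvalidInputError(f"mass_seeds={mass_seeds!r} must be > 0")
    if not math.isfinite(mass_oil) or mass_oil < 0:
        raise InvalidInputError(f"mass_oil={mass_oil!r} must be >= 0")
    return 100.0 * mass_oil / mass_seeds


# ---------------------------------------------------------------------------
# delimited-text I/O


def profiles_from_wide(df: pd.DataFrame) -> list[FattyAcidProfile]:
    """Wide table (code rows × sample columns) → per-sample profiles."""
    return [
        FattyAcidProfile(sample=str(col), entries=df[col].astype(float).to_dict())
        for col in df.columns
    ]


def read_composition_csv(path: str | Path) -> pd.DataFrame:
    """Wide composition CSV: first column analyte code/name, one column per sample."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0]).astype(float)


def read_composition_long_csv(path: str | Path) -> pd.DataFrame:
    """Long composition CSV (sample, analyte, value) → wide analyte × sample."""
    df = pd.read_csv(path)
    expected = {"sample", "analyte", "value"}
    if not expected.issubset(df.columns):
        raise InvalidInputError(f"long format requires columns {sorted(expected)}")
    wide = df.pivot(index="analyte", columns="sample", values="value")
    wide.columns.name = None
    return wide.astype(float)
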