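"""Relative-solubility scoring from chemical potentials.

COSMO-RS-style screening ranks solvents for a solute by the base-10 log of
its predicted solubility at infinite dilution,

    log10 x_j = (μ_pure − μ_solvent − ΔG_fusion) / (R·T·ln 10),

with μ_pure the chemical potential of the pure compound, μ_solvent its
chemical potential at infinite dilution in the candidate solvent (both
J/mol), ΔG_fusion the free energy of fusion (0 for solutes liquid at the
working temperature) and R = 8.314 J/(mol·K).  For screening, each solute's
row is normalized by subtracting its maximum so the best solvent reads
exactly 0 and every other solvent a negative offset.

The chemical potentials themselves come from external quantum-chemistry
software; this module consumes them (or an already-normalized relative-
solubility matrix) and never recomputes them from structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyInputError, InvalidInputError, NormalizationError

R_GAS = 8.314  # J/(mol*K)
LN10 = math.log(10.0)
DEFAULT_TEMPERATURE = 298.15  # K

NORMALIZATION_TOL = 1e-9

__all__ = [
    "ChemicalPotentialRecord",
    "RelativeSolubilityTable",
    "log10_solubility",
    "normalize_best_to_zero",
    "rank_by_relative_solubility",
    "table_from_records",
    "read_relative_solubility_csv",
    "read_chemical_potentials_csv",
    "R_GAS",
    "DEFAULT_TEMPERATURE",
]


@dataclass(frozen=True)
class ChemicalPotentialRecord:
    """Thermodynamic inputs for one solute–solvent pair."""

    solute: str
    solvent: str
    mu_pure: float  # J/mol
    mu_solvent: float  # J/mol, at infinite dilution
    dg_fusion: float = 0.0  # J/mol, 0 for liquids at working temperature
    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise InvalidInputError(f"temperature={self.temperature!r} must be > 0")
        if not math.isfinite(self.dg_fusion) or self.dg_fusion < 0:
            raise InvalidInputError(f"dg_fusion={self.dg_fusion!r} must be >= 0")
        for field_name in ("mu_pure", "mu_solvent"):
            if not math.isfinite(getattr(self, field_name)):
                raise InvalidInputError(f"{field_name} must be finite")


def log10_solubility(rec: ChemicalPotentialRecord) -> float:
    """log10 of predicted solubility at infinite dilution (dimensionless)."""
    return (rec.mu_pure - rec.mu_solvent - rec.dg_fusion) / (
        R_GAS * rec.temperature * LN10
    )


def normalize_best_to_zero(row: Sequence[float]) -> np.ndarray:
    """Subtract the row maximum: best solvent maps to 0, order preserved.

    Idempotent; raises on empty or non-finite input.
    """
    arr = np.asarray(row, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot normalize an empty row")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("row contains non-finite values")
    return arr - arr.max()


@dataclass
class RelativeSolubilityTable:
    """Normalized solute × solvent grid of log10 relative solubilities.

    Every row maximum is 0 (the reference solvent); `reference_solvent`
    records, per solute, the first solvent (input order) attaining 0.
    """

    solutes: list[str]
    solvents: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.solutes), len(self.solvents)):
            raise InvalidInputError("grid shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("relative solubilities must be finite")

    @property
    def reference_solvent(self) -> dict[str, str]:
        refs = {}
        for solute, row in zip(self.solutes, self.values):
            refs[solute] = self.solvents[int(np.argmax(row))]
        return refs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.solutes, columns=self.solvents)

    def normalized(self) -> "RelativeSolubilityTable":
        return RelativeSolubilityTable(
            self.solutes,
            self.solvents,
            np.vstack([normalize_best_to_zero(r) for r in self.values]),
        )


def table_from_records(
    records: Sequence[ChemicalPotentialRecord],
) -> RelativeSolubilityTable:
    """Assemble and normalize a table from per-pair chemical potentials."""
    if len(records) == 0:
        raise EmptyInputError("no chemical-potential records supplied")
    solutes = list(dict.fromkeys(r.solute for r in records))
    solvents = list(dict.fromkeys(r.solvent for r in records))
    raw = np.full((len(solutes), len(solvents)), np.nan)
    for r in records:
        raw[solutes.index(r.solute), solvents.index(r.solvent)] = log10_solubility(r)
    if np.any(np.isnan(raw)):
        raise InvalidInputError("incomplete solute x solvent grid of records")
    values = np.vstack([normalize_best_to_zero(row) for row in raw])
    return RelativeSolubilityTable(solutes, solvents, values)


def rank_by_relative_solubility(table: RelativeSolubilityTable) -> pd.DataFrame:
    """Per-solute solvent ranks, 1 = best; equal values share the top rank of
    their band (competition ranking), report order follows solvent input order.

    Requires a normalized table (row maxima 0 within 1e-9).
    """
    row_max = table.values.max(axis=1)
    if np.any(np.abs(row_max) > NORMALIZATION_TOL):
        bad = [s for s, m in zip(table.solutes, row_max) if abs(m) > NORMALIZATION_TOL]
        raise NormalizationError(f"rows not normalized to 0 max: {bad}")
    ranks = np.vstack(
        [rankdata(-row, method="min").astype(int) for row in table.values]
    )
    return pd.DataFrame(ranks, index=table.solutes, columns=table.solvents)


def read_relative_solubility_csv(path: str | Path) -> RelativeSolubilityTable:
    """Read a solute-rows × solvent-columns relative-solubility CSV."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0]).astype(float)
    return RelativeSolubilityTable(list(df.index), list(df.columns), df.to_numpy())


def read_chemical_potentials_csv(path: str | Path) -> list[ChemicalPotentialRecord]:
    """Read per-pair records: solute, solvent, mu_pure, mu_solvent
    [, dg_fusion, temperature]."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        if "dg_fusion" in df.columns and pd.notna(row["dg_fusion"]):
            kwargs["dg_fusion"] = float(row["dg_fusion"])
        if "temperature" in df.columns and pd.notna(row["temperature"]):
            kwargs["temperature"] = float(row["temperature"])
        records.append(
            ChemicalPotentialRecord(
                solute=str(row["solute"]),
                solvent=str(row["solvent"]),
                mu_pure=float(row["mu_pure"]),
                mu_solvent=float(row["mu_solvent"]),
                **kwargs,
            )
        )
    return records
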