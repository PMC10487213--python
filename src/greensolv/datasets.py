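"""Packaged reference data for the sesame-oil green-solvent study.

Six solvents (n-hexane as the petroleum reference; the bio-based MeTHF,
CPME, d-limonene, p-cymene and ethanol) screened against the five major
lipid solutes of sesame oil (palmitic, oleic and linoleic acid,
γ-tocopherol, β-sitosterol).  The files transcribe the study's printed
tables: solvent properties and Hansen coordinates, the RED screening
matrix, the normalized COSMO-RS relative solubilities, fatty-acid
compositions with their printed class-summary rows, sterol and tocopherol
contents with printed family totals, phenolic/antioxidant endpoints,
extraction yields and the study's reported composition–activity correlation
coefficients.

Printed totals and summary rows are annotations to check against, not
inputs: the analytics recompute them and flag disagreements (the tables
contain a few internal inconsistencies, which the loaders carry verbatim).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cosmo import RelativeSolubilityTable, read_relative_solubility_csv
from .hsp import SolventRecord, read_red_matrix_csv, read_solvents_csv
from .quality import (
    STEROL,
    TOCOPHEROL,
    ComponentTable,
    FattyAcidProfile,
    profiles_from_wide,
    read_composition_csv,
)
from .report import BioactivityTable

__all__ = [
    "SOLVENTS",
    "SOLUTES",
    "load_solvents",
    "load_red_matrix",
    "load_relative_solubility",
    "load_fatty_acids",
    "load_fatty_acid_profiles",
    "load_fatty_acid_summary",
    "load_component_table",
    "load_bioactivity",
    "load_yields",
    "load_reported_correlations",
    "load_fatty_acid_names",
]

SOLVENTS = ["n-Hexane", "MeTHF", "CPME", "d-Limonene", "p-Cymene", "Ethanol"]
SOLUTES = ["C16:0", "C18:1", "C18:2", "gamma-Tocopherol", "beta-Sitosterol"]


def _path(name: str):
    return resources.files("greensolv.data").joinpath(name)


def load_solvents() -> list[SolventRecord]:
    """The six study solvents: Hansen coordinates plus physical properties."""
    with resources.as_file(_path("solvents.csv")) as p:
        return read_solvents_csv(p)


def load_red_matrix() -> pd.DataFrame:
    """RED screening matrix, solute rows × solvent columns."""
    with resources.as_file(_path("red_matrix.csv")) as p:
        return read_red_matrix_csv(p)


def load_relative_solubility() -> RelativeSolubilityTable:
    """Normalized log10 relative solubilities, solute rows × solvent columns."""
    with resources.as_file(_path("relative_solubility.csv")) as p:
        return read_relative_solubility_csv(p)


def load_fatty_acids() -> pd.DataFrame:
    """Fatty-acid percentages, code rows × solvent columns."""
    with resources.as_file(_path("fatty_acids.csv")) as p:
        return read_composition_csv(p)


def load_fatty_acid_profiles() -> list[FattyAcidProfile]:
    return profiles_from_wide(load_fatty_acids())


def load_fatty_acid_summary() -> pd.DataFrame:
    """Printed class-summary rows (SFA/MUFA/PUFA/PUFA:SFA) as annotations."""
    with resources.as_file(_path("fatty_acid_summary.csv")) as p:
        return read_composition_csv(p)


def load_component_table(family: str) -> ComponentTable:
    """Sterol or tocopherol contents with the printed totals as annotations."""
    filename = {STEROL: "sterols.csv", TOCOPHEROL: "tocopherols.csv"}[family]
    with resources.as_file(_path(filename)) as p:
        df = read_composition_csv(p)
    printed = df.loc["Total"]
    return ComponentTable(
        family=family, data=df.drop(index="Total"), printed_totals=printed
    )


def load_yields() -> pd.Series:
    """Extraction yields, % of dry seed mass, per solvent."""
    with resources.as_file(_path("yields.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("sample")["extraction_yield"].astype(float)


def load_bioactivity(join_totals: bool = True) -> BioactivityTable:
    """Experimental endpoints; by default joined with the recomputed sterol
    and tocopherol totals and the extraction yields."""
    with resources.as_file(_path("bioactivity.csv")) as p:
        df = pd.read_csv(p).set_index("sample").astype(float)
    if join_totals:
        df["total_sterols"] = load_component_table(STEROL).data.sum(axis=0)
        df["total_tocopherols"] = load_component_table(TOCOPHEROL).data.sum(axis=0)
        df["extraction_yield"] = load_yields()
    return BioactivityTable(data=df)


def load_reported_correlations() -> pd.DataFrame:
    """The study's reported r values (endpoint, driver, r_reported) —
    informational metadata, compared but never asserted."""
    with resources.as_file(_path("reported_correlations.csv")) as p:
        return pd.read_csv(p)


def load_fatty_acid_names() -> dict[str, str]:
    """Optional Cx:y → common-name lookup."""
    with resources.as_file(_path("fatty_acid_names.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["code"], df["common_name"]))
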