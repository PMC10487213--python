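"""Hansen solubility parameter (HSP) mathematics.

A solvent or solute is a point (δd, δp, δh) in Hansen space, MPa^1/2:
dispersion, polar and hydrogen-bonding contributions to the cohesive energy
density.  A solute carries in addition an interaction radius R_spher; the
sphere of that radius around its coordinate is the region of solvents
expected to dissolve it.  The solvent–solute affinity score is the relative
energy difference

    RED = R_solv / R_spher,

where R_solv is the Hansen distance

    R_solv = sqrt(4·(δd_solute − δd_solvent)² + (δp_solute − δp_solvent)²
                  + (δh_solute − δh_solvent)²).

The factor 4 on the dispersion axis is the empirical anisotropy of the
classical Hansen model.  RED < 1 (solvent inside the sphere) predicts a
good solvent; RED ≥ 1 predicts a poor one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifierError,
    EmptyInputError,
    InvalidInputError,
    InvalidSphereError,
)

SUITABLE = "suitable"
UNSUITABLE = "unsuitable"

__all__ = [
    "HSPTriple",
    "SolventRecord",
    "SoluteSphere",
    "ScreeningMatrix",
    "total_solubility_parameter",
    "hansen_distance",
    "red_number",
    "classify_red",
    "screen_solvents",
    "screening_from_red",
    "rank_ascending",
    "read_solvents_csv",
    "write_solvents_csv",
    "read_spheres_csv",
    "write_spheres_csv",
    "read_red_matrix_csv",
    "SUITABLE",
    "UNSUITABLE",
]


@dataclass(frozen=True)
class HSPTriple:
    """Hansen coordinate (δd, δp, δh), MPa^1/2; components finite and ≥ 0."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        for name in ("delta_d", "delta_p", "delta_h"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(
                    f"HSP component {name}={v!r} must be finite and non-negative"
                )
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_d, self.delta_p, self.delta_h], dtype=float)


@dataclass(frozen=True)
class SolventRecord:
    """A named solvent: Hansen coordinate plus optional physical properties."""

    name: str
    hsp: HSPTriple
    boiling_point: float | None = None
    log_p: float | None = None
    molecular_weight: float | None = None
    viscosity: float | None = None
    resource: str | None = None
    cmr_class: str | None = None


@dataclass(frozen=True)
class SoluteSphere:
    """A solute's Hansen-sphere center and interaction radius R_spher (> 0)."""

    name: str
    center: HSPTriple
    r_spher: float

    def __post_init__(self) -> None:
        r = float(self.r_spher)
        if not math.isfinite(r) or r <= 0:
            raise InvalidSphereError(f"r_spher={r!r} must be finite and > 0")
        object.__setattr__(self, "r_spher", r)


def total_solubility_parameter(hsp: HSPTriple) -> float:
    """Hildebrand total parameter: Euclidean norm of the Hansen triple."""
    return float(math.sqrt(hsp.delta_d**2 + hsp.delta_p**2 + hsp.delta_h**2))


def hansen_distance(solute: HSPTriple, solvent: HSPTriple) -> float:
    """4-weighted Hansen distance R_solv between two coordinates, MPa^1/2."""
    return float(
        math.sqrt(
            4.0 * (solute.delta_d - solvent.delta_d) ** 2
            + (solute.delta_p - solvent.delta_p) ** 2
            + (solute.delta_h - solvent.delta_h) ** 2
        )
    )


def red_number(r_solv: float, r_spher: float) -> float:
    """Relative energy difference R_solv / R_spher (dimensionless, ≥ 0)."""
    if not math.isfinite(r_spher) or r_spher <= 0:
        raise InvalidSphereError(f"r_spher={r_spher!r} must be > 0")
    if not math.isfinite(r_solv) or r_solv < 0:
        raise InvalidInputError(f"r_solv={r_solv!r} must be finite and >= 0")
    return float(r_solv) / float(r_spher)


def classify_red(red: float) -> str:
    """Suitability label for a RED score.

    RED strictly below 1 means the solvent sits inside the solute's sphere
    and is classified ``suitable``; the boundary RED == 1 goes to
    ``unsuitable`` (suitability is defined strictly).
    """
    if not math.isfinite(red) or red < 0:
        raise InvalidInputError(f"RED={red!r} must be finite and >= 0")
    return SUITABLE if red < 1.0 else UNSUITABLE


def rank_ascending(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n, 1 = smallest; ties broken by input order (stable sort)."""
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def _check_unique(names: Iterable[str], kind: str) -> list[str]:
    names = list(names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DuplicateIdentifierError(f"duplicate {kind} names: {dupes}")
    return names


@dataclass
class ScreeningMatrix:
    """Solute × solvent grid of RED scores with labels and per-solute ranks.

    ``values[i, j]`` is the RED of solvent j for solute i; ``labels`` holds
    the suitable/unsuitable classification and ``ranks`` the within-row
    ordering (1 = lowest RED, ties broken by solvent input order).
    """

    solutes: list[str]
    solvents: list[str]
    values: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.solutes = _check_unique(self.solutes, "solute")
        self.solvents = _check_unique(self.solvents, "solvent")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.solutes), len(self.solvents)):
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.solutes)} solutes x {len(self.solvents)} solvents"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidInputError("RED values must be finite and >= 0")
        if self.labels is None:
            self.labels = np.vectorize(classify_red)(self.values)
        if self.ranks is None:
            self.ranks = np.vstack([rank_ascending(row) for row in self.values])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.solutes, columns=self.solvents)

    def label_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.solutes, columns=self.solvents)

    def rank_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=self.solutes, columns=self.solvents)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("solute").to_csv(path, float_format="%.12g")

    def to_json_dict(self) -> dict:
        return {
            "solutes": self.solutes,
            "solvents": self.solvents,
            "values": self.values.tolist(),
            "labels": self.labels.tolist(),
            "ranks": self.ranks.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def screen_solvents(
    spheres: Sequence[SoluteSphere], solvents: Sequence[SolventRecord]
) -> ScreeningMatrix:
    """Score every solvent against every solute sphere.

    ``values[i, j] = hansen_distance(center_i, hsp_j) / r_spher_i``; labels
    and per-solute ranks follow.
    """
    if len(spheres) == 0 or len(solvents) == 0:
        raise EmptyInputError("need at least one solute sphere and one solvent")
    _check_unique([s.name for s in spheres], "solute")
    _check_unique([s.name for s in solvents], "solvent")
    values = np.array(
        [
            [
                red_number(hansen_distance(sphere.center, solv.hsp), sphere.r_spher)
                for solv in solvents
            ]
            for sphere in spheres
        ]
    )
    return ScreeningMatrix(
        solutes=[s.name for s in spheres],
        solvents=[s.name for s in solvents],
        values=values,
    )


def screening_from_red(red: pd.DataFrame) -> ScreeningMatrix:
    """Wrap an externally supplied RED table (solute rows × solvent columns)."""
    return ScreeningMatrix(
        solutes=list(red.index),
        solvents=list(red.columns),
        values=red.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

_NUMERIC_OPTIONAL = ("boiling_point", "log_p", "molecular_weight", "viscosity")
_TEXT_OPTIONAL = ("resource", "cmr_class")
_OPTIONAL_COLUMNS = _NUMERIC_OPTIONAL + _TEXT_OPTIONAL


def read_solvents_csv(path: str | Path) -> list[SolventRecord]:
    """Read a solvent set from CSV with columns name, delta_d, delta_p, delta_h
    plus any of the optional property columns."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        extra = {}
        for col in _NUMERIC_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                extra[col] = float(row[col])
        for col in _TEXT_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                value = row[col]
                # an all-blank-but-one text column parses numeric; keep text
                if isinstance(value, float) and value.is_integer():
                    value = int(value)
                extra[col] = str(value)
        records.append(
            SolventRecord(
                name=str(row["name"]),
                hsp=HSPTriple(row["delta_d"], row["delta_p"], row["delta_h"]),
                **extra,
            )
        )
    _check_unique([r.name for r in records], "solvent")
    return records


def write_solvents_csv(records: Sequence[SolventRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "name": r.name,
            "delta_d": r.hsp.delta_d,
            "delta_p": r.hsp.delta_p,
            "delta_h": r.hsp.delta_h,
        }
        for col in _OPTIONAL_COLUMNS:
            value = getattr(r, col)
            if value is not None:
                row[col] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_spheres_csv(path: str | Path) -> list[SoluteSphere]:
    """Read solute spheres from CSV: name, delta_d, delta_p, delta_h, r_spher."""
    df = pd.read_csv(path)
    spheres = [
        SoluteSphere(
            name=str(row["name"]),
            center=HSPTriple(row["delta_d"], row["delta_p"], row["delta_h"]),
            r_spher=row["r_spher"],
        )
        for _, row in df.iterrows()
    ]
    _check_unique([s.name for s in spheres], "solute")
    return spheres


def write_spheres_csv(spheres: Sequence[SoluteSphere], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "delta_d": s.center.delta_d,
                "delta_p": s.center.delta_p,
                "delta_h": s.center.delta_h,
                "r_spher": s.r_spher,
            }
            for s in spheres
        ]
    ).to_csv(path, index=False, float_format="%.12g")


def read_red_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a RED matrix CSV (first column = solute, one column per solvent)."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0]).astype(float)
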