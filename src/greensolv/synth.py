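"""Synthetic inputs with known ground truth.

Every stage of the screening pipeline can be exercised without any external
data: solvent sets drawn uniformly over a Hansen-space box, RED rows
generated from a known sphere with additive Gaussian noise (truncated at 0,
since RED is non-negative by definition), compositional fatty-acid profiles
drawn on the simplex (symmetric Dirichlet, so the class-partition/closure
property holds exactly), and bioactivity endpoints built to a controlled
population correlation with a compositional driver.  Defaults mirror the
scale of the packaged study: six solvents, ten fatty acids, endpoints on the
order of the packaged experimental table.

All draws derive from a single integer seed; rerunning with the same spec is
bit-reproducible, and serialized fixtures are written at 12 significant
digits.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .hsp import (
    HSPTriple,
    SoluteSphere,
    SolventRecord,
    write_solvents_csv,
)
from .inverse import predict_red
from .quality import FattyAcidProfile
from .report import (
    BioactivityTable,
    ENDPOINT_DIRECTIONS,
    HIGHER_BETTER,
    LOWER_BETTER,
)

__all__ = [
    "SyntheticSpec",
    "gen_solvent_set",
    "gen_red_table",
    "gen_composition",
    "gen_bioactivity",
    "default_fatty_acid_codes",
    "simulate_sphere_recovery",
    "simulate_correlation_calibration",
    "write_fixture_dir",
]

#: Hansen-space sampling box bracketing common extraction solvents, MPa^1/2.
DEFAULT_HSP_RANGES: dict[str, tuple[float, float]] = {
    "delta_d": (13.0, 16.0),
    "delta_p": (0.0, 10.0),
    "delta_h": (0.0, 16.0),
}

#: Location/scale of each synthetic endpoint, on the packaged table's order
#: of magnitude; sign follows the endpoint's direction metadata.
ENDPOINT_SCALES: dict[str, tuple[float, float]] = {
    "total_phenols": (18.0, 3.0),
    "tac": (2.5, 0.4),
    "dpph_ic50": (110.0, 20.0),
    "frap_ec50": (700.0, 120.0),
}


def _default_sphere() -> SoluteSphere:
    # a lipid-like solute: mid-box center, generous interaction radius
    return SoluteSphere(name="synthetic-solute", center=HSPTriple(17.0, 3.0, 5.0), r_spher=8.0)


@dataclass
class SyntheticSpec:
    """Knobs of the generators; one seed fixes every downstream draw."""

    seed: int = 0
    n_solvents: int = 6
    hsp_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HSP_RANGES)
    )
    sphere_truth: SoluteSphere = field(default_factory=_default_sphere)
    red_noise_sd: float = 0.05
    n_fatty_acids: int = 10
    composition_concentration: float = 1.0
    target_correlation: float = 0.9
    n_samples: int = 6

    def __post_init__(self) -> None:
        if self.red_noise_sd < 0:
            raise InvalidSpecError("red_noise_sd must be >= 0")
        if self.composition_concentration <= 0:
            raise InvalidSpecError("composition_concentration must be > 0")
        if abs(self.target_correlation) > 1:
            raise InvalidSpecError("target_correlation must lie in [-1, 1]")
        for comp, (lo, hi) in self.hsp_ranges.items():
            if lo > hi:
                raise InvalidSpecError(f"degenerate range for {comp}: ({lo}, {hi})")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator per named stream."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode()) % 2**31])


def gen_solvent_set(spec: SyntheticSpec) -> list[SolventRecord]:
    """Solvents with HSPs uniform in the spec's box; names S1..Sn."""
    rng = spec.rng("solvents")
    records = []
    for i in range(spec.n_solvents):
        coords = {
            comp: rng.uniform(lo, hi) for comp, (lo, hi) in spec.hsp_ranges.items()
        }
        records.append(SolventRecord(name=f"S{i + 1}", hsp=HSPTriple(**coords)))
    return records


def gen_red_table(
    spec: SyntheticSpec, solvents: Sequence[SolventRecord]
) -> tuple[np.ndarray, dict]:
    """Observed RED row from the spec's truth sphere plus the truth record.

    observed_j = max(distance_j / R_spher + eps_j, 0), eps ~ N(0, sd).
    """
    rng = spec.rng("red")
    noise_free = predict_red(spec.sphere_truth, solvents)
    eps = rng.normal(0.0, spec.red_noise_sd, size=len(solvents)) if spec.red_noise_sd else np.zeros(len(solvents))
    observed = np.maximum(noise_free + eps, 0.0)
    truth = {
        "sphere": spec.sphere_truth,
        "noise_free_red": noise_free,
        "noise_sd": spec.red_noise_sd,
    }
    return observed, truth


def default_fatty_acid_codes(n: int) -> list[str]:
    """Valid Cx:y codes cycling the three saturation classes."""
    if n < 2:
        raise InvalidSpecError("need at least 2 fatty acids")
    return [f"C{8 + 2 * i}:{i % 3}" for i in range(n)]


def gen_composition(spec: SyntheticSpec) -> list[FattyAcidProfile]:
    """Per-sample simplex draws scaled to 100% over class-spanning codes."""
    rng = spec.rng("composition")
    codes = default_fatty_acid_codes(spec.n_fatty_acids)
    alpha = np.full(spec.n_fatty_acids, spec.composition_concentration)
    profiles = []
    for i in range(spec.n_samples):
        pct = rng.dirichlet(alpha) * 100.0
        profiles.append(
            FattyAcidProfile(sample=f"S{i + 1}", entries=dict(zip(codes, pct)))
        )
    return profiles


def gen_bioactivity(
    spec: SyntheticSpec, driver: Sequence[float]
) -> BioactivityTable:
    """Endpoints linear in `driver` plus noise, sized so the population
    correlation equals ±target_correlation (sign per endpoint direction).

    With z the standardized driver, each endpoint is loc + scale·x where
    x = s·ρ·z + sqrt(1 − ρ²)·e, e ~ N(0,1), and s = −1 for IC50/EC50-type
    endpoints (stronger activity at lower dose).
    """
    driver = np.asarray(driver, dtype=float)
    if driver.shape != (spec.n_samples,):
        raise InvalidSpecError(
            f"driver length {driver.shape} does not match n_samples={spec.n_samples}"
        )
    if np.ptp(driver) == 0:
        raise InvalidSpecError("driver must vary across samples")
    rng = spec.rng("bioactivity")
    rho = spec.target_correlation
    z = (driver - driver.mean()) / driver.std()
    data = {"total_sterols": driver}
    for endpoint, (loc, scale) in ENDPOINT_SCALES.items():
        sign = -1.0 if ENDPOINT_DIRECTIONS[endpoint] == LOWER_BETTER else 1.0
        noise = rng.standard_normal(spec.n_samples) if abs(rho) < 1 else 0.0
        x = sign * rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        data[endpoint] = np.maximum(loc + scale * x, 0.0)
    # a second positive driver so report joins have tocopherol totals too
    toco_noise = rng.standard_normal(spec.n_samples) if abs(rho) < 1 else 0.0
    toco = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * toco_noise
    data["total_tocopherols"] = np.maximum(46.0 + 4.0 * toco, 0.0)
    df = pd.DataFrame(data, index=[f"S{i + 1}" for i in range(spec.n_samples)])
    df.index.name = "sample"
    return BioactivityTable(data=df)


def simulate_sphere_recovery(
    *,
    truth: SoluteSphere | None = None,
    noise_sds: Sequence[float] = (0.0, 0.02, 0.05, 0.1),
    n_reps: int = 100,
    seed: int = 0,
    n_solvents: int = 6,
    n_starts: int = 16,
) -> pd.DataFrame:
    """Parameter-recovery simulation for the inverse sphere fit.

    Per replicate, a fresh solvent set is drawn and one standard-normal
    noise vector is shared across all noise levels (common random numbers,
    so recovery degradation is measured against identical perturbation
    shapes); observed RED = max(noise-free + sd·eps, tiny).  Returns one row
    per noise sd with the mean Euclidean center error, mean |radius error|
    and mean residual RMS over replicates.
    """
    from .inverse import fit_sphere_from_red  # local import to avoid a cycle

    truth = truth or _default_sphere()
    center_true = truth.center.as_array()
    rows = {sd: {"center_err": [], "radius_err": [], "rms": []} for sd in noise_sds}
    for rep in range(n_reps):
        rep_spec = SyntheticSpec(seed=seed + rep, n_solvents=n_solvents)
        solvents = gen_solvent_set(rep_spec)
        noise_free = predict_red(truth, solvents)
        eps = rep_spec.rng("recovery-noise").standard_normal(n_solvents)
        for sd in noise_sds:
            observed = np.maximum(noise_free + sd * eps, 1e-9)
            fit = fit_sphere_from_red(
                solvents, observed, n_starts=n_starts, seed=seed + rep
            )
            rows[sd]["center_err"].append(
                float(np.linalg.norm(fit.sphere.center.as_array() - center_true))
            )
            rows[sd]["radius_err"].append(abs(fit.sphere.r_spher - truth.r_spher))
            rows[sd]["rms"].append(fit.residual_rms)
    return pd.DataFrame(
        {
            "noise_sd": list(noise_sds),
            "mean_center_error": [np.mean(rows[sd]["center_err"]) for sd in noise_sds],
            "mean_radius_error": [np.mean(rows[sd]["radius_err"]) for sd in noise_sds],
            "mean_residual_rms": [np.mean(rows[sd]["rms"]) for sd in noise_sds],
        }
    )


def simulate_correlation_calibration(
    *,
    target_correlation: float = 0.9,
    n_samples: int = 200,
    n_reps: int = 500,
    seed: int = 0,
    endpoint: str = "tac",
) -> pd.DataFrame:
    """Calibration of the bioactivity generator: recovered Pearson
    coefficient between the driver and `endpoint` over `n_reps` regenerated
    tables.  Returns per-replicate coefficients (column ``r``)."""
    from scipy.stats import pearsonr

    coeffs = []
    for rep in range(n_reps):
        spec = SyntheticSpec(
            seed=seed + rep,
            n_samples=n_samples,
            target_correlation=target_correlation,
        )
        driver = spec.rng("driver").uniform(400.0, 800.0, n_samples)
        table = gen_bioactivity(spec, driver)
        coeffs.append(
            float(pearsonr(table.data["total_sterols"], table.data[endpoint]).statistic)
        )
    return pd.DataFrame({"replicate": np.arange(n_reps), "r": coeffs})


def write_fixture_dir(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory: solvents.csv, red.csv, relsol.csv,
    composition.csv, bioactivity.csv and truth.json (12 significant digits)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    solvents = gen_solvent_set(spec)
    paths["solvents"] = out / "solvents.csv"
    write_solvents_csv(solvents, paths["solvents"])

    observed, truth = gen_red_table(spec, solvents)
    red_df = pd.DataFrame(
        [observed], index=[spec.sphere_truth.name], columns=[s.name for s in solvents]
    )
    paths["red"] = out / "red.csv"
    red_df.rename_axis("solute").to_csv(paths["red"], float_format="%.12g")

    # relative-solubility surrogate: monotone map of -RED, then normalized
    rel = -red_df.to_numpy()
    rel = rel - rel.max(axis=1, keepdims=True)
    paths["relsol"] = out / "relsol.csv"
    pd.DataFrame(rel, index=red_df.index, columns=red_df.columns).rename_axis(
        "solute"
    ).to_csv(paths["relsol"], float_format="%.12g")

    profiles = gen_composition(spec)
    comp = pd.DataFrame({p.sample: p.entries for p in profiles})
    paths["composition"] = out / "composition.csv"
    comp.rename_axis("code").to_csv(paths["composition"], float_format="%.12g")

    bio = gen_bioactivity(spec, driver=spec.rng("driver").uniform(400, 800, spec.n_samples))
    paths["bioactivity"] = out / "bioactivity.csv"
    bio.data.to_csv(paths["bioactivity"], float_format="%.12g")

    sphere = spec.sphere_truth
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(
        json.dumps(
            {
                "seed": spec.seed,
                "sphere": {
                    "name": sphere.name,
                    "delta_d": sphere.center.delta_d,
                    "delta_p": sphere.center.delta_p,
                    "delta_h": sphere.center.delta_h,
                    "r_spher": sphere.r_spher,
                },
                "noise_free_red": [float(f"{v:.12g}") for v in truth["noise_free_red"]],
                "red_noise_sd": spec.red_noise_sd,
                "target_correlation": spec.target_correlation,
            },
            indent=2,
        )
    )
    return paths
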