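"""Inverse Hansen-sphere estimation.

Published screening tables often print the RED score of each solvent for a
solute without printing the solute's sphere (center δd, δp, δh and radius
R_spher) behind it.  Given the solvents' Hansen coordinates and an observed
RED row, the sphere is recoverable as the least-squares minimizer of

    sum_j ( R_solv,j(center) / R_spher  −  RED_obs,j )²

over a bounded box.  The objective is non-convex — a far-away center with a
large radius imitates a close center with a small one — so the fit is
multi-started from a low-discrepancy (Sobol) design over the box and the
best terminal objective kept.

A coarse grid search over the same box serves as an independent oracle in
the tests; `grid_search_oracle` scans the center grid exhaustively and, for
each center, exploits that the objective is a convex quadratic in 1/R_spher,
so its minimum over the radius grid is attained at a grid point bracketing
the unconstrained minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import (
    InvalidInputError,
    RankDeficientError,
    UnderdeterminedError,
    UnknownIdentifierError,
)
from .hsp import HSPTriple, SoluteSphere, SolventRecord

__all__ = [
    "BOUNDS",
    "InverseFitResult",
    "fit_sphere_from_red",
    "grid_search_oracle",
    "loo_predict_red",
    "predict_red",
]

# (δd, δp, δh, R_spher) box, MPa^1/2: brackets the Hansen coordinates of
# lipid-extraction solvents with margin and keeps the radius scale bounded.
BOUNDS = np.array([[10.0, 25.0], [0.0, 20.0], [0.0, 25.0], [0.5, 25.0]])

MIN_SOLVENTS = 5  # 4 unknowns + 1
DEFAULT_N_STARTS = 16


@dataclass
class InverseFitResult:
    """Outcome of a sphere fit: recovered sphere plus diagnostics."""

    sphere: SoluteSphere
    residual_rms: float
    predicted_red: np.ndarray
    residuals: np.ndarray  # signed, predicted − observed, per solvent
    objective: float  # sum of squared residuals
    converged: bool
    n_starts_used: int


def _solvent_coords(solvents: Sequence[SolventRecord]) -> np.ndarray:
    return np.array([s.hsp.as_array() for s in solvents])


def _distances(params3: np.ndarray, coords: np.ndarray) -> np.ndarray:
    d = coords - params3
    return np.sqrt(4.0 * d[:, 0] ** 2 + d[:, 1] ** 2 + d[:, 2] ** 2)


def predict_red(sphere: SoluteSphere, solvents: Sequence[SolventRecord]) -> np.ndarray:
    """Forward model: RED of each solvent under a given sphere."""
    coords = _solvent_coords(solvents)
    return _distances(sphere.center.as_array(), coords) / sphere.r_spher


def _validate(solvents: Sequence[SolventRecord], observed: np.ndarray) -> np.ndarray:
    observed = np.asarray(observed, dtype=float)
    if len(solvents) < MIN_SOLVENTS:
        raise UnderdeterminedError(
            f"need at least {MIN_SOLVENTS} solvents to constrain 4 sphere "
            f"parameters, got {len(solvents)}"
        )
    if observed.shape != (len(solvents),):
        raise InvalidInputError(
            f"observed RED vector length {observed.shape} does not match "
            f"{len(solvents)} solvents"
        )
    if not np.all(np.isfinite(observed)) or np.any(observed <= 0):
        raise InvalidInputError("observed RED values must be finite and > 0")
    coords = _solvent_coords(solvents)
    if np.allclose(coords, coords[0], atol=1e-12):
        raise RankDeficientError("all solvents share one Hansen coordinate")
    return observed


def fit_sphere_from_red(
    solvents: Sequence[SolventRecord],
    observed_red: Sequence[float],
    *,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    name: str = "solute",
) -> InverseFitResult:
    """Recover a solute sphere from an observed RED row by bounded
    multi-start nonlinear least squares.

    Parameters
    ----------
    solvents : solvent records with known Hansen coordinates (≥ 5, distinct).
    observed_red : per-solvent RED observations (> 0).
    n_starts : number of Sobol starting points over the bound box.
    seed : scrambling seed of the Sobol design (default 0, documented).
    name : identifier given to the recovered sphere.
    """
    observed = _validate(solvents, np.asarray(observed_red, dtype=float))
    coords = _solvent_coords(solvents)

    def residual(x: np.ndarray) -> np.ndarray:
        return _distances(x[:3], coords) / x[3] - observed

    sampler = qmc.Sobol(d=4, scramble=True, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), BOUNDS[:, 0], BOUNDS[:, 1])

    # two deterministic data-driven starts guard against the Sobol design
    # missing the global basin: the solvent centroid and the lowest-RED
    # solvent's coordinate, each with a moment-matched radius estimate
    def _with_radius(center3: np.ndarray) -> np.ndarray:
        d = _distances(center3, coords)
        r_est = np.median(d) / max(np.median(observed), 1e-6)
        x = np.concatenate([center3, [r_est]])
        return np.clip(x, BOUNDS[:, 0] + 1e-6, BOUNDS[:, 1] - 1e-6)

    extra = [
        _with_radius(coords.mean(axis=0)),
        _with_radius(coords[int(np.argmin(observed))]),
    ]
    starts = np.vstack([starts, extra])

    best = None
    for x0 in starts:
        sol = least_squares(
            residual,
            x0,
            bounds=(BOUNDS[:, 0], BOUNDS[:, 1]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    assert best is not None
    params = best.x
    predicted = _distances(params[:3], coords) / params[3]
    residuals = predicted - observed
    objective = float(np.sum(residuals**2))
    return InverseFitResult(
        sphere=SoluteSphere(
            name=name,
            center=HSPTriple(params[0], params[1], params[2]),
            r_spher=float(params[3]),
        ),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        predicted_red=predicted,
        residuals=residuals,
        objective=objective,
        converged=bool(best.status > 0),
        n_starts_used=len(starts),
    )


def grid_search_oracle(
    solvents: Sequence[SolventRecord],
    observed_red: Sequence[float],
    *,
    step: float = 0.25,
) -> tuple[np.ndarray, float]:
    """Exact minimum of the fit objective over the `step`-spaced grid on the
    bound box; returns (best (δd, δp, δh, R), objective).

    Per center the objective  t²·Σd² − 2t·Σ(d·obs) + Σobs²  with t = 1/R is
    convex in t, so its grid minimum lies at a radius grid point adjacent to
    the clamped unconstrained minimizer; only those candidates are evaluated.
    """
    observed = _validate(solvents, np.asarray(observed_red, dtype=float))
    coords = _solvent_coords(solvents)

    axes = [np.arange(lo, hi + step / 2, step) for lo, hi in BOUNDS[:3]]
    radii = np.arange(BOUNDS[3, 0], BOUNDS[3, 1] + step / 2, step)
    t_grid = 1.0 / radii  # descending in R, ascending in t reversed; order irrelevant

    gd, gp, gh = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gd.ravel(), gp.ravel(), gh.ravel()], axis=1)

    sum_obs2 = float(np.dot(observed, observed))
    best_obj = np.inf
    best_params = None
    # chunk the center grid to bound peak memory
    for chunk in np.array_split(centers, max(1, len(centers) // 200_000)):
        diff = chunk[:, None, :] - coords[None, :, :]
        dist = np.sqrt(
            4.0 * diff[:, :, 0] ** 2 + diff[:, :, 1] ** 2 + diff[:, :, 2] ** 2
        )
        a = np.einsum("ij,ij->i", dist, dist)  # Σ d²
        b = dist @ observed  # Σ d·obs
        t_star = np.clip(b / a, t_grid.min(), t_grid.max())
        # radius grid points bracketing 1/t*: indices into the (ascending) radii
        r_star = 1.0 / t_star
        hi_idx = np.clip(np.searchsorted(radii, r_star), 0, len(radii) - 1)
        lo_idx = np.clip(hi_idx - 1, 0, len(radii) - 1)
        for idx in (lo_idx, hi_idx):
            t = 1.0 / radii[idx]
            obj = a * t**2 - 2.0 * b * t + sum_obs2
            k = int(np.argmin(obj))
            if obj[k] < best_obj:
                best_obj = float(obj[k])
                best_params = np.array([*chunk[k], radii[idx[k]]])

    assert best_params is not None
    return best_params, best_obj


def loo_predict_red(
    solvents: Sequence[SolventRecord],
    observed_red: Sequence[float],
    held_out: str,
    *,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> float:
    """Leave-one-out prediction: fit the sphere without `held_out`, then
    predict that solvent's RED from the fitted sphere."""
    names = [s.name for s in solvents]
    if held_out not in names:
        raise UnknownIdentifierError(f"unknown solvent {held_out!r}")
    idx = names.index(held_out)
    kept = [s for i, s in enumerate(solvents) if i != idx]
    observed = np.asarray(observed_red, dtype=float)
    if observed.shape != (len(solvents),):
        raise InvalidInputError("observed RED vector length mismatch")
    kept_obs = np.delete(observed, idx)
    fit = fit_sphere_from_red(kept, kept_obs, n_starts=n_starts, seed=seed)
    return float(predict_red(fit.sphere, [solvents[idx]])[0])


def fit_report_dict(result: InverseFitResult, solvents: Sequence[SolventRecord],
                    observed_red: Sequence[float]) -> dict:
    """JSON-serializable per-solute fit report."""
    return {
        "solute": result.sphere.name,
        "center": {
            "delta_d": result.sphere.center.delta_d,
            "delta_p": result.sphere.center.delta_p,
            "delta_h": result.sphere.center.delta_h,
        },
        "r_spher": result.sphere.r_spher,
        "residual_rms": result.residual_rms,
        "objective": result.objective,
        "converged": result.converged,
        "n_starts_used": result.n_starts_used,
        "solvents": [s.name for s in solvents],
        "observed_red": list(map(float, observed_red)),
        "predicted_red": result.predicted_red.tolist(),
        "residuals": result.residuals.tolist(),
    }
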