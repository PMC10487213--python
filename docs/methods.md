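# Methods

## Hansen model

A solvent's cohesive energy density is decomposed into dispersion, polar and
hydrogen-bonding contributions δd, δp, δh (MPa^1/2); the Hildebrand total is
the Euclidean norm of the triple. Solvent–solute affinity uses the
anisotropic Hansen distance with the classical factor-4 weight on the
dispersion axis, and the relative energy difference RED = R_solv/R_spher.
The suitability rule is strict: RED < 1 → suitable, RED ≥ 1 → unsuitable,
so a solvent exactly on the sphere boundary is classified unsuitable (the
suitable class is defined by strict inequality; the boundary goes to the
complement). Components equal to 0 are legal coordinates — near-zero polar
and hydrogen-bonding values are physically meaningful for alkanes. Units
are fixed to MPa^1/2 throughout; there is no unit-conversion layer and no
temperature dependence of the parameters.

Within a screening row, solvents are ranked by ascending RED with ties
broken by input order (a stable sort), so ranks are always a 1..n
permutation and rerunning is bit-reproducible.

## Inverse sphere estimation

Published RED tables usually omit the solute spheres behind them. The fit
minimizes Σ_j (R_solv,j(center)/R_spher − RED_obs,j)² over the box
δd ∈ [10, 25], δp ∈ [0, 20], δh ∈ [0, 25], R_spher ∈ [0.5, 25] MPa^1/2.
The box brackets the Hansen coordinates of lipid-extraction solvents with
margin; unbounded fits can drift along the scale degeneracy of the
objective (a far-away center with a proportionally large radius imitates a
near center with a small one), which the radius bound cuts off.

The objective is non-convex, so the solver (trust-region-reflective least
squares, tolerances 1e-14) is multi-started: 16 points of a scrambled Sobol
design over the box, plus two deterministic data-driven starts — the
solvent centroid and the lowest-RED solvent's coordinate, each with a
moment-matched radius estimate median(distance)/median(observed RED). The
data-driven starts were added because a pure 16-point low-discrepancy
design can miss the global basin on rare solvent geometries and terminate
on a boundary local minimum; with them, noise-free recovery across 100
random instances is exact to ~1e-14. The best terminal objective wins.
Requirements: at least 5 solvents (4 unknowns), distinct solvent
coordinates, strictly positive observed REDs.

Diagnostics are RMS and signed per-solvent residuals, plus leave-one-out
prediction (refit without a named solvent, predict its RED). For the
packaged reference rows the fit is reported, not asserted: those REDs came
from proprietary group-contribution solute parameters, a per-solute single
sphere reproduces them only approximately (residual RMS 0.14–0.46), and
whether the original table used one shared radius per solute is unknowable
from the printed values.

An independent test oracle scans the same box on a 0.25-step grid. It is
exact for that grid: for a fixed center the objective is a convex quadratic
in t = 1/R_spher, so its minimum over the radius grid must lie at one of
the two grid radii bracketing the unconstrained minimizer, and only those
are evaluated. This keeps the full scan vectorized and cheap while
guaranteeing the optimizer is never reported better than it is.

## Relative solubility

log10 x_j = (μ_pure − μ_solvent − ΔG_fusion)/(R·T·ln 10), R = 8.314
J/(mol·K). The natural-log-scale quantity (chemical-potential difference
over RT) is converted to base 10 by the ln 10 factor — the standard and the
only dimensionally coherent reading of the screening expression. Defaults:
T = 298.15 K when a record omits temperature, ΔG_fusion = 0 (solutes liquid
at working temperature). Rows are normalized by subtracting the row maximum
(idempotent, order-preserving); ranking requires normalization within 1e-9
and uses competition ranking so tied best solvents share rank 1. The
chemical potentials themselves are external inputs: the packaged
relative-solubility matrix is reference data produced by quantum-chemistry
software, and the package never claims to recompute it from structure.

## Oil-quality analytics

Fatty acids are classified purely by the double-bond count of the Cx:y code
(0 → SFA, 1 → MUFA, ≥ 2 → PUFA); common names are an optional lookup only,
since prose and footnotes in source tables occasionally swap names while
the codes stay consistent. Class sums are computed at full precision; the
PUFA/SFA ratio is undefined (raises) when SFA = 0.

Display conventions follow the packaged reference table: class sums are
shown at 2 decimals (exact, since the inputs are 2-decimal percentages) and
the PUFA/SFA display row is *truncated* at 2 decimals rather than rounded —
the reference table's printed ratios (e.g. 42.56/15.71 = 2.7091 printed as
2.70) are truncations, and the display helper reproduces that convention so
recomputed and printed rows are comparable cell by cell. Full-precision
values are always available from `ClassSummary`.

Composition columns are validated to total 100 ± 3 percentage points
(rounding and minor unlisted peaks make exact closure impossible);
violations are reported, not fatal. Sterol/tocopherol family totals are
compared to printed totals with a ±2 mg/100 g tolerance; the recomputed
value is always reported next to the printed one with the discrepancy. The
packaged tables contain known internal inconsistencies — the d-limonene
∑SFA cell (printed 15.66 vs component sum 15.76, with the printed ratio
2.52 consistent only with the former), the n-hexane and ethanol sterol
totals (printed 568 and 588 vs component sums 553.71 and 540.17), and the
CPME α-tocopherol value (62.7, irreconcilable with the printed CPME total
52.3) — which are carried verbatim and flagged, never corrected, since
inventing a correction would be worse than reporting the conflict.

## Joint report

The report inner-joins all layers on solvent name (≥ 3 shared solvents
required; unmatched names reported per source). One in-silico ranking per
solvent comes from aggregating the solute × solvent grid — mean by default,
median and worst-case available — because the source analysis ranks
solvents globally without stating an aggregation. Report-level rankings use
average-rank ties so the report is invariant to input row order (the two
ether solvents tie at 0 on aggregated relative solubility, which
input-order tie-breaking would make order-sensitive).

Correlations are computed on raw endpoint values with an explicit
direction flag (IC50/EC50-type endpoints are stronger when smaller) instead
of silently sign-flipping. With six solvents the study is descriptive:
p-values are unadjusted and labeled descriptive, and every statistic
carries its n. The study's reported correlation coefficients ship as
metadata and are compared informationally with the absolute difference:
they are not reproducible from the printed per-solvent means (they were
plausibly computed on replicate-level data that was never published), so
the report prints both and asserts neither. Whether the original
correlations used n = 6 solvent means or n = 18 replicates is unstated;
the package computes on the means and says so.

## Synthetic data

The generators emulate the study's data shapes with known truth: 6 solvents
with HSPs uniform over δd 13–16, δp 0–10, δh 0–16 (bracketing all six real
solvents), a default truth sphere (17, 3, 5, R = 8) on the lipid-solute
scale, RED noise additive Gaussian truncated at 0 (RED is non-negative by
definition; no error model exists in the source), 10 fatty-acid codes
cycling the three classes with symmetric-Dirichlet simplex draws scaled to
100 (closure holds exactly by construction, default concentration 1 giving
strongly uneven profiles like real oils), and bioactivity endpoints
loc + scale·(s·ρ·z + sqrt(1 − ρ²)·e) with z the standardized driver,
s = −1 for dose-type endpoints, and loc/scale on the order of the packaged
experimental table. One integer seed derives a separate stream per
generator (CRC-based stream keys), so runs are bit-reproducible and
serialized fixtures (12 significant digits) round-trip through the
package's readers.

What the synthetic data does not emulate: correlated fatty-acid profiles
across solvents (real profiles are near-identical across solvents; the
generator draws them independently), replicate-level measurement error
structure, and any chromatographic or assay artifacts. Passing synthetic
tests therefore demonstrates correctness of the computations and estimator
calibration, not robustness to real instrument noise.

## Simulation designs

The noise-degradation study (sd ∈ {0, 0.02, 0.05, 0.1}, 100 replicates per
level) shares one standard-normal draw per replicate across all noise
levels (common random numbers): each level sees the same perturbation shape
scaled by its sd, which removes between-level Monte-Carlo variance from the
monotonicity comparison. Recovery error is the Euclidean center distance,
averaged over replicates. The correlation calibration regenerates 500
tables at n = 200, ρ = 0.9 and averages the recovered Pearson coefficient
(the estimator's O(1/n) bias at this n is ~4e-4, far inside the ±0.02
band). Problem sizes throughout (6 solvents, 50–100 fit replicates, 500
calibration replicates) were chosen as the smallest designs that make the
Monte-Carlo error negligible relative to the effects being checked.

## Known limitations

- No estimation of Hansen parameters from molecular structure; solute
  spheres come from inverse fitting only, and exact agreement with
  group-contribution values is not expected.
- No quantum chemistry: chemical potentials and the packaged
  relative-solubility matrix are consumed as given.
- The classical sphere fit from binary good/bad solubility data is not
  implemented (the screening workflow never uses it).
- Significance letters from the source tables are carried as annotations
  only; no ANOVA/post-hoc machinery is provided.
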