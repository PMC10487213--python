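# greensolv

In-silico screening of green solvents for edible seed-oil extraction, with
oil-quality analytics. The package implements the computational layer of a
solvent-substitution study for sesame seed oil: can bio-based solvents
(2-methyltetrahydrofuran, cyclopentyl methyl ether, d-limonene, p-cymene,
ethanol) replace petroleum-derived n-hexane?

It is written for extraction scientists and formulators who want to rank
candidate solvents *before* going to the bench, and to check in-silico
predictions against experimental oil quality afterwards.

## What it computes

**Hansen solubility screening.** Each solvent is a point (δd, δp, δh) in
Hansen space (MPa^1/2); each solute has a solubility sphere with center
(δd, δp, δh) and radius R_spher. The affinity score is the relative energy
difference

    RED = R_solv / R_spher,
    R_solv = sqrt(4 (δd,solute − δd,solvent)² + (δp,solute − δp,solvent)²
                  + (δh,solute − δh,solvent)²),

with RED < 1 predicting a good solvent. `hsp.screen_solvents` builds the
solute × solvent RED matrix with suitability labels and per-solute ranks;
`inverse.fit_sphere_from_red` solves the inverse problem — recovering an
unpublished sphere (center + radius) from a printed RED row — by bounded
multi-start least squares, with a grid-search oracle, residual diagnostics
and leave-one-out prediction.

**Relative solubility.** `cosmo.log10_solubility` evaluates
log10 x_j = (μ_pure − μ_solvent − ΔG_fusion)/(R·T·ln 10) from supplied
chemical potentials (the quantum-chemistry step that produces them is out of
scope); rows are normalized so the best solvent reads exactly 0 and solvents
are ranked per solute with shared top ranks for ties.

**Oil quality.** `quality` classifies Cx:y fatty-acid codes by double-bond
count (SFA/MUFA/PUFA), sums classes and the nutritional PUFA/SFA ratio,
totals sterol and tocopherol contents (mg/100 g oil), validates composition
tables, and computes extraction yield. Printed totals in the packaged
reference tables are annotations: recomputed values are reported and
disagreements flagged, never silently corrected.

**Joint report.** `report.build_report` joins the RED screening, the
relative-solubility ranking, the composition summaries and the experimental
endpoints over the shared solvents, computing composition–activity Pearson
correlations (with explicit higher-better / lower-better direction metadata
for IC50/EC50-type endpoints) and Spearman rank concordance between the
in-silico and experimental solvent orderings.

**Synthetic data.** `synth` generates every input with known ground truth
(solvent sets, RED rows from a known sphere with truncated Gaussian noise,
Dirichlet compositional profiles closing to 100%, bioactivity tables with a
controlled target correlation), so the whole pipeline is testable offline.

The reference tables of the six-solvent sesame-oil study ship as packaged
CSV fixtures under `greensolv.datasets`.

## Worked example

```python
from greensolv import datasets
from greensolv.hsp import screening_from_red

red = datasets.load_red_matrix()
matrix = screening_from_red(red)
print(red.mean(axis=0).sort_values().round(3))
```

prints the per-solvent mean RED over the five major sesame-oil solutes
(palmitic, oleic, linoleic acid, γ-tocopherol, β-sitosterol):

```
d-Limonene    0.568
MeTHF         0.924
CPME          1.368
p-Cymene      1.488
n-Hexane      1.904
Ethanol       4.130
```

Lower is better: d-limonene is the strongest theoretical substitute
(RED < 1, i.e. inside the solubility sphere, for all five solutes), the
ether solvents MeTHF and CPME follow, and ethanol (mean RED 4.13, every
value > 2) is predicted worse than the n-hexane reference. Fatty-acid class
sums from the packaged composition table:

```python
from greensolv.quality import class_sums, summary_table
print(summary_table([class_sums(p) for p in datasets.load_fatty_acid_profiles()]))
```

```
          n-Hexane  MeTHF   CPME  d-Limonene  p-Cymene  Ethanol
SFA          14.57  15.71  12.59       15.76     18.10    16.20
MUFA         42.94  39.82  42.42       44.76     40.99    40.97
PUFA         44.32  42.56  43.58       39.52     39.59    43.57
PUFA/SFA      3.04   2.70   3.46        2.50      2.18     2.68
```

CPME gives the best nutritional PUFA/SFA ratio (3.46). The full narrative
analysis lives in the numbered scripts under `analysis/`
(`01_hsp_screening.py` … `06_synthetic_validation.py`), each of which writes
its tables under `results/`.

A console script exposes the same pipeline from the shell:

```sh
greensolv screen --spheres my_spheres.csv     # RED matrix for your solutes
greensolv quality                             # composition summaries + total checks
greensolv report                              # joined statistics
greensolv synth --seed 7 --out fixtures/      # synthetic data with truth.json
```

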