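"""Relative-solubility ranking of the packaged reference data.

Verifies each solute row of the log10 relative-solubility matrix is already
normalized (best solvent at exactly 0), ranks solvents per solute with
shared top ranks for ties, and writes the ranking under results/.
"""

from pathlib import Path

import numpy as np

from greensolv import datasets
from greensolv.cosmo import normalize_best_to_zero, rank_by_relative_solubility

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = datasets.load_relative_solubility()

    renorm = table.normalized()
    max_shift = float(np.abs(renorm.values - table.values).max())
    ranks = rank_by_relative_solubility(table)
    ranks.rename_axis("solute").to_csv(OUT / "relsol_ranks.csv")

    print("log10 relative solubility (solute x solvent):")
    print(table.to_frame().to_string())
    print(f"\nNormalization check: re-normalizing shifts values by at most {max_shift:g}.")
    print("\nPer-solute solvent ranks (1 = best, ties share the band):")
    print(ranks.to_string())
    joint_best = (ranks[["MeTHF", "CPME"]] == 1).all(axis=None)
    print(f"\nFinding: MeTHF and CPME are jointly top-ranked for every solute: {joint_best}.")


if __name__ == "__main__":
    main()
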