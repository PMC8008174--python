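"""Generate the synthetic hatch-of-fertile study data.

Emulates the field data on a desk scale: a hierarchical pedigree
(25 sires x 5 dams x 4 offspring = 500 phenotyped hens), weekly records
from 27 to 58 weeks of age with ~30% missing weeks, contemporary groups
of 3 hatch weeks, egg storage age ~3.2 +/- 1.4 d, and 5-6 eggs set per
hen-week.  Records are generated the way the real trait arises: each
hen-week's hatched count is binomial in the fertile eggs with a
logit-scale liability carrying the lay-cycle curve plus genetic, hen
and mate permanent-environment effects (liability variances 0.45 /
0.30 / 0.05, i.e. a liability heritability of 0.11 once the logistic
residual pi^2/3 is counted), and %HoF is the count ratio — so the
linear models downstream face exactly the coarse, bounded percentages
that field data deliver.

Writes pedigree.txt, phenotypes.csv and truth.json under results/data/.
"""

import json
import sys
from pathlib import Path

from hofgen.components import VarianceComponents
from hofgen.io import write_pedigree, write_phenotypes
from hofgen.simulate import SimulationConfig, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

#: liability-scale truth: with the logistic residual pi^2/3 these give
#: h2_liab = 0.45 / (0.45 + 0.30 + 0.05 + 3.29) ~ 0.11
LIABILITY_TRUTH = VarianceComponents(
    terms={"aF": [[0.45]], "peF": [[0.30]], "peM": [[0.05]]}, residual=[0.0])


def main(seed: int = 2026) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        seed=seed, n_sires=25, n_dams_per_sire=5, n_offspring_per_dam=4,
        truth=LIABILITY_TRUTH, pou_effect_sd=0.3, mode="binomial",
    )
    ped, table, truth = simulate(cfg)
    write_pedigree(ped, OUT / "pedigree.txt")
    write_phenotypes(table, OUT / "phenotypes.csv")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    n_hens = table["hen_id"].nunique()
    print(f"wrote {len(table)} weekly records for {n_hens} hens "
          f"({len(table) / n_hens:.1f} records/hen), pedigree of {ped.n}")
    print(f"mean %HoF {table['hof'].mean():.2f}, sd {table['hof'].std():.2f}")
    print(f"egg age {table['egg_age'].mean():.2f} +/- {table['egg_age'].std():.2f} d; "
          f"eggs set {table['eggs_set'].mean():.2f}/hen-week; mean incidence "
          f"{table['eggs_hatched'].sum() / table['eggs_fertile'].sum():.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2026)
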