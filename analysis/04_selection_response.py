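"""Expected annual response to selection under each model.

For each single-trait model the response uses R = i r sigma_a / L (one
record) or its repeated-records extension; the multitrait model uses
the Smith-Hazel index with equal economic weights.  A 50% selected
fraction of hens (i = 0.798) and a generation interval of L = 1 year
are assumed; both are configuration knobs, and L in particular must be
set to the breeding program's own value for absolute gains to mean
anything.  Accuracies are computed from the fits' prediction error
variances over the phenotyped hens.

Writes results/responses/model_comparison.csv: per model, the annual
genetic gain in %HoF units and as a percentage of the phenotypic mean.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hofgen.components import VarianceComponents
from hofgen.design import ModelSpec, build_design
from hofgen.io import read_pedigree, read_phenotypes
from hofgen.legendre import AgeGrid, basis_matrix
from hofgen.mme import solve_mme
from hofgen.parameters import heritability_scalar, rrm_surface
from hofgen.phenotypes import apply_editing
from hofgen.selection import (IndexInputs, SelectionInputs, accuracy_from_pev,
                              model_comparison_report, response_index,
                              response_repeated, response_single,
                              selection_intensity)

ROOT = Path(__file__).resolve().parents[1] / "results"
PROPORTION = 0.5
L_YEARS = 1.0


def load_vc(name):
    with open(ROOT / "fits" / f"{name}.json") as fh:
        return VarianceComponents.from_dict(
            json.load(fh)["variance_components"])


def main() -> None:
    out = ROOT / "responses"
    out.mkdir(parents=True, exist_ok=True)
    ped = read_pedigree(ROOT / "data" / "pedigree.txt")
    table = apply_editing(read_phenotypes(ROOT / "data" / "phenotypes.csv"))
    hens = sorted(table["hen_id"].unique(), key=str)
    hen_idx = np.array([ped.index_of(h) for h in hens])
    n_bar = float(table.groupby("hen_id").size().mean())
    mean_hof = float(table["hof"].mean())
    i_sel = selection_intensity(PROPORTION)
    grid = AgeGrid.weekly()
    responses = {}

    for kind in ("cum", "rep", "frm"):
        vc = load_vc(kind)
        h2, re = heritability_scalar(vc)
        design = build_design(table, ModelSpec(kind), ped)
        sol = solve_mme(design, vc)
        pev = sol.pev["aF"][hen_idx, 0, 0]
        r = float(np.mean(accuracy_from_pev(pev, vc.scalar("aF"))))
        si = SelectionInputs(i=i_sel, r=r, sigma_a=np.sqrt(vc.scalar("aF")),
                             L=L_YEARS, n=n_bar, re=re)
        responses[kind] = (response_single(si) if kind == "cum"
                           else response_repeated(si))
        print(f"{kind:4s}: r = {r:.3f}, R = {responses[kind]:.4f} %HoF/yr")

    vc = load_vc("rrm")
    surf = rrm_surface(vc, grid)
    design = build_design(table, ModelSpec("rrm"), ped)
    sol = solve_mme(design, vc)
    phi_bar = basis_matrix(grid, vc.K("aF").shape[0] - 1).mean(axis=0)
    pev_bar = np.einsum("a,nab,b->n", phi_bar, sol.pev["aF"][hen_idx], phi_bar)
    var_a_bar = float(phi_bar @ vc.K("aF") @ phi_bar)
    r = float(np.mean(accuracy_from_pev(pev_bar, max(var_a_bar, 1e-12))))
    perm = surf.var_a + surf.var_pef + surf.var_pem
    re_bar = float(np.mean(perm / (perm + surf.var_e)))
    si = SelectionInputs(i=i_sel, r=r, sigma_a=np.sqrt(var_a_bar),
                         L=L_YEARS, n=n_bar, re=re_bar)
    responses["rrm"] = response_repeated(si)
    print(f"rrm : r = {r:.3f}, R = {responses['rrm']:.4f} %HoF/yr")

    vc = load_vc("mtm")
    G = vc.K("aF")
    P = G + np.diag(vc.residual)
    R_index, var_I = response_index(IndexInputs(P=P, G=G, a=np.ones(3)),
                                    i=i_sel, L=L_YEARS)
    responses["mtm"] = R_index
    print(f"mtm : Var(I) = {var_I:.3f}, R = {R_index:.4f} %HoF/yr")

    report = model_comparison_report(responses, mean_hof)
    report.to_csv(out / "model_comparison.csv", index=False)
    print()
    print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\n(phenotypic mean {mean_hof:.2f}%; i = {i_sel:.4f}, "
          f"L = {L_YEARS} yr assumed)")


if __name__ == "__main__":
    main()
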