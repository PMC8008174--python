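"""Turn the fitted variance components into genetic parameters.

Reads results/fits/ and writes, under results/params/:

  - scalar_parameters.csv: heritability and repeatability for CUM, REP,
    FRM, the RRM grid average, the MTM per-period heritabilities, and
    the threshold model's liability- and observed-scale heritability;
  - rrm_surface.csv: per-age variances and heritability from the RRM;
  - rrm_corr_g.csv / rrm_corr_p.csv: age x age genetic and phenotypic
    correlation matrices;
  - mtm_correlations.csv: the 3x3 genetic correlation matrix.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hofgen.components import VarianceComponents
from hofgen.legendre import AgeGrid
from hofgen.parameters import (heritability_scalar, liability_to_observed,
                               rrm_surface)

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_vc(name):
    with open(ROOT / "fits" / f"{name}.json") as fh:
        return json.load(fh)


def main() -> None:
    out = ROOT / "params"
    out.mkdir(parents=True, exist_ok=True)
    grid = AgeGrid.weekly()
    rows = []

    for kind in ("cum", "rep", "frm"):
        vc = VarianceComponents.from_dict(load_vc(kind)["variance_components"])
        h2, re = heritability_scalar(vc)
        rows.append({"model": kind, "h2": h2, "repeatability": re})
        print(f"{kind:4s}: h2 = {h2:.3f}, re = {re:.3f}")

    vc_rrm = VarianceComponents.from_dict(load_vc("rrm")["variance_components"])
    surf = rrm_surface(vc_rrm, grid)
    surf.to_frame().to_csv(out / "rrm_surface.csv", index=False)
    ages = list(grid.ages)
    pd.DataFrame(surf.corr_g, index=ages, columns=ages).to_csv(out / "rrm_corr_g.csv")
    pd.DataFrame(surf.corr_p, index=ages, columns=ages).to_csv(out / "rrm_corr_p.csv")
    rows.append({"model": "rrm", "h2": surf.h2_average, "repeatability": np.nan})
    print(f"rrm : average h2 over ages = {surf.h2_average:.3f} "
          f"(range {surf.h2.min():.3f}-{surf.h2.max():.3f})")

    vc_mtm = VarianceComponents.from_dict(load_vc("mtm")["variance_components"])
    G = vc_mtm.K("aF")
    R = np.diag(vc_mtm.residual)
    P = G + R
    h2_traits = np.diag(G) / np.diag(P)
    sd = np.sqrt(np.diag(G))
    corr_g = G / np.outer(sd, sd)
    labels = ["early_27_37", "mid_38_47", "late_48_58"]
    pd.DataFrame(corr_g, index=labels, columns=labels).to_csv(
        out / "mtm_correlations.csv")
    for lab, h2 in zip(labels, h2_traits):
        rows.append({"model": f"mtm_{lab}", "h2": h2, "repeatability": np.nan})
    print(f"mtm : per-period h2 = {np.round(h2_traits, 3)}, "
          f"rg(early,mid) = {corr_g[0, 1]:.2f}")

    th = load_vc("threshold")
    h2_obs = liability_to_observed(th["h2_liability"], th["mean_incidence"])
    rows.append({"model": "threshold_liability", "h2": th["h2_liability"],
                 "repeatability": np.nan})
    rows.append({"model": "threshold_observed", "h2": h2_obs,
                 "repeatability": np.nan})
    print(f"threshold: liability h2 {th['h2_liability']:.3f} -> "
          f"observed-scale {h2_obs:.3f} at incidence {th['mean_incidence']:.3f}")

    pd.DataFrame(rows).to_csv(out / "scalar_parameters.csv", index=False)


if __name__ == "__main__":
    main()
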