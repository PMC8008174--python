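"""File formats, run configuration and the end-to-end pipeline.

Pedigrees are 3-column delimited text (animal sire dam; 0/blank/NA =
unknown parent; '#' comments; optional header auto-detected).
Phenotypes are CSV with a header; %HoF is always recomputed from the
hatched and fertile counts, never trusted from a file.  Results are
written as JSON carrying the variance components (K matrices
row-major), log-likelihoods, convergence flags, and the seed and config
hash of the run so reruns are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ModelSpec, build_design
from .legendre import AgeGrid
from .parameters import heritability_scalar, liability_to_observed, rrm_surface
from .pedigree import Pedigree, reorder_pedigree
from .phenotypes import REQUIRED_COLUMNS, apply_editing, compute_hof, validate_table
from .reml import reml_fit
from .selection import (SelectionInputs, IndexInputs, accuracy_from_pev,
                        model_comparison_report, response_index,
                        response_repeated, response_single,
                        selection_intensity)
from .threshold import fit_threshold_repeatability

__all__ = ["read_pedigree", "write_pedigree", "read_phenotypes",
           "write_phenotypes", "write_results_text", "RunConfig",
           "run_pipeline"]

_HEADER_WORDS = {"animal", "id", "sire", "dam", "animal_id", "sire_id", "dam_id"}


def read_pedigree(path) -> Pedigree:
    """Read and topologically order a 3-column pedigree file."""
    triples = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s;]+", line)
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns (animal sire dam), got {len(parts)}"
                )
            if lineno == 1 and any(p.lower() in _HEADER_WORDS for p in parts):
                continue
            triples.append(tuple(parts))
    return reorder_pedigree(triples)


def write_pedigree(ped: Pedigree, path):
    with open(path, "w") as fh:
        fh.write("animal sire dam\n")
        for a, s, d in ped.records():
            fh.write(f"{a} {s if s is not None else 0} {d if d is not None else 0}\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV; HoF is computed, never read."""
    t = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = t.index[t["eggs_hatched"] > t["eggs_fertile"]]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0]}: eggs_hatched > eggs_fertile")
    t = t.drop(columns=[c for c in t.columns if c == "hof"])
    t["hof"] = compute_hof(t["eggs_hatched"], t["eggs_fertile"])
    return validate_table(t)


def write_phenotypes(table: pd.DataFrame, path):
    cols = [c for c in table.columns if c != "hof"]
    table[cols].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full edit -> fit -> parameters -> response run."""

    pedigree_path: str
    phenotype_path: str
    out_dir: str
    models: tuple = ("cum", "rep", "frm", "rrm", "mtm")
    fit_threshold: bool = False
    min_records: int = 5
    year_window: tuple | None = None
    age_min: int = 27
    age_max: int = 58
    proportion_selected: float = 0.5
    generation_interval: float = 1.0
    economic_weights: tuple = (1.0, 1.0, 1.0)
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["models"] = list(self.models)
        d["economic_weights"] = list(self.economic_weights)
        if self.year_window is not None:
            d["year_window"] = list(self.year_window)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_results_text(results: dict, path):
    """Flat ``key = value`` rendering of a (nested) results mapping."""
    def walk(prefix, obj, lines):
        if isinstance(obj, dict):
            for k in sorted(obj, key=str):
                walk(f"{prefix}.{k}" if prefix else str(k), obj[k], lines)
        elif isinstance(obj, (list, tuple, np.ndarray)):
            vals = " ".join(str(v) for v in np.asarray(obj).ravel())
            lines.append(f"{prefix} = {vals}")
        else:
            lines.append(f"{prefix} = {obj}")
    lines: list = []
    walk("", results, lines)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(cfg: RunConfig) -> dict:
    """Edit the data, fit the requested models, derive parameters and
    selection responses, and write all artifacts under ``cfg.out_dir``.

    Returns the results bundle that was written to ``results.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_sha256": cfg.digest(),
             "config": cfg.to_dict()}

    def stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

    ped = stage("read_pedigree", lambda: read_pedigree(cfg.pedigree_path))
    table = stage("read_phenotypes", lambda: read_phenotypes(cfg.phenotype_path))
    edited = stage("edit", lambda: apply_editing(
        table, min_records=cfg.min_records, year_window=cfg.year_window))

    results: dict = {"stamp": stamp, "n_records": len(edited),
                     "n_hens": int(edited["hen_id"].nunique()), "models": {}}
    mean_hof = float(edited["hof"].mean())
    grid = AgeGrid.weekly(cfg.age_min, cfg.age_max)
    i_sel = selection_intensity(cfg.proportion_selected)
    responses = {}

    for kind in cfg.models:
        spec = ModelSpec(kind, age_min=cfg.age_min, age_max=cfg.age_max)
        design = stage(f"design[{kind}]", lambda s=spec: build_design(edited, s, ped))
        fit = stage(f"fit[{kind}]", lambda d=design: reml_fit(
            d, max_iter=cfg.max_iter, tol=cfg.tol))
        entry = fit.report()
        vc = fit.vc
        # selection candidates: phenotyped hens
        hens = sorted(edited["hen_id"].unique(), key=str)
        hen_idx = np.array([ped.index_of(h) for h in hens])
        n_bar = float(edited.groupby("hen_id").size().mean())

        if kind == "mtm":
            G = vc.K("aF")
            R = np.diag(vc.residual)
            P = G + R
            a = np.asarray(cfg.economic_weights, dtype=float)[: G.shape[0]]
            R_year, var_I = response_index(IndexInputs(P=P, G=G, a=a),
                                           i=i_sel, L=cfg.generation_interval)
            entry["h2_traits"] = (np.diag(G) / np.diag(P)).tolist()
            entry["index_variance"] = var_I
            responses["mtm"] = R_year
        elif kind == "rrm":
            surf = rrm_surface(vc, grid)
            surf.to_frame().to_csv(out / "rrm_surface.csv", index=False)
            pd.DataFrame(surf.corr_g, index=grid.ages, columns=grid.ages
                         ).to_csv(out / "rrm_corr_g.csv")
            pd.DataFrame(surf.corr_p, index=grid.ages, columns=grid.ages
                         ).to_csv(out / "rrm_corr_p.csv")
            entry["h2_average"] = surf.h2_average
            # accuracy and response via the age-average genetic value
            pev = fit.solve.pev["aF"][hen_idx]
            var_a_mean = float(np.mean(surf.var_a))
            from .legendre import basis_matrix as _bm
            phi_bar = _bm(grid, vc.K("aF").shape[0] - 1).mean(axis=0)
            pev_bar = np.einsum("a,nab,b->n", phi_bar, pev, phi_bar)
            r = float(np.mean(accuracy_from_pev(pev_bar, max(var_a_mean, 1e-12))))
            _, re_bar = _average_repeatability(surf)
            si = SelectionInputs(i=i_sel, r=r, sigma_a=np.sqrt(var_a_mean),
                                 L=cfg.generation_interval, n=n_bar, re=re_bar)
            responses["rrm"] = response_repeated(si)
            entry["accuracy"] = r
        else:
            h2, re = heritability_scalar(vc)
            entry["h2"] = h2
            entry["repeatability"] = re
            sigma_a = np.sqrt(vc.scalar("aF"))
            pev = fit.solve.pev["aF"][hen_idx, 0, 0]
            r = float(np.mean(accuracy_from_pev(pev, vc.scalar("aF"))))
            entry["accuracy"] = r
            si = SelectionInputs(i=i_sel, r=r, sigma_a=sigma_a,
                                 L=cfg.generation_interval, n=n_bar, re=re)
            responses[kind] = (response_single(si) if kind == "cum"
                               else response_repeated(si))
        results["models"][kind] = entry

    if cfg.fit_threshold:
        th = stage("fit[threshold]", lambda: fit_threshold_repeatability(edited, ped))
        results["models"]["threshold"] = {
            "variance_components": th.vc.to_dict(),
            "h2_liability": th.h2_liability,
            "h2_observed": liability_to_observed(th.h2_liability, th.mean_incidence),
            "converged": th.converged,
        }

    report = model_comparison_report(responses, mean_hof)
    report.to_csv(out / "model_comparison.csv", index=False)
    results["responses"] = {m: {"gain_per_year": float(r),
                                "pct_of_mean": float(100.0 * r / mean_hof)}
                            for m, r in responses.items()}
    results["phenotypic_mean"] = mean_hof
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
    write_results_text(results, out / "results.txt")
    return results


def _average_repeatability(surf) -> tuple:
    var_perm = surf.var_a + surf.var_pef + surf.var_pem
    var_p = var_perm + surf.var_e
    re_t = np.where(var_p > 0, var_perm / np.where(var_p > 0, var_p, 1.0), np.nan)
    return re_t, float(np.nanmean(re_t))
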