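"""Pedigrees and the numerator relationship matrix A.

Every animal model in this package assumes additive genetic effects
distributed N(0, A * sigma2_a) where A is the numerator relationship
matrix: twice the kinship matrix expected from the pedigree, with an
unrelated, non-inbred founder population as the base.  This module
represents pedigrees in topological order (parents before offspring),
builds A by Henderson's tabular method, computes inbreeding
coefficients, and builds the sparse inverse of A directly from pedigree
structure (Henderson/Quaas rules, with inbreeding accounted for
exactly), which is what the mixed-model equations actually consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "CycleError",
    "reorder_pedigree",
    "build_A",
    "inbreeding",
    "mendelian_variances",
    "build_A_inverse",
]

#: ids treated as "parent unknown" (founder)
UNKNOWN_IDS = {None, 0, "0", "", ".", "NA"}


class PedigreeError(ValueError):
    """Malformed pedigree (duplicate ids, unknown structure)."""


class CycleError(PedigreeError):
    """An animal is its own ancestor."""


def _is_unknown(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    if isinstance(x, str):
        return x.strip() in {"0", "", ".", "NA"}
    return x in UNKNOWN_IDS


@dataclass(frozen=True)
class Pedigree:
    """A topologically ordered pedigree.

    Attributes
    ----------
    animals:
        Animal ids in topological order (every known parent precedes
        its offspring).
    sire, dam:
        Integer positions of each animal's parents in ``animals``;
        ``-1`` encodes an unknown (founder) parent.
    """

    animals: tuple
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.animals)})

    @property
    def n(self) -> int:
        return len(self.animals)

    def index_of(self, animal) -> int:
        return self._index[animal]

    def __contains__(self, animal) -> bool:
        return animal in self._index

    def records(self):
        """Yield (animal, sire, dam) triples with None for unknown parents."""
        for i, a in enumerate(self.animals):
            s = self.animals[self.sire[i]] if self.sire[i] >= 0 else None
            d = self.animals[self.dam[i]] if self.dam[i] >= 0 else None
            yield (a, s, d)


def reorder_pedigree(records: Iterable[Sequence]) -> Pedigree:
    """Topologically sort (animal, sire, dam) triples into a Pedigree.

    Parents listed after their offspring, or appearing only as parents,
    are handled; a parent never listed as an animal is added as a
    founder.  Unknown parents are encoded as 0, "0", "", "NA", None or
    NaN.

    Raises
    ------
    PedigreeError
        On duplicate animal ids.
    CycleError
        If an animal is its own ancestor; the message names one animal
        on the cycle.
    """
    triples = []
    seen = set()
    for rec in records:
        a, s, d = rec[0], rec[1], rec[2]
        if _is_unknown(a):
            raise PedigreeError("animal id may not be the unknown code")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
        triples.append((a, None if _is_unknown(s) else s, None if _is_unknown(d) else d))

    # implicit founders: parents never listed as animals
    for _, s, d in list(triples):
        for p in (s, d):
            if p is not None and p not in seen:
                seen.add(p)
                triples.append((p, None, None))

    parents = {a: (s, d) for a, s, d in triples}

    # Kahn's algorithm on the parent -> offspring DAG
    n_parents = {a: sum(p is not None for p in ps) for a, ps in parents.items()}
    children: dict = {a: [] for a in parents}
    for a, (s, d) in parents.items():
        for p in {s, d} - {None}:
            children[p].append(a)

    order = [a for a, k in n_parents.items() if k == 0]
    head = 0
    placed = set(order)
    remaining = dict(n_parents)
    while head < len(order):
        a = order[head]
        head += 1
        for c in children[a]:
            # a parent appearing as both sire and dam decrements twice
            k = sum(p == a for p in parents[c] if p is not None)
            remaining[c] -= k
            if remaining[c] == 0 and c not in placed:
                placed.add(c)
                order.append(c)
    if len(order) < len(parents):
        on_cycle = sorted(set(parents) - placed, key=str)
        raise CycleError(
            f"pedigree contains a cycle: animal {on_cycle[0]!r} is its own ancestor"
        )

    index = {a: i for i, a in enumerate(order)}
    sire = np.array([index[parents[a][0]] if parents[a][0] is not None else -1 for a in order])
    dam = np.array([index[parents[a][1]] if parents[a][1] is not None else -1 for a in order])
    return Pedigree(tuple(order), sire, dam)


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by Henderson's tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))
    for j < i, with unknown parents contributing 0 (unrelated,
    non-inbred base).  Dense; intended for pedigrees up to a few
    thousand animals (the mixed-model equations use the sparse inverse
    instead).
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        asd = A[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        if i == 0:
            continue
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * A[:i, s[i]]
        if d[i] >= 0:
            row += 0.5 * A[:i, d[i]]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F = diag(A) - 1.

    Computed by the Meuwissen & Luo (1992) algorithm, which avoids
    storing A and therefore scales to large pedigrees.
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    for i in range(n):
        if s[i] < 0 or d[i] < 0:
            continue
        # youngest-first sweep accumulating each ancestor's path
        # contribution to a_ii; a_ii = sum_j contrib_j^2 * d_j
        aii = 0.0
        contrib = np.zeros(i + 1)
        contrib[i] = 1.0
        for j in range(i, -1, -1):
            cj = contrib[j]
            if cj == 0.0:
                continue
            sj, dj = s[j], d[j]
            # d_j: Mendelian sampling variance of j
            if sj >= 0 and dj >= 0:
                dj_var = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0 or dj >= 0:
                p = sj if sj >= 0 else dj
                dj_var = 0.75 - 0.25 * F[p]
            else:
                dj_var = 1.0
            aii += cj * cj * dj_var
            if sj >= 0:
                contrib[sj] += 0.5 * cj
            if dj >= 0:
                contrib[dj] += 0.5 * cj
        # aii here is a_ii of animal i computed from path contributions;
        # F_i = 0.5 * a(sire, dam) = a_ii - 1
        F[i] = aii - 1.0
    return F


def mendelian_variances(ped: Pedigree) -> np.ndarray:
    """Mendelian sampling variances d_i (diagonal of D in A = T D T').

    log|A| = sum(log d_i), used in the REML likelihood.
    """
    F = inbreeding(ped)
    s, d = ped.sire, ped.dam
    out = np.ones(ped.n)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    Fs = np.where(s >= 0, F[np.clip(s, 0, None)], 0.0)
    Fd = np.where(d >= 0, F[np.clip(d, 0, None)], 0.0)
    out[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    out[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    return out


def build_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A from pedigree structure.

    Uses the Henderson (1976) / Quaas rules with exact inbreeding:
    with alpha_i = 1/d_i, add alpha_i to (i,i), -alpha_i/2 to (i,p),
    and alpha_i/4 to (p,q) for each pair of known parents p, q.
    """
    n = ped.n
    d = mendelian_variances(ped)
    rows, cols, vals = [], [], []
    s, dd = ped.sire, ped.dam
    for i in range(n):
        alpha = 1.0 / d[i]
        rows.append(i); cols.append(i); vals.append(alpha)
        ps = [p for p in (s[i], dd[i]) if p >= 0]
        for p in ps:
            rows += [i, p]; cols += [p, i]; vals += [-alpha / 2.0, -alpha / 2.0]
        for p in ps:
            for q in ps:
                rows.append(p); cols.append(q); vals.append(alpha / 4.0)
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
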