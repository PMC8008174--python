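"""Independent brute-force oracles used by the test suite.

Each oracle implements the quantity under test by a different route
than the package (recursive definitions, Monte Carlo, dense linear
algebra) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np


def kinship(i, j, parents, order):
    """Recursive kinship coefficient f(i, j) from a parent map.

    ``parents[x] = (sire, dam)`` with None for unknown; ``order[x]``
    gives the pedigree position (parents before offspring).  The
    recursion always expands the animal that appears later, which is
    never an ancestor of the other.  The numerator relationship is
    a_ij = 2 f(i, j) for i != j and a_ii = 1 + f(s, d).
    """
    if i is None or j is None:
        return 0.0
    if i == j:
        s, d = parents[i]
        return 0.5 * (1.0 + kinship(s, d, parents, order))
    if order[i] < order[j]:
        i, j = j, i
    s, d = parents[i]
    return 0.5 * (kinship(s, j, parents, order) + kinship(d, j, parents, order))


def relationship_matrix_bruteforce(records):
    """A matrix from the recursive-kinship definition (ordered records)."""
    parents = {a: (s, d) for a, s, d in records}
    animals = [a for a, _, _ in records]
    order = {a: k for k, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    for i, x in enumerate(animals):
        for j, y in enumerate(animals):
            if i == j:
                s, d = parents[x]
                A[i, j] = 1.0 + kinship(s, d, parents, order)
            else:
                A[i, j] = 2.0 * kinship(x, y, parents, order)
    return A


def random_pedigree(rng, n, p_known=0.7):
    """Random acyclic pedigree of n animals (ids 1..n, ordered)."""
    records = []
    for i in range(1, n + 1):
        pool = list(range(1, i))
        s = d = None
        if pool and rng.random() < p_known:
            s = int(rng.choice(pool))
        if pool and rng.random() < p_known:
            d = int(rng.choice(pool))
            if d == s:
                d = None
        records.append((i, s, d))
    return records


def gene_drop_kinship(records, pair, n_rep, rng):
    """Monte-Carlo kinship of a pair by gene dropping.

    Founders get unique allele labels; each offspring inherits one
    allele per parent uniformly.  The kinship estimate is the
    probability that one random allele from each of the two animals is
    identical by descent.
    """
    animals = [a for a, _, _ in records]
    idx = {a: k for k, a in enumerate(animals)}
    hits = 0
    for _ in range(n_rep):
        alleles = {}
        counter = 0
        for a, s, d in records:
            pair_alleles = []
            for p in (s, d):
                if p is None:
                    pair_alleles.append(counter)
                    counter += 1
                else:
                    pair_alleles.append(alleles[p][rng.integers(2)])
            alleles[a] = pair_alleles
        x = alleles[pair[0]][rng.integers(2)]
        y = alleles[pair[1]][rng.integers(2)]
        hits += x == y
    return hits / n_rep


def anova_one_way(y, groups):
    """Balanced one-way ANOVA variance components (sigma2_u, sigma2_e).

    Method-of-moments: sigma2_e = MSW, sigma2_u = (MSB - MSW) / n0 with
    n0 the common group size.  Matches REML for balanced data with a
    grand-mean fixed effect when estimates are interior.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    sizes = np.array([np.sum(groups == g) for g in labels])
    assert len(set(sizes)) == 1, "oracle requires balanced data"
    n0 = sizes[0]
    means = np.array([y[groups == g].mean() for g in labels])
    msb = n0 * np.sum((means - y.mean()) ** 2) / (k - 1)
    msw = sum(np.sum((y[groups == g] - y[groups == g].mean()) ** 2)
              for g in labels) / (len(y) - k)
    return (msb - msw) / n0, msw
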