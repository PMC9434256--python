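"""Independent oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: brute-force graph search, gene-dropping Monte
Carlo, direct textbook formulas.
"""

from __future__ import annotations

import numpy as np

from pedbench import Pedigree


def random_pedigree(n_founders: int, n_extra: int,
                    rng: np.random.Generator) -> Pedigree:
    """Random acyclic pedigree: each non-founder draws two distinct earlier
    individuals as parents (or one/none unknown with small probability)."""
    ids = list(range(1, n_founders + n_extra + 1))
    sires: list = [None] * n_founders
    dams: list = [None] * n_founders
    for i in range(n_founders, n_founders + n_extra):
        a, b = rng.choice(i, size=2, replace=False)
        sires.append(ids[a] if rng.random() > 0.05 else None)
        dams.append(ids[b] if rng.random() > 0.05 else None)
    return Pedigree(ids=ids, sires=sires, dams=dams)


def path_distance_oracle(ped: Pedigree) -> np.ndarray:
    """All-pairs shortest path by Floyd–Warshall on the dense undirected
    parent-child graph (O(n^3); brute force, independent of scipy BFS)."""
    n = len(ped)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i, (s, d) in enumerate(zip(ped.sires, ped.dams)):
        for p in (s, d):
            if p is not None:
                j = ped.index_of(p)
                D[i, j] = D[j, i] = 1.0
    for k in range(n):
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    return D


def gene_dropping_relationship(ped: Pedigree, n_drops: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo estimate of 2x kinship by dropping unique founder alleles.

    Every founder gets two globally unique allele labels; each offspring
    inherits one uniformly chosen allele from each parent (unknown parents
    contribute fresh unique alleles).  The kinship phi_ij is the
    probability that one random allele from i and one from j are identical
    by descent; the numerator relationship is 2*phi_ij.  Vectorized over
    replicate drops.
    """
    n = len(ped)
    s, d = ped.parent_indices()
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    next_allele = 0
    for i in ped.topological_order:
        for slot, p in enumerate((s[i], d[i])):
            if p < 0:
                alleles[i, slot, :] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[i, slot, :] = alleles[p, pick, np.arange(n_drops)]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            share = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    share += alleles[i, a] == alleles[j, b]
            phi = share.mean() / 4.0
            A[i, j] = A[j, i] = 2.0 * phi
    # diagonal: 2*phi_ii = 1 + F_i, with phi_ii = (2 + 2*P(ibd across slots))/4
    return A


def wc_theta_oracle(counts_per_pop: list[np.ndarray]) -> float:
    """Weir–Cockerham theta via per-locus scalar arithmetic (direct formula).

    ``counts_per_pop[k]`` is an (L, 3) array of genotype counts
    (hom-ref, het, hom-alt) for subpopulation k.
    """
    r = len(counts_per_pop)
    L = counts_per_pop[0].shape[0]
    num = den = 0.0
    for l in range(L):
        n_i, p_i, h_i = [], [], []
        for k in range(r):
            c0, c1, c2 = counts_per_pop[k][l]
            n = c0 + c1 + c2
            n_i.append(n)
            p_i.append((c1 + 2 * c2) / (2 * n))
            h_i.append(c1 / n)
        n_i = np.array(n_i, dtype=float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = nbar / nc * (s2 - 1.0 / (nbar - 1)
                         * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r by the direct covariance / sigma-sigma formula."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
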