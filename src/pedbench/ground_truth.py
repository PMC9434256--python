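"""Ancestral ground-truth distances derived from a pedigree.

Two notions of "true" ancestral distance between individuals are computed
from pedigree records alone, independent of any genotype data:

* **pedigree path distance** — the number of parent-child edges on the
  shortest path between two individuals in the undirected pedigree graph.
  Parent and offspring are 1 apart, full siblings 2, grandparent and
  grandchild 2, and so on.  Pairs in disconnected components have no
  defined distance.
* **inverse expected IBD** — the reciprocal of the numerator relationship
  matrix (A-matrix) entry, where A is built by the Henderson tabular
  recursion.  A_ij is twice the kinship coefficient, i.e. the expected
  fraction of alleles shared identical by descent; unrelated pairs
  (A_ij = 0) have undefined inverse distance and are masked.

Both are returned as condensed pairwise vectors with an explicit
defined/undefined mask so that downstream correlations only ever use
pairs for which the pedigree actually determines a value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform

__all__ = [
    "Pedigree",
    "GroundTruthDistances",
    "PedigreeError",
    "pedigree_path_distance",
    "a_matrix",
    "ibd_distance",
    "reference_mds",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids...)."""


@dataclass
class Pedigree:
    """Parent records for a set of individuals.

    Parameters
    ----------
    ids
        Unique individual labels (any hashable; the simulator uses ints).
    sires, dams
        Parent labels aligned with ``ids``; ``None`` marks an unknown parent.
    generation, subpopulation
        Optional per-individual annotations.
    """

    ids: list
    sires: list
    dams: list
    generation: np.ndarray | None = None
    subpopulation: np.ndarray | None = None

    _index: dict = field(init=False, repr=False)
    _topo: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.sires) == len(self.dams) == n):
            raise PedigreeError("ids, sires and dams must have equal length")
        self._index = {x: i for i, x in enumerate(self.ids)}
        if len(self._index) != n:
            seen, dup = set(), None
            for x in self.ids:
                if x in seen:
                    dup = x
                    break
                seen.add(x)
            raise PedigreeError(f"duplicate individual id: {dup!r}")
        self._topo = self._topological_order()

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, individual) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"unknown individual id: {individual!r}") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam as integer positions; -1 where unknown."""
        n = len(self)
        s = np.full(n, -1, dtype=np.int64)
        d = np.full(n, -1, dtype=np.int64)
        for i, (si, di) in enumerate(zip(self.sires, self.dams)):
            if si is not None:
                s[i] = self._index[si]
            if di is not None:
                d[i] = self._index[di]
        return s, d

    def _topological_order(self) -> np.ndarray:
        """Order in which parents precede offspring; raises on cycles."""
        n = len(self)
        # resolve parents, complaining about references to absent individuals
        for col, name in ((self.sires, "sire"), (self.dams, "dam")):
            for i, p in enumerate(col):
                if p is not None and p not in self._index:
                    raise PedigreeError(
                        f"{name} {p!r} of individual {self.ids[i]!r} "
                        "is not in the pedigree"
                    )
        s, d = self.parent_indices()
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (s[i], d[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != n:
            bad = self.ids[int(np.flatnonzero(indeg > 0)[0])]
            raise PedigreeError(
                f"pedigree contains a cycle (individual {bad!r} is its own ancestor)"
            )
        return np.asarray(order, dtype=np.int64)

    @property
    def topological_order(self) -> np.ndarray:
        return self._topo


@dataclass
class GroundTruthDistances:
    """Condensed pairwise ancestral distances with a defined-pair mask.

    ``values`` and ``defined_mask`` are condensed vectors of length
    n*(n-1)/2 in :func:`scipy.spatial.distance.squareform` order over
    ``ids``.  Entries where ``defined_mask`` is False carry no meaning and
    must be excluded from any correlation.
    """

    ids: list
    values: np.ndarray
    defined_mask: np.ndarray
    metric: str

    def __post_init__(self):
        n = len(self.ids)
        m = n * (n - 1) // 2
        if self.values.shape != (m,) or self.defined_mask.shape != (m,):
            raise ValueError("condensed vector length does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def as_matrix(self, fill=np.nan) -> np.ndarray:
        """Square matrix with undefined pairs set to ``fill`` and 0 diagonal."""
        vals = np.where(self.defined_mask, self.values, np.nan)
        m = squareform(vals, checks=False)
        if not np.isnan(fill):
            m = np.where(np.isnan(m), fill, m)
        np.fill_diagonal(m, 0.0)
        return m


def pedigree_path_distance(ped: Pedigree, ids: Sequence | None = None) -> GroundTruthDistances:
    """Shortest-path distance in the undirected pedigree graph.

    Edges are parent-child links, traversable in both directions, so
    collateral relatives (siblings, cousins) receive finite distances
    through their shared ancestors.  Pairs in disconnected components are
    flagged undefined.
    """
    if ids is None:
        ids = list(ped.ids)
    idx = np.asarray([ped.index_of(x) for x in ids], dtype=np.int64)
    n = len(ped)
    s, d = ped.parent_indices()
    child = np.arange(n)
    rows, cols = [], []
    for p in (s, d):
        known = p >= 0
        rows.append(child[known])
        cols.append(p[known])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    graph = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    dist = shortest_path(graph, method="D", directed=False, unweighted=True,
                         indices=idx)
    sub = dist[:, idx]
    condensed = squareform(sub, checks=False)
    mask = np.isfinite(condensed)
    condensed = np.where(mask, condensed, np.nan)
    return GroundTruthDistances(list(ids), condensed, mask, "pedigree_path")


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the Henderson tabular recursion.

    Processing individuals parents-first: a founder has a_ii = 1; otherwise
    a_ii = 1 + 0.5 * a(sire, dam) and a_ij = 0.5 * (a(j, sire) + a(j, dam))
    for previously processed j, with unknown parents contributing 0.  The
    result is symmetric PSD with diagonal in [1, 2]; a_ij is twice the
    kinship (expected IBD fraction) between i and j.

    Rows/columns follow the order of ``ped.ids``.
    """
    n = len(ped)
    s, d = ped.parent_indices()
    A = np.zeros((n, n), dtype=np.float64)
    for i in ped.topological_order:
        si, di = s[i], d[i]
        row = np.zeros(n, dtype=np.float64)
        if si >= 0:
            row += A[si]
        if di >= 0:
            row += A[di]
        row *= 0.5
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return A


def ibd_distance(A: np.ndarray, ids: Sequence,
                 subset: Sequence | None = None) -> GroundTruthDistances:
    """Inverse-relationship distance d_ij = 1 / a_ij.

    Pairs with a_ij = 0 (no pedigree relationship) are masked undefined
    rather than mapped to an arbitrary large constant.  ``subset`` selects
    the individuals to evaluate (default: all of ``ids``).
    """
    ids = list(ids)
    if A.shape != (len(ids), len(ids)):
        raise ValueError("A shape does not match ids")
    if subset is None:
        subset = ids
    lookup = {x: i for i, x in enumerate(ids)}
    idx = np.asarray([lookup[x] for x in subset], dtype=np.int64)
    sub = A[np.ix_(idx, idx)]
    a = squareform(sub - np.diag(np.diag(sub)), checks=False)
    mask = a > 0
    with np.errstate(divide="ignore"):
        vals = np.where(mask, 1.0 / np.where(mask, a, 1.0), np.nan)
    return GroundTruthDistances(list(subset), vals, mask, "ibd_inverse")


def reference_mds(truth: GroundTruthDistances, seed: int = 0):
    """Stress-minimizing 2-D MDS of a fully defined ground-truth matrix.

    This is the visual reference configuration: what an embedding would
    look like if pairwise distances reflected ancestry exactly.  It is not
    one of the scored candidate methods.
    """
    from sklearn.manifold import MDS

    from .embeddings import EmbeddingResult

    if not truth.defined_mask.all():
        raise ValueError(
            "ground truth has undefined pairs; restrict to a connected "
            "subset of individuals before embedding"
        )
    D = truth.as_matrix(fill=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_components=2, dissimilarity="precomputed",
                  random_state=seed, normalized_stress=False)
        coords = mds.fit_transform(D)
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=np.float64),
        ids=list(truth.ids),
        method="reference_mds",
        hyperparams={"dissimilarity": "precomputed", "metric": truth.metric},
        seed=seed,
    )
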