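"""Binding-motif comparison: pairwise distances between per-allele 9x20
score matrices, UPGMA clustering, and Newick tree output.

The distance is d = (1 - r) / 2 with r the Pearson correlation of the
flattened matrices, mapping perfectly similar motifs to 0 and perfectly
anti-correlated motifs to 1 — the red(0)/white(1) scale used when
visualising motif-similarity heat maps. Correlation distance does not
guarantee the triangle inequality; the trees are descriptive clusterings,
not metric embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .model import PSSM

__all__ = [
    "MotifDistanceMatrix",
    "motif_distance",
    "distance_matrix",
    "build_tree",
    "top_bipartition",
]


@dataclass
class MotifDistanceMatrix:
    """Symmetric allele-by-allele motif distances in [0, 1], zero diagonal."""

    alleles: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.alleles)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.distances = np.clip(d, 0.0, 1.0)


def motif_distance(a: PSSM, b: PSSM) -> float:
    """(1 - Pearson r)/2 over the flattened 9x20 matrices; 0 = identical
    preference pattern, 1 = exactly opposite. A constant matrix has no
    defined correlation and raises."""
    x = a.scores.ravel()
    y = b.scores.ravel()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(
            f"correlation undefined: zero-variance PSSM ({a.allele} or {b.allele})"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return (1.0 - r) / 2.0


def distance_matrix(pssms: list[PSSM]) -> MotifDistanceMatrix:
    """All pairwise motif distances, rows/columns in input allele order."""
    n = len(pssms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = motif_distance(pssms[i], pssms[j])
    return MotifDistanceMatrix(alleles=[p.allele for p in pssms], distances=d)


def _upgma(m: MotifDistanceMatrix) -> tuple[list[str], np.ndarray]:
    """Average-linkage (UPGMA) clustering with deterministic tie-breaking:
    alleles are sorted lexicographically first, so equal-distance merges
    resolve to the lexicographically smallest pair."""
    if len(m.alleles) < 2:
        raise ValueError("need at least 2 alleles to build a tree")
    order = sorted(range(len(m.alleles)), key=lambda i: m.alleles[i])
    alleles = [m.alleles[i] for i in order]
    d = m.distances[np.ix_(order, order)]
    return alleles, linkage(squareform(d, checks=False), method="average")


def _quote_label(name: str) -> str:
    """Quote a leaf label when it contains Newick-reserved characters
    (HLA names like B*38:02 contain ':')."""
    if any(ch in name for ch in "():;,'[] \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def build_tree(m: MotifDistanceMatrix, method: str = "upgma") -> str:
    """Rooted ultrametric tree over the alleles, as Newick text.

    Branch lengths place every leaf at the same depth (half the merge
    distance at each internal node, as UPGMA defines)."""
    if method != "upgma":
        raise ValueError(f"unsupported method {method!r}")
    alleles, z = _upgma(m)
    n = len(alleles)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: _quote_label(alleles[i]) for i in range(n)}
    for step, (left, right, dist, _) in enumerate(z):
        node = n + step
        h = dist / 2.0
        heights[node] = h
        li, ri = int(left), int(right)
        newick[node] = (
            f"({newick[li]}:{h - heights[li]:.6g},{newick[ri]}:{h - heights[ri]:.6g})"
        )
    return newick[2 * n - 2] + ";"


def top_bipartition(m: MotifDistanceMatrix) -> tuple[frozenset[str], frozenset[str]]:
    """The two allele sets separated by the root of the UPGMA tree."""
    alleles, z = _upgma(m)
    n = len(alleles)
    members: dict[int, frozenset[str]] = {i: frozenset([alleles[i]]) for i in range(n)}
    for step, (left, right, _, _) in enumerate(z):
        members[n + step] = members[int(left)] | members[int(right)]
    left, right = int(z[-1][0]), int(z[-1][1])
    return members[left], members[right]
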