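"""Spanning-tree backbone of a connectivity matrix and its global topology.

The backbone keeps the strongest couplings: a maximum spanning tree over
the raw coupling values (equivalently, a minimum spanning tree over
inverted weights).  Ties are broken deterministically by lexicographic
edge order.  A full 64-channel matrix yields 64 nodes and 63 edges.

Six normalized global measures characterize the tree (n nodes, M = n - 1
edges, distances in edge counts):

* ``kmax``            max node degree / M
* ``leaf_fraction``   leaf count L / n (leaves have degree 1)
* ``diameter``        max pairwise distance / M
* ``bc_max``          max betweenness centrality, normalized by (n-1)(n-2)/2
* ``ecc_mean``        mean over nodes of the eccentricity / M
* ``tree_hierarchy``  L / (2 * M * bc_max)

For a tree, the maximum possible leaf count (n - 1, the star) equals the
edge count, so the two published readings of the hierarchy denominator
coincide for every tree size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["SpanningTree", "MSTMetrics", "build_mst", "mst_metrics",
           "MSTError", "METRIC_NAMES"]

METRIC_NAMES = ("kmax", "leaf_fraction", "diameter", "bc_max", "ecc_mean",
                "tree_hierarchy")


class MSTError(ValueError):
    pass


@dataclass
class SpanningTree:
    nodes: list[str]
    edges: list[tuple[int, int, float]]

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class MSTMetrics:
    kmax: float
    leaf_fraction: float
    diameter: float
    bc_max: float
    ecc_mean: float
    tree_hierarchy: float

    def as_dict(self) -> dict[str, float]:
        return {"kmax": self.kmax, "leaf_fraction": self.leaf_fraction,
                "diameter": self.diameter, "bc_max": self.bc_max,
                "ecc_mean": self.ecc_mean,
                "tree_hierarchy": self.tree_hierarchy}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(values: np.ndarray, labels: list[str] | None = None,
              ) -> SpanningTree:
    """Maximum spanning tree over coupling values (Kruskal).

    Accepts a full symmetric finite matrix (or a ConnectivityMatrix via its
    ``.values``/``.channel_labels``).  Equal weights resolve to the
    lexicographically first spanning tree.
    """
    if hasattr(values, "values") and hasattr(values, "channel_labels"):
        labels = list(values.channel_labels)
        values = values.values
    w = np.asarray(values, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MSTError("matrix must be square")
    if not np.all(np.isfinite(w)):
        raise MSTError("matrix must be finite")
    if not np.allclose(w, w.T, atol=1e-10):
        raise MSTError("matrix must be symmetric")
    n = w.shape[0]
    if n < 2:
        raise MSTError("need at least 2 nodes")
    if labels is None:
        labels = [str(i) for i in range(n)]

    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(iu.size), key=lambda k: (-w[iu[k], ju[k]], iu[k], ju[k]))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[i, j])))
            if len(edges) == n - 1:
                break
    return SpanningTree(nodes=list(labels), edges=edges)


def mst_metrics(tree: SpanningTree) -> MSTMetrics:
    """The six normalized global topology measures of a spanning tree."""
    n = tree.n
    if n < 3:
        raise MSTError("betweenness undefined for trees with fewer than 3 nodes")
    if len(tree.edges) != n - 1:
        raise MSTError(f"not a spanning tree: {len(tree.edges)} edges, "
                       f"expected {n - 1}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in tree.edges)
    if not nx.is_tree(g):
        raise MSTError("edge list does not form a tree")

    m = n - 1
    degrees = np.array([d for _, d in g.degree()])
    leaves = int((degrees == 1).sum())
    ecc = nx.eccentricity(g)
    ecc_values = np.array([ecc[v] for v in range(n)], dtype=float)
    bc = nx.betweenness_centrality(g, normalized=True)
    bc_max = max(bc.values())

    return MSTMetrics(
        kmax=degrees.max() / m,
        leaf_fraction=leaves / n,
        diameter=ecc_values.max() / m,
        bc_max=bc_max,
        ecc_mean=ecc_values.mean() / m,
        tree_hierarchy=leaves / (2 * m * bc_max),
    )
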