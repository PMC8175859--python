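"""Classical per-node features of a weighted network.

Four graph-theory features are computed on the positive-weight skeleton:

* degree centrality ``C_D(v) = d(v) / (n - 1)`` with ``d`` the number of
  distinct neighbors (weights are not summed);
* betweenness centrality ``c_B(v)`` — the sum over unordered node pairs of
  the fraction of geodesics passing through ``v``;
* closeness centrality ``C_c(v) = (n - 1) / sum_j d(v_j, v)``, with
  reachable-set (Wasserman–Faust) scaling on disconnected graphs;
* ``N_MC(v)`` — the number of maximal cliques containing ``v``.

By default shortest paths use unit edge lengths on the binarized skeleton;
``weighted=True`` uses length ``1/w`` so heavier edges are shorter.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from gfsnet.graph_io import WeightedGraph

__all__ = [
    "FeatureVector",
    "to_networkx",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "maximal_clique_counts",
]

#: canonical feature order used throughout the package
FEATURE_NAMES = ("C_D", "c_B", "C_c", "N_MC", "S_2hop")


@dataclass(frozen=True)
class FeatureVector:
    """A named per-node score vector aligned to a graph's label order."""

    name: str
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        if v.ndim != 1 or len(v) != len(self.labels):
            raise ValueError(
                f"feature '{self.name}': {len(v)} values for {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"feature '{self.name}' contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def to_networkx(g: WeightedGraph, weighted: bool = False) -> nx.Graph:
    """Positive-weight skeleton as a networkx graph over node indices.

    With ``weighted=True`` each edge also carries ``length = 1/w`` for
    shortest-path computations (heavier fiber bundles = closer regions).
    """
    n = g.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(g.W, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = float(g.W[i, j])
        if weighted:
            G.add_edge(i, j, weight=w, length=1.0 / w)
        else:
            G.add_edge(i, j, weight=w)
    return G


def _require_n2(g: WeightedGraph) -> None:
    if g.n_nodes < 2:
        raise ValueError("feature requires a graph with at least 2 nodes")


def degree_centrality(g: WeightedGraph) -> FeatureVector:
    """Fraction of other nodes adjacent to each node, d(v)/(n-1).

    The degree counts distinct positive-weight neighbors; edge magnitudes do
    not matter, so an edge of weight 100 contributes exactly like weight 1.
    """
    _require_n2(g)
    d = (g.W > 0).sum(axis=1).astype(float)
    return FeatureVector("C_D", g.labels, d / (g.n_nodes - 1))


def betweenness_centrality(g: WeightedGraph, weighted: bool = False) -> FeatureVector:
    """Per-node sum over unordered pairs of the geodesic fraction through it.

    Pairs in different components contribute nothing; endpoints are never
    counted as intermediates.
    """
    _require_n2(g)
    G = to_networkx(g, weighted=weighted)
    cb = nx.betweenness_centrality(
        G, normalized=False, weight="length" if weighted else None
    )
    return FeatureVector("c_B", g.labels, np.array([cb[i] for i in range(g.n_nodes)]))


def closeness_centrality(g: WeightedGraph, weighted: bool = False) -> FeatureVector:
    """Normalized reciprocal farness, (n-1)/sum of geodesic distances.

    On disconnected graphs each node's closeness within its reachable set of
    r nodes, (r-1)/sum, is scaled by (r-1)/(n-1); this reduces to the plain
    definition on connected graphs and gives isolated nodes 0.
    """
    _require_n2(g)
    G = to_networkx(g, weighted=weighted)
    cc = nx.closeness_centrality(
        G, distance="length" if weighted else None, wf_improved=True
    )
    return FeatureVector("C_c", g.labels, np.array([cc[i] for i in range(g.n_nodes)]))


def maximal_clique_counts(g: WeightedGraph, max_cliques: int = 2_000_000) -> FeatureVector:
    """Number of maximal cliques each node belongs to (Bron–Kerbosch with pivoting).

    An isolated node forms its own singleton maximal clique and scores 1.
    ``max_cliques`` caps the enumeration (clique counts can grow
    exponentially); exceeding it raises ``RuntimeError``.
    """
    G = to_networkx(g)
    counts = np.zeros(g.n_nodes)
    for k, clique in enumerate(nx.find_cliques(G)):
        if k >= max_cliques:
            raise RuntimeError(
                f"maximal clique enumeration exceeded the cap of {max_cliques}"
            )
        counts[list(clique)] += 1
    return FeatureVector("N_MC", g.labels, counts)
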