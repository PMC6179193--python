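"""Cluster-quality metrics, always evaluated on the original graph.

The headline statistic is the average normalized cut between clusters:

    Ncut(A, B) = edge(A, B) / edge(A)  +  edge(A, B) / edge(B)

where ``edge(A, B)`` counts edges with one endpoint in each cluster and
``edge(X)``, by default, counts edges with at least one endpoint in X
(incident-edge convention; every pairwise term is then at most 1).  An
alternative internal-only reading of ``edge(X)`` is available behind the
``mode`` switch.  The average runs over unordered cluster pairs that share
at least one crossing edge — pairs with no contact carry no information
about separation quality and would wash the statistic out as the number of
clusters grows.

Also provided: Newman modularity of the (partial) partition, with
unassigned nodes treated as singleton communities so degree mass is
conserved, plus cluster-count / size-histogram / remaining-node summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .errors import ParameterError, UndefinedMetricError
from .graph_io import Clustering, Graph

__all__ = [
    "MetricsReport",
    "normalized_cut",
    "average_ncut",
    "modularity",
    "summarize",
]

_NCUT_MODES = ("incident", "internal")


@dataclass
class MetricsReport:
    avg_ncut: float | None
    modularity: float | None
    n_clusters: int
    remaining_ratio: float
    size_histogram: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "avg_ncut": self.avg_ncut,
            "modularity": self.modularity,
            "n_clusters": self.n_clusters,
            "remaining_ratio": self.remaining_ratio,
            "size_histogram": {str(k): v for k, v in sorted(self.size_histogram.items())},
        }


def _crossing_edges(g: Graph, a: set[int], b: set[int]) -> int:
    return sum(1 for u, v in g.edges if (u in a and v in b) or (u in b and v in a))


def _edge_mass(g: Graph, x: set[int], mode: str) -> int:
    if mode == "incident":
        return sum(1 for u, v in g.edges if u in x or v in x)
    return sum(1 for u, v in g.edges if u in x and v in x)


def normalized_cut(
    g: Graph, a: Iterable[int], b: Iterable[int], *, mode: str = "incident"
) -> float:
    """Pairwise normalized cut between two disjoint node sets.

    Symmetric in its arguments; exactly 0 when no edge crosses between the
    sets (including the degenerate case where neither set touches any
    edge).  A crossing edge is incident to both sets, so whenever the
    numerator is positive both denominators are too.
    """
    if mode not in _NCUT_MODES:
        raise ParameterError(f"mode must be one of {_NCUT_MODES}, got {mode!r}")
    a, b = set(a), set(b)
    if not a or not b:
        raise ParameterError("both node sets must be non-empty")
    if a & b:
        raise ParameterError("node sets must be disjoint")
    cross = _crossing_edges(g, a, b)
    if cross == 0:
        return 0.0
    ea = _edge_mass(g, a, mode)
    eb = _edge_mass(g, b, mode)
    # mode="internal" can have a positive cut with zero internal edges;
    # treat an empty side as contributing nothing rather than dividing by 0
    term_a = cross / ea if ea else 0.0
    term_b = cross / eb if eb else 0.0
    return term_a + term_b


def average_ncut(g: Graph, clustering: Clustering, *, mode: str = "incident") -> float:
    """Mean normalized cut over cluster pairs joined by at least one edge.

    0.0 when every pair of clusters is disconnected.  Unassigned nodes take
    no part.  Raises for a clustering with no clusters at all.
    """
    if clustering.n_clusters == 0:
        raise UndefinedMetricError("average N-cut is undefined with zero clusters")
    values = []
    for ca, cb in combinations(sorted(clustering.clusters), 2):
        a, b = clustering.clusters[ca], clustering.clusters[cb]
        if _crossing_edges(g, a, b) == 0:
            continue
        values.append(normalized_cut(g, a, b, mode=mode))
    if not values:
        return 0.0
    return sum(values) / len(values)


def modularity(g: Graph, clustering: Clustering) -> float:
    """Newman modularity Q = sum_c [ L_c/|E| - (D_c / 2|E|)^2 ].

    L_c is the number of edges internal to community c and D_c the total
    degree of its members.  Unassigned nodes enter as singleton communities
    (zero internal edges, their degree still counted), so the trivial
    all-in-one clustering scores exactly 0.
    """
    n_edges = g.number_of_edges
    if n_edges == 0:
        raise UndefinedMetricError("modularity is undefined on an empty graph")
    communities = [members for _, members in sorted(clustering.clusters.items())]
    communities.extend({v} for v in sorted(clustering.unassigned))
    q = 0.0
    for members in communities:
        internal = sum(1 for u, v in g.edges if u in members and v in members)
        total_degree = sum(g.degree(v) for v in members if g.has_node(v))
        q += internal / n_edges - (total_degree / (2 * n_edges)) ** 2
    return q


def summarize(
    clustering: Clustering, g: Graph, *, mode: str = "incident"
) -> MetricsReport:
    """Full quality report for a clustering of ``g``.

    ``avg_ncut`` and ``modularity`` are ``None`` when undefined (no
    clusters / empty graph).
    """
    n_nodes = g.number_of_nodes
    sizes: dict[int, int] = {}
    for members in clustering.clusters.values():
        sizes[len(members)] = sizes.get(len(members), 0) + 1
    try:
        avg = average_ncut(g, clustering, mode=mode)
    except UndefinedMetricError:
        avg = None
    try:
        q = modularity(g, clustering)
    except UndefinedMetricError:
        q = None
    return MetricsReport(
        avg_ncut=avg,
        modularity=q,
        n_clusters=clustering.n_clusters,
        remaining_ratio=(len(clustering.unassigned) / n_nodes) if n_nodes else 0.0,
        size_histogram=sizes,
    )
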