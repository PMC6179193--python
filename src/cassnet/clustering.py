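"""From a weighted network to clusters.

The pipeline mirrors the SCAN family of structural clustering methods:

1. **prune** — drop every edge whose structure similarity falls below the
   user threshold epsilon (edges exactly at epsilon are kept);
2. **label** — a node is a *core* if it still has at least ``m`` neighbors
   in the pruned graph, otherwise *non-core*;
3. **refine** — keep an edge iff at least one endpoint is core (edges
   between two non-core nodes are removed; a core keeps all its neighbors);
4. **extract** — every connected component of the refined graph with at
   least two nodes is a cluster, identified by its minimum member node id;
   isolated nodes are reported as unassigned.

Component extraction is an iterative minimum-label propagation: every node
starts labelled with its own id and repeatedly adopts the smallest label in
its closed neighborhood until a full pass changes nothing.  Labels only
decrease and are bounded below, so a fixed point is guaranteed, and at the
fixed point each node carries the minimum id of its component — which is by
construction the cluster identifier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError, ParameterError
from .graph_io import Clustering, DirectedEdgeList, Graph, WeightedEdgeTable
from .similarity import PipelineStats, compute_all_similarities

__all__ = [
    "Params",
    "CoreLabeling",
    "prune_by_epsilon",
    "label_cores",
    "refine_edges",
    "connected_components",
    "cass_cluster",
]


@dataclass(frozen=True)
class Params:
    """Clustering parameters.

    epsilon: similarity threshold in (0, 1] below which edges are pruned.
    m: minimum number of surviving neighbors for a node to be a core
       (integer >= 2).
    """

    epsilon: float = 0.7
    m: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon <= 1.0:
            raise ParameterError(
                f"epsilon must lie in (0, 1], got {self.epsilon}"
            )
        if int(self.m) != self.m or self.m < 2:
            raise ParameterError(f"m must be an integer >= 2, got {self.m}")


@dataclass
class CoreLabeling:
    """Core / non-core flag for every node of the pruned graph."""

    cores: set[int]
    nodes: set[int]

    def is_core(self, v: int) -> bool:
        return v in self.cores


def prune_by_epsilon(
    table: WeightedEdgeTable, g: Graph, epsilon: float
) -> Graph:
    """Subgraph of ``g`` keeping exactly the edges with similarity >= epsilon.

    The node set is unchanged.  Every edge of ``g`` must be present in the
    table; a missing edge raises :class:`~cassnet.errors.ConsistencyError`.
    """
    if not 0.0 < epsilon <= 1.0:
        raise ParameterError(f"epsilon must lie in (0, 1], got {epsilon}")
    kept = []
    for edge in g.edges:
        s = table.get(edge)
        if s is None:
            raise ConsistencyError(f"edge {edge} missing from similarity table")
        if s >= epsilon:
            kept.append(edge)
    return Graph(g.nodes, kept)


def label_cores(
    pruned: Graph, m: int, *, strict: bool = False, count_self: bool = False
) -> CoreLabeling:
    """Label each node core iff its pruned-graph neighbor count meets ``m``.

    The default comparison is ``degree >= m``; ``strict=True`` switches to
    ``degree > m`` for the literal "more than m" reading.  ``count_self=True``
    counts the node itself (closed-neighborhood size, degree + 1), matching
    SCAN's epsilon-neighborhood convention, which shifts the effective
    threshold by one.
    """
    if int(m) != m or m < 2:
        raise ParameterError(f"m must be an integer >= 2, got {m}")
    cores: set[int] = set()
    for v in pruned.nodes:
        n_adjacent = pruned.degree(v) + (1 if count_self else 0)
        if (n_adjacent > m) if strict else (n_adjacent >= m):
            cores.add(v)
    return CoreLabeling(cores, pruned.nodes)


def refine_edges(pruned: Graph, labels: CoreLabeling) -> Graph:
    """Drop exactly the edges between two non-core nodes.

    A core node keeps all its neighbors, core or not; a non-core node keeps
    only its core neighbors.  Afterwards only core–core and core–non-core
    edges remain, so no path can connect two clusters through non-cores.
    """
    if not pruned.nodes <= labels.nodes:
        raise ConsistencyError("labeling does not cover the pruned graph")
    kept = [
        (u, v)
        for u, v in pruned.edges
        if labels.is_core(u) or labels.is_core(v)
    ]
    return Graph(pruned.nodes, kept)


def connected_components(refined: Graph) -> Clustering:
    """Clusters = non-singleton components, labelled by their minimum node id.

    Implemented as minimum-label propagation over the edge list until a full
    pass changes no label; labels only decrease, so termination is
    guaranteed and the fixed-point label of a node is the minimum id
    reachable from it.  Isolated nodes become unassigned.
    """
    labels = {v: v for v in refined.nodes}
    edge_order = sorted(refined.edges)
    changed = True
    while changed:
        changed = False
        for u, v in edge_order:
            lo = labels[u] if labels[u] < labels[v] else labels[v]
            if labels[u] != lo:
                labels[u] = lo
                changed = True
            if labels[v] != lo:
                labels[v] = lo
                changed = True
    components: dict[int, set[int]] = {}
    for v, lab in labels.items():
        components.setdefault(lab, set()).add(v)
    return Clustering.from_components(components.values(), refined.nodes)


def cass_cluster(
    g: Graph,
    edges: DirectedEdgeList | None = None,
    params: Params = Params(),
    *,
    similarity_table: WeightedEdgeTable | None = None,
    use_bloom: bool = True,
    use_shuffle_selection: bool = True,
    fp_rate: float = 0.3,
    partitions: int = 1,
    direction: str | None = None,
    strict_core: bool = False,
    count_self: bool = False,
    bloom_seed: int = 0,
) -> tuple[Clustering, WeightedEdgeTable, PipelineStats | None]:
    """End-to-end pipeline: similarity → prune → label → refine → components.

    A precomputed ``similarity_table`` (e.g. loaded from a cache written by
    a previous run) skips the similarity stage entirely; the resulting
    clustering is identical to one computed from scratch.  Returns the
    clustering, the similarity table (for caching), and the dataflow stats
    (``None`` when the similarity stage was skipped).
    """
    if similarity_table is not None:
        table, stats = similarity_table, None
    else:
        table, stats = compute_all_similarities(
            g,
            edges,
            use_bloom=use_bloom,
            use_shuffle_selection=use_shuffle_selection,
            fp_rate=fp_rate,
            partitions=partitions,
            direction=direction,
            bloom_seed=bloom_seed,
        )
    pruned = prune_by_epsilon(table, g, params.epsilon)
    labeling = label_cores(pruned, params.m, strict=strict_core, count_self=count_self)
    refined = refine_edges(pruned, labeling)
    clustering = connected_components(refined)
    return clustering, table, stats
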