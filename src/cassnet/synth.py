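"""Synthetic networks and canned toy fixtures.

Two generators cover the experimental designs the package is exercised on:

* Erdős–Rényi G(n, p) graphs parameterised by a *target mean degree*
  (p = degree / (n - 1)) — the scaling-study workload;
* planted-partition graphs (equal-size blocks, independent within/between
  edge probabilities p_in > p_out) with ground-truth labels, for scoring
  cluster recovery with the adjusted Rand index.

Both are pure functions of their parameters and a mandatory seed, drawn
row-by-row from ``numpy.random.default_rng`` so the same call always yields
the same graph without materialising the full pair matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .graph_io import DirectedEdgeList, Graph

__all__ = [
    "PlantedTruth",
    "erdos_renyi_graph",
    "planted_partition_graph",
    "ToyFixture",
    "toy_fixtures",
]


@dataclass
class PlantedTruth:
    """Ground-truth block structure of a planted-partition graph."""

    block_of: dict[int, int]
    k: int
    p_in: float
    p_out: float

    def labels(self) -> list[int]:
        return [self.block_of[v] for v in sorted(self.block_of)]


def erdos_renyi_graph(n_nodes: int, mean_degree: float, seed: int) -> Graph:
    """G(n, p) with p chosen so the expected mean degree hits the target."""
    if n_nodes < 1:
        raise ParameterError("need at least one node")
    if not 0 <= mean_degree < n_nodes:
        raise ParameterError(
            f"mean degree must lie in [0, n_nodes), got {mean_degree}"
        )
    p = mean_degree / (n_nodes - 1) if n_nodes > 1 else 0.0
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = []
    for u in range(n_nodes - 1):
        draws = rng.random(n_nodes - u - 1)
        for offset in np.nonzero(draws < p)[0]:
            edges.append((u, u + 1 + int(offset)))
    return Graph(range(n_nodes), edges)


def planted_partition_graph(
    k: int, n_per: int, p_in: float, p_out: float, seed: int
) -> tuple[Graph, PlantedTruth]:
    """Equal-block planted partition with independent edge draws.

    Requires ``p_in > p_out`` (otherwise there is no structure to plant).
    Nodes 0..n_per-1 form block 0, the next n_per block 1, and so on.
    """
    if k < 1 or n_per < 1:
        raise ParameterError("need at least one block and one node per block")
    if not (0.0 <= p_out <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ParameterError("probabilities must lie in [0, 1]")
    if p_in <= p_out:
        raise ParameterError(
            f"p_in must exceed p_out, got p_in={p_in}, p_out={p_out}"
        )
    n = k * n_per
    block = np.arange(n) // n_per
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = []
    for u in range(n - 1):
        others = np.arange(u + 1, n)
        p_vec = np.where(block[others] == block[u], p_in, p_out)
        draws = rng.random(n - u - 1)
        for offset in np.nonzero(draws < p_vec)[0]:
            edges.append((u, u + 1 + int(offset)))
    truth = PlantedTruth({v: int(block[v]) for v in range(n)}, k, p_in, p_out)
    return Graph(range(n), edges), truth


@dataclass
class ToyFixture:
    """A small named graph with hand-checked expectations."""

    graph: Graph
    edges: DirectedEdgeList
    description: str
    #: canonical edge -> exact similarity, where hand-derived
    expected_similarities: dict[tuple[int, int], float] | None = None
    #: cluster id -> members under the documented default parameters
    expected_clusters: dict[int, set[int]] | None = None


def _fixture(graph: Graph, description: str, **kw) -> ToyFixture:
    return ToyFixture(graph, DirectedEdgeList.from_graph(graph), description, **kw)


def toy_fixtures() -> dict[str, ToyFixture]:
    """Small graphs used across the test suites and the documentation.

    The ``two_k4_bridge`` fixture (two 4-cliques joined by a single bridge
    edge) is the worked example: the bridge edge has similarity 2/5, the
    clique edges at the bridge endpoints 4/sqrt(20), all other clique edges
    exactly 1, so at epsilon 0.6 and m = 2 the pipeline returns the two
    cliques as clusters 0 and 4 with nothing unassigned.
    """
    import math

    k3 = Graph(range(3), [(0, 1), (0, 2), (1, 2)])
    k4 = Graph(range(4), [(u, v) for u in range(4) for v in range(u + 1, 4)])
    path3 = Graph(range(3), [(0, 1), (1, 2)])
    path4 = Graph(range(4), [(0, 1), (1, 2), (2, 3)])
    cycle4 = Graph(range(4), [(0, 1), (1, 2), (2, 3), (0, 3)])
    star10 = Graph(range(11), [(0, leaf) for leaf in range(1, 11)])

    k4_edges_a = [(u, v) for u in range(4) for v in range(u + 1, 4)]
    k4_edges_b = [(u + 4, v + 4) for u, v in k4_edges_a]
    two_k4 = Graph(range(8), k4_edges_a + k4_edges_b + [(3, 4)])
    sim_bridge_end = 4 / math.sqrt(20)
    two_k4_sims: dict[tuple[int, int], float] = {}
    for u, v in two_k4.edges:
        if (u, v) == (3, 4):
            two_k4_sims[(u, v)] = 0.4
        elif 3 in (u, v) or 4 in (u, v):
            two_k4_sims[(u, v)] = sim_bridge_end
        else:
            two_k4_sims[(u, v)] = 1.0

    # two separate communities plus one isolated node, in the style of a
    # refined graph whose components are read off as clusters 0 and 5
    two_comp = Graph(
        range(9),
        [(0, 1), (0, 2), (1, 3), (2, 3), (5, 6), (6, 7), (5, 7), (7, 8)],
    )

    star_sim = {
        (0, leaf): 2 / math.sqrt((10 + 1) * 2) for leaf in range(1, 11)
    }

    return {
        "k3": _fixture(
            k3,
            "triangle: identical closed neighborhoods, all similarities 1",
            expected_similarities={e: 1.0 for e in k3.edges},
            expected_clusters={0: {0, 1, 2}},
        ),
        "k4": _fixture(
            k4,
            "4-clique: every edge closes two triangles, all similarities 1",
            expected_similarities={e: 1.0 for e in k4.edges},
            expected_clusters={0: {0, 1, 2, 3}},
        ),
        "path_3": _fixture(
            path3,
            "2-edge path: no triangles, both similarities 2/sqrt(6)",
            expected_similarities={e: 2 / math.sqrt(6) for e in path3.edges},
        ),
        "path_4": _fixture(path4, "3-edge path: no triangles"),
        "cycle_4": _fixture(
            cycle4,
            "4-cycle: no triangles, every similarity 2/3",
            expected_similarities={e: 2 / 3 for e in cycle4.edges},
        ),
        "star_10": _fixture(
            star10,
            "star with 10 leaves: zero triangles, empty second join",
            expected_similarities=star_sim,
        ),
        "two_k4_bridge": _fixture(
            two_k4,
            "two 4-cliques joined by bridge (3,4); the worked example",
            expected_similarities=two_k4_sims,
            expected_clusters={0: {0, 1, 2, 3}, 4: {4, 5, 6, 7}},
        ),
        "two_components": _fixture(
            two_comp,
            "two components plus isolated node 4; min-id labels 0 and 5",
            expected_clusters={0: {0, 1, 2, 3}, 5: {5, 6, 7, 8}},
        ),
    }
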