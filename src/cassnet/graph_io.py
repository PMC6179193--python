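"""Graph containers and on-disk formats.

The package works on undirected simple graphs given as plain-text edge lists
(SNAP dialect: two whitespace-separated node ids per line, ``#`` comments).
Node identifiers are non-negative integers; inputs with symbolic ids (gene
names) can be relabelled to a dense integer space so that minimum-id cluster
labels are well defined, and mapped back on output.

Three tabular formats are written and read here:

* edge lists (``u v`` per line),
* similarity caches (``u  v  similarity`` TSV, canonical ``u < v``), which
  let a network be re-clustered under new parameters without recomputing
  edge weights,
* cluster tables (``node  cluster`` TSV, ``-`` for unassigned nodes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from .errors import ParseError, ValidationError

__all__ = [
    "Graph",
    "DirectedEdgeList",
    "WeightedEdgeTable",
    "Clustering",
    "ReadReport",
    "EdgeListData",
    "read_edge_list",
    "write_edge_list",
    "write_similarity_cache",
    "read_similarity_cache",
    "write_clusters",
    "read_clusters",
]


def canonical_edge(u: int, v: int) -> tuple[int, int]:
    """Return the unordered edge ``{u, v}`` as an ordered ``(min, max)`` pair."""
    return (u, v) if u < v else (v, u)


class Graph:
    """Undirected simple graph over integer node ids.

    Maintains the invariants: no self-loops, no duplicate edges, every edge
    endpoint present in the node set, and ``sum(degrees) == 2 * |edges|``
    (the last holds by construction of the adjacency structure).
    """

    __slots__ = ("_adj", "_edges")

    def __init__(
        self,
        nodes: Iterable[int] = (),
        edges: Iterable[tuple[int, int]] = (),
    ) -> None:
        self._adj: dict[int, set[int]] = {int(v): set() for v in nodes}
        self._edges: set[tuple[int, int]] = set()
        for u, v in edges:
            self.add_edge(u, v)

    def add_node(self, v: int) -> None:
        self._adj.setdefault(int(v), set())

    def add_edge(self, u: int, v: int) -> None:
        u, v = int(u), int(v)
        if u == v:
            raise ValidationError(f"self-loop on node {u} is not allowed")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)
        self._edges.add(canonical_edge(u, v))

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set[int]:
        return set(self._adj)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self._edges)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        """The canonical edge set without copying overhead for callers that
        only need membership tests."""
        return frozenset(self._edges)

    def has_node(self, v: int) -> bool:
        return v in self._adj

    def has_edge(self, u: int, v: int) -> bool:
        return canonical_edge(u, v) in self._edges

    def neighbors(self, v: int) -> set[int]:
        return set(self._adj[v])

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def adjacency(self) -> Mapping[int, set[int]]:
        """Read-only view of the internal adjacency dict (do not mutate)."""
        return self._adj

    @property
    def number_of_nodes(self) -> int:
        return len(self._adj)

    @property
    def number_of_edges(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(|V|={self.number_of_nodes}, |E|={self.number_of_edges})"

    def subgraph_with_edges(self, edges: Iterable[tuple[int, int]]) -> "Graph":
        """Same node set, restricted edge set (used by epsilon pruning)."""
        return Graph(self.nodes, edges)


@dataclass
class DirectedEdgeList:
    """Edges exactly as oriented in the source file, first occurrence only.

    The raw orientation is what the shuffle-direction heuristic inspects;
    the clustering pipeline itself is orientation-free.
    """

    records: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.records)

    def reversed(self) -> "DirectedEdgeList":
        return DirectedEdgeList([(v, u) for u, v in self.records])

    @classmethod
    def from_graph(cls, g: Graph) -> "DirectedEdgeList":
        """Canonical (min, max) orientation, sorted — for graphs built in
        memory rather than read from a file."""
        return cls(sorted(g.edges))


class WeightedEdgeTable:
    """Per-edge structure similarity in [0, 1], keyed by canonical edge."""

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[tuple[int, int], float] | None = None) -> None:
        self._entries: dict[tuple[int, int], float] = {}
        if entries:
            for (u, v), s in entries.items():
                self[(u, v)] = s

    def __setitem__(self, edge: tuple[int, int], similarity: float) -> None:
        s = float(similarity)
        if not 0.0 <= s <= 1.0:
            raise ValidationError(
                f"similarity {s!r} for edge {edge} outside [0, 1]"
            )
        self._entries[canonical_edge(*edge)] = s

    def __getitem__(self, edge: tuple[int, int]) -> float:
        return self._entries[canonical_edge(*edge)]

    def get(self, edge: tuple[int, int], default: float | None = None):
        return self._entries.get(canonical_edge(*edge), default)

    def __contains__(self, edge: tuple[int, int]) -> bool:
        return canonical_edge(*edge) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedEdgeTable):
            return NotImplemented
        return self._entries == other._entries

    def edges(self) -> set[tuple[int, int]]:
        return set(self._entries)

    def sorted_items(self) -> list[tuple[tuple[int, int], float]]:
        return sorted(self._entries.items())


@dataclass
class Clustering:
    """A partial partition of the node set.

    Cluster ids equal the minimum member node id; every cluster has at least
    two members; nodes in no cluster are listed as unassigned.
    """

    assignment: dict[int, int]
    clusters: dict[int, set[int]]
    unassigned: set[int]

    @classmethod
    def from_components(
        cls, components: Iterable[set[int]], all_nodes: Iterable[int]
    ) -> "Clustering":
        clusters: dict[int, set[int]] = {}
        assignment: dict[int, int] = {}
        for comp in components:
            if len(comp) < 2:
                continue
            cid = min(comp)
            clusters[cid] = set(comp)
            for v in comp:
                assignment[v] = cid
        unassigned = {v for v in all_nodes if v not in assignment}
        return cls(assignment, clusters, unassigned)

    def validate(self) -> None:
        seen: set[int] = set()
        for cid, members in self.clusters.items():
            if len(members) < 2:
                raise ValidationError(f"cluster {cid} has fewer than 2 members")
            if cid != min(members):
                raise ValidationError(
                    f"cluster id {cid} is not the minimum member id"
                )
            if seen & members:
                raise ValidationError("clusters are not pairwise disjoint")
            seen |= members
            for v in members:
                if self.assignment.get(v) != cid:
                    raise ValidationError(
                        f"assignment of node {v} disagrees with cluster {cid}"
                    )
        if set(self.assignment) != seen:
            raise ValidationError("assignment and clusters are inconsistent")
        if seen & self.unassigned:
            raise ValidationError("a node is both assigned and unassigned")

    @property
    def all_nodes(self) -> set[int]:
        return set(self.assignment) | self.unassigned

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, nodes: Iterable[int] | None = None) -> list[int]:
        """Integer label per node (sorted order); each unassigned node gets a
        unique negative label so it forms its own singleton for scoring."""
        order = sorted(self.all_nodes if nodes is None else nodes)
        return [self.assignment.get(v, -1 - v) for v in order]


@dataclass
class ReadReport:
    """What happened while parsing an edge list."""

    n_edges: int = 0
    n_comment_lines: int = 0
    n_self_loops_dropped: int = 0
    n_duplicates_merged: int = 0


@dataclass
class EdgeListData:
    """Bundled result of :func:`read_edge_list`."""

    graph: Graph
    edges: DirectedEdgeList
    report: ReadReport
    #: original label -> integer id, only when relabelling was requested
    label_map: dict[str, int] | None = None


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, PathLike)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_edge_list(source: str | PathLike | IO[str], *, relabel: bool = False) -> EdgeListData:
    """Parse a SNAP-style edge list into a canonical :class:`Graph` plus the
    raw-orientation :class:`DirectedEdgeList`.

    Lines starting with ``#`` and blank lines are skipped.  Self-loops are
    dropped and duplicate edges (either orientation) merged, with counts in
    the returned :class:`ReadReport`.  With ``relabel=True`` arbitrary string
    tokens are accepted and mapped, in order of first appearance, to dense
    integer ids (the mapping is returned); otherwise non-integer tokens raise
    :class:`~cassnet.errors.ParseError`.
    """
    stream, owned = _open_text(source)
    graph = Graph()
    records: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    report = ReadReport()
    label_map: dict[str, int] = {}

    def node_id(token: str, lineno: int) -> int:
        if relabel:
            if token not in label_map:
                label_map[token] = len(label_map)
            return label_map[token]
        try:
            value = int(token)
        except ValueError:
            raise ParseError(
                f"line {lineno}: node id {token!r} is not an integer"
            ) from None
        if value < 0:
            raise ParseError(f"line {lineno}: negative node id {value}")
        return value

    try:
        for lineno, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                report.n_comment_lines += 1
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"line {lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            u = node_id(tokens[0], lineno)
            v = node_id(tokens[1], lineno)
            if u == v:
                report.n_self_loops_dropped += 1
                graph.add_node(u)
                continue
            key = canonical_edge(u, v)
            if key in seen:
                report.n_duplicates_merged += 1
                continue
            seen.add(key)
            records.append((u, v))
            graph.add_edge(u, v)
    finally:
        if owned:
            stream.close()

    report.n_edges = len(records)
    return EdgeListData(
        graph,
        DirectedEdgeList(records),
        report,
        label_map if relabel else None,
    )


def write_edge_list(edges: DirectedEdgeList, sink: str | PathLike | IO[str]) -> None:
    """Write one ``u v`` line per record, preserving orientation and order."""
    stream, owned = _open_text(sink, "w")
    try:
        for u, v in edges:
            stream.write(f"{u} {v}\n")
    finally:
        if owned:
            stream.close()


_CACHE_HEADER = "u\tv\tsimilarity"


def write_similarity_cache(table: WeightedEdgeTable, sink: str | PathLike | IO[str]) -> None:
    """Persist a similarity table as TSV with full float precision.

    Values are serialised with ``repr`` (shortest round-tripping decimal), so
    a read-back table compares equal bit for bit.
    """
    stream, owned = _open_text(sink, "w")
    try:
        stream.write(_CACHE_HEADER + "\n")
        for (u, v), s in table.sorted_items():
            stream.write(f"{u}\t{v}\t{s!r}\n")
    finally:
        if owned:
            stream.close()


def read_similarity_cache(source: str | PathLike | IO[str]) -> WeightedEdgeTable:
    """Read a table written by :func:`write_similarity_cache`.

    Raises :class:`~cassnet.errors.ValidationError` for similarities outside
    [0, 1] and :class:`~cassnet.errors.ParseError` for malformed rows.
    """
    stream, owned = _open_text(source)
    table = WeightedEdgeTable()
    try:
        for lineno, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if lineno == 1 and stripped == _CACHE_HEADER:
                continue
            parts = stripped.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"line {lineno}: expected 3 tab-separated columns"
                )
            try:
                u, v, s = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed cache row") from None
            table[(u, v)] = s  # range-checked by the table
    finally:
        if owned:
            stream.close()
    return table


_CLUSTER_HEADER = "node\tcluster"
_UNASSIGNED_SENTINEL = "-"


def write_clusters(
    clustering: Clustering,
    sink: str | PathLike | IO[str],
    *,
    include_unassigned: bool = True,
) -> None:
    """Write ``node<TAB>cluster`` rows sorted by node id.

    Unassigned nodes appear with the sentinel ``-`` when requested.  Output
    is byte-deterministic for equal inputs.
    """
    stream, owned = _open_text(sink, "w")
    try:
        stream.write(_CLUSTER_HEADER + "\n")
        for v in sorted(clustering.all_nodes):
            cid = clustering.assignment.get(v)
            if cid is None:
                if include_unassigned:
                    stream.write(f"{v}\t{_UNASSIGNED_SENTINEL}\n")
                continue
            stream.write(f"{v}\t{cid}\n")
    finally:
        if owned:
            stream.close()


def read_clusters(source: str | PathLike | IO[str]) -> Clustering:
    """Read a cluster table written by :func:`write_clusters`."""
    stream, owned = _open_text(source)
    assignment: dict[int, int] = {}
    unassigned: set[int] = set()
    try:
        for lineno, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if lineno == 1 and stripped == _CLUSTER_HEADER:
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 2 columns")
            node = int(parts[0])
            if parts[1] == _UNASSIGNED_SENTINEL:
                unassigned.add(node)
            else:
                assignment[node] = int(parts[1])
    finally:
        if owned:
            stream.close()
    clusters: dict[int, set[int]] = {}
    for v, cid in assignment.items():
        clusters.setdefault(cid, set()).add(v)
    clustering = Clustering(assignment, clusters, unassigned)
    clustering.validate()
    return clustering
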