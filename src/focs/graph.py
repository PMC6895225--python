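"""Multigraph and community representation, degree bookkeeping, and file I/O.

Graphs are undirected multigraphs over a fixed node universe, stored as a
symmetric adjacency of integer multiplicities.  Self-loops are rejected at
load time (the null model re-assigns stubs between distinct nodes) and
multi-edges are kept with multiplicity.  Bipartite graphs carry a side label
per node; in bipartite edge lists column 1 is always side U and column 2
always side V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ParseError, ValidationError
from .null_model import NullParams

logger = logging.getLogger(__name__)

SIDE_U = "U"
SIDE_V = "V"

__all__ = [
    "Graph",
    "Community",
    "BipartiteCommunity",
    "DegreeSummary",
    "load_edge_list",
    "write_edge_list",
    "load_communities",
    "degree_summary",
    "external_view",
]


class Graph:
    """Undirected multigraph with integer edge multiplicities.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` or ``(u, v, multiplicity)`` tuples; repeated
        pairs accumulate multiplicity.  Self-loops are dropped (counted in
        :attr:`n_self_loops_dropped`).
    nodes
        Extra nodes to include in the universe even if isolated.
    side
        Mapping node -> ``"U"``/``"V"``; presence makes the graph bipartite.
    """

    def __init__(self, edges=(), nodes=(), side=None):
        self._adj: dict[str, dict[str, int]] = {}
        self.side: dict[str, str] | None = dict(side) if side is not None else None
        self.n_self_loops_dropped = 0
        for n in nodes:
            self._adj.setdefault(str(n), {})
        for edge in edges:
            if len(edge) == 2:
                u, v, m = edge[0], edge[1], 1
            else:
                u, v, m = edge
            self._add_edge(str(u), str(v), int(m))
        if self.side is not None:
            missing = self.nodes - self.side.keys()
            if missing:
                raise ValidationError(f"bipartite graph has nodes without a side: {sorted(missing)[:5]}")
        self._deg = {u: sum(nbrs.values()) for u, nbrs in self._adj.items()}

    def _add_edge(self, u: str, v: str, mult: int) -> None:
        if mult <= 0:
            raise ValidationError(f"edge multiplicity must be positive, got {mult}")
        if u == v:
            self.n_self_loops_dropped += 1
            logger.warning("dropping self-loop on node %r", u)
            return
        if self.side is not None and self.side.get(u) == self.side.get(v):
            raise ValidationError(f"same-side edge {u!r}-{v!r} in bipartite graph")
        self._adj.setdefault(u, {})
        self._adj.setdefault(v, {})
        self._adj[u][v] = self._adj[u].get(v, 0) + mult
        self._adj[v][u] = self._adj[v].get(u, 0) + mult

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def bipartite(self) -> bool:
        return self.side is not None

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    def __contains__(self, u) -> bool:
        return u in self._adj

    def multiplicity(self, u: str, v: str) -> int:
        return self._adj.get(u, {}).get(v, 0)

    def neighbors(self, u: str) -> dict[str, int]:
        """Neighbor -> multiplicity mapping (do not mutate)."""
        return self._adj[u]

    def degree(self, u: str) -> int:
        if u not in self._deg:
            raise KeyError(f"unknown node {u!r}")
        return self._deg[u]

    @property
    def total_degree(self) -> int:
        return sum(self._deg.values())

    @property
    def total_multiplicity(self) -> int:
        """Total number of edges counted with multiplicity."""
        return self.total_degree // 2

    def side_nodes(self, side: str) -> set[str]:
        if not self.bipartite:
            raise ValidationError("graph is not bipartite")
        return {u for u in self._adj if self.side[u] == side}

    def edges(self):
        """Yield (u, v, multiplicity) with u < v lexicographically."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]

    def to_networkx(self):
        """Weighted simple :class:`networkx.Graph` (weight = multiplicity)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self._adj))
        g.add_weighted_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class Community:
    """A candidate node subset of a unipartite graph."""

    members: frozenset = field()
    id: str = "community"

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class BipartiteCommunity:
    """A candidate community of a bipartite graph: one subset per side."""

    u_members: frozenset = field()
    v_members: frozenset = field()
    id: str = "community"

    def __post_init__(self):
        object.__setattr__(self, "u_members", frozenset(self.u_members))
        object.__setattr__(self, "v_members", frozenset(self.v_members))

    @property
    def members(self) -> frozenset:
        return self.u_members | self.v_members

    @property
    def size(self) -> int:
        return len(self.u_members) + len(self.v_members)


@dataclass(frozen=True)
class DegreeSummary:
    """The four degree sums describing a community/exterior partition.

    ``cross`` is the total multiplicity of boundary edges;
    ``external_internal`` counts both endpoints of every edge internal to
    the exterior, so it is even for unipartite graphs.
    """

    d_C: int
    cross: int
    external_internal: int

    @property
    def d_Cp(self) -> int:
        return self.cross + self.external_internal


def validate_community(graph: Graph, community) -> None:
    members = community.members
    if not members:
        raise ValidationError(f"community {community.id!r} is empty")
    unknown = members - graph.nodes
    if unknown:
        raise ValidationError(
            f"community {community.id!r} has nodes not in the graph: {sorted(unknown)[:5]}"
        )
    if members == graph.nodes:
        raise ValidationError(f"community {community.id!r} equals the whole node universe")
    if isinstance(community, BipartiteCommunity):
        if not graph.bipartite:
            raise ValidationError("bipartite community given for a unipartite graph")
        if not community.u_members or not community.v_members:
            raise ValidationError(
                f"bipartite community {community.id!r} must be non-empty on both sides"
            )
        for u in community.u_members:
            if graph.side[u] != SIDE_U:
                raise ValidationError(f"node {u!r} is not on side U")
        for v in community.v_members:
            if graph.side[v] != SIDE_V:
                raise ValidationError(f"node {v!r} is not on side V")
    elif graph.bipartite:
        raise ValidationError("unipartite community given for a bipartite graph")


def _parse_edge_line(parts, path, lineno):
    if len(parts) not in (2, 3):
        raise ParseError(path, lineno, f"expected 2 or 3 columns, got {len(parts)}")
    u, v = parts[0], parts[1]
    mult = 1
    if len(parts) == 3:
        try:
            mult = int(parts[2])
        except ValueError:
            raise ParseError(path, lineno, f"multiplicity {parts[2]!r} is not an integer")
        if mult <= 0:
            raise ParseError(path, lineno, f"multiplicity must be positive, got {mult}")
    return u, v, mult


def load_edge_list(path, bipartite: bool = False) -> Graph:
    """Read a whitespace-delimited edge list into a :class:`Graph`.

    Lines are ``node-id node-id [multiplicity]``; ``#`` starts a comment.
    Duplicate lines accumulate multiplicity; self-loop lines are dropped with
    a warning (count available as ``graph.n_self_loops_dropped``).  With
    ``bipartite=True`` column 1 declares side U and column 2 side V; a node
    appearing on both sides is a validation error.
    """
    edges = []
    side: dict[str, str] | None = {} if bipartite else None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            u, v, mult = _parse_edge_line(line.split(), path, lineno)
            if bipartite:
                if u == v:
                    raise ValidationError(
                        f"{path}:{lineno}: node {u!r} appears on both sides"
                    )
                for node, s in ((u, SIDE_U), (v, SIDE_V)):
                    prev = side.setdefault(node, s)
                    if prev != s:
                        raise ValidationError(
                            f"{path}:{lineno}: node {node!r} appears on both sides"
                        )
            edges.append((u, v, mult))
    return Graph(edges, side=side)


def write_edge_list(graph: Graph, path) -> None:
    """Write the graph so that :func:`load_edge_list` round-trips it."""
    with open(path, "w") as fh:
        for u, v, mult in graph.edges():
            if graph.bipartite and graph.side[u] == SIDE_V:
                u, v = v, u
            fh.write(f"{u}\t{v}\t{mult}\n")


def load_communities(path, graph: Graph | None = None) -> list:
    """Read a node-membership file (columns: node-id community-id).

    A node may belong to several communities.  If ``graph`` is bipartite the
    members are split by side into :class:`BipartiteCommunity` objects.
    """
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
            node, cid = parts
            groups.setdefault(cid, []).append(node)
    communities = []
    for cid, members in groups.items():
        if graph is not None and graph.bipartite:
            unknown = set(members) - graph.nodes
            if unknown:
                raise ValidationError(
                    f"community {cid!r} has nodes not in the graph: {sorted(unknown)[:5]}"
                )
            u_side = frozenset(m for m in members if graph.side[m] == SIDE_U)
            v_side = frozenset(m for m in members if graph.side[m] == SIDE_V)
            communities.append(BipartiteCommunity(u_side, v_side, id=cid))
        else:
            communities.append(Community(frozenset(members), id=cid))
    return communities


def degree_summary(graph: Graph, community) -> DegreeSummary:
    """Degree sums for the partition (community, exterior)."""
    validate_community(graph, community)
    members = community.members
    d_C = 0
    internal = 0  # sum over members of their degree into the community
    for u in members:
        d_C += graph.degree(u)
        internal += sum(m for v, m in graph.neighbors(u).items() if v in members)
    cross = d_C - internal
    external_internal = graph.total_degree - d_C - cross
    return DegreeSummary(d_C=d_C, cross=cross, external_internal=external_internal)


def _unipartite_view(graph: Graph, members: frozenset, u: str) -> NullParams:
    """Null parameters with ``u`` treated as external to ``members``."""
    c_star = members - {u}
    if not c_star:
        raise ValidationError(f"community too small to test node {u!r} against")
    d_C = 0
    internal = 0
    for c in c_star:
        d_C += graph.degree(c)
        internal += sum(m for v, m in graph.neighbors(c).items() if v in c_star)
    successes = d_C - internal  # edges from the community into the exterior
    population = graph.total_degree - d_C
    return NullParams(draws=graph.degree(u), successes=successes,
                      failures=population - successes)


def _bipartite_view(graph: Graph, community: BipartiteCommunity, u: str) -> NullParams:
    """Null parameters for a bipartite graph, ``u`` treated as external.

    With ``u`` on side U, the stub pool is the degree mass of all external
    U-side nodes (including ``u``); successes are the stubs of the V-side
    community reaching outside the U-side community.
    """
    if graph.side[u] == SIDE_U:
        same, other = community.u_members, community.v_members
        same_side_total = sum(graph.degree(w) for w in graph.side_nodes(SIDE_U))
    else:
        same, other = community.v_members, community.u_members
        same_side_total = sum(graph.degree(w) for w in graph.side_nodes(SIDE_V))
    c_star = same - {u}
    if u in community.members and not c_star and not other:
        raise ValidationError(f"community too small to test node {u!r} against")
    d_other = 0
    into_c_star = 0
    for w in other:
        d_other += graph.degree(w)
        into_c_star += sum(m for v, m in graph.neighbors(w).items() if v in c_star)
    successes = d_other - into_c_star  # other-side community stubs leaving C*
    population = same_side_total - sum(graph.degree(c) for c in c_star)
    return NullParams(draws=graph.degree(u), successes=successes,
                      failures=population - successes)


def external_view(graph: Graph, community, u: str) -> NullParams:
    """Null parameters for testing node ``u`` against ``community``.

    If ``u`` is a member it is first moved to the exterior, i.e. the
    parameters are computed on the partition ``(C \\ {u}, C' ∪ {u})`` — the
    null explicitly models the tested node's stubs as re-assignable from the
    external pool.
    """
    validate_community(graph, community)
    if u not in graph:
        raise KeyError(f"unknown node {u!r}")
    if isinstance(community, BipartiteCommunity):
        return _bipartite_view(graph, community, u)
    return _unipartite_view(graph, community.members, u)


def community_in_degree(graph: Graph, community, u: str) -> int:
    """Observed in-degree of ``u``: edges into the community (bipartite:
    into the opposite-side subset), excluding ``u`` itself."""
    if isinstance(community, BipartiteCommunity):
        target = community.v_members if graph.side[u] == SIDE_U else community.u_members
    else:
        target = community.members
    return sum(m for v, m in graph.neighbors(u).items() if v in target and v != u)
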