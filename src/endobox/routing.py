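"""Eulerian scaffold routing over the duplexes of a DX wireframe mesh.

Each mesh edge carries two antiparallel duplexes.  Doubling every edge makes
all vertex degrees even, so a single closed scaffold strand can traverse
every duplex exactly once (an Eulerian circuit).  A spanning tree decides
which edges carry a scaffold double crossover (the non-tree edges, one per
independent cycle), and an optional run of unpaired scaffold nucleotides is
inserted at every vertex transition to absorb corner geometry.

Global scaffold coordinates are 1-based and start at the 5' end of duplex 0
of the lowest-id tree edge.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .mesh import EdgePlan, PolyhedralMesh

__all__ = [
    "RoutingError",
    "DuplexTraversal",
    "ScaffoldRouting",
    "compute_spanning_tree",
    "route_scaffold",
]


class RoutingError(ValueError):
    pass


@dataclass(frozen=True)
class DuplexTraversal:
    """One pass of the scaffold through one duplex of one edge."""

    edge_id: int
    duplex: int              # 0 or 1
    start_vertex: int
    end_vertex: int
    bp: int


def compute_spanning_tree(mesh: PolyhedralMesh) -> frozenset[int]:
    """Deterministic BFS spanning tree from vertex 0 (ascending neighbors).

    Returns the set of tree edge ids; ``|tree| = V - 1``.
    """
    adj = mesh.adjacency()
    seen = {0}
    tree: set[int] = set()
    queue = deque([0])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                tree.add(mesh.edge_id(u, v))
                queue.append(v)
    if len(seen) != mesh.n_vertices:
        raise RoutingError("mesh graph is disconnected")
    return frozenset(tree)


def _eulerian_circuit(mesh: PolyhedralMesh, bp_of: dict[int, int]) -> list[DuplexTraversal]:
    """Hierholzer circuit over the doubled edge multigraph, deterministic.

    At each vertex the next unused (edge_id, duplex) is the lowest edge id,
    duplex 0 before duplex 1.
    """
    incident: dict[int, list[tuple[int, int, int]]] = {
        v: [] for v in range(mesh.n_vertices)
    }
    for eid, (u, v) in enumerate(mesh.edges):
        for d in (0, 1):
            incident[u].append((eid, d, v))
            incident[v].append((eid, d, u))
    for lst in incident.values():
        lst.sort()

    used: set[tuple[int, int]] = set()
    ptr = {v: 0 for v in incident}
    stack: list[tuple[int, DuplexTraversal | None]] = [(0, None)]
    out: list[DuplexTraversal] = []
    while stack:
        v, _ = stack[-1]
        lst = incident[v]
        i = ptr[v]
        while i < len(lst) and (lst[i][0], lst[i][1]) in used:
            i += 1
        ptr[v] = i
        if i < len(lst):
            eid, d, w = lst[i]
            used.add((eid, d))
            stack.append(
                (w, DuplexTraversal(eid, d, v, w, bp_of[eid]))
            )
        else:
            _, tr = stack.pop()
            if tr is not None:
                out.append(tr)
    out.reverse()
    if len(out) != 2 * mesh.n_edges:
        raise RoutingError("failed to cover all duplexes (disconnected mesh?)")
    return out


@dataclass(frozen=True)
class ScaffoldRouting:
    """Closed Eulerian circuit with global 1-based scaffold coordinates.

    Position layout: for traversal i covering B bp, positions
    ``start_i + 1 .. start_i + B`` map to duplex offsets 1..B (counted along
    the scaffold's 5'->3' direction through that duplex), followed by
    ``spacer_nt`` unpaired positions for the vertex transition.
    """

    circuit: tuple[DuplexTraversal, ...]
    crossover_edges: frozenset[int]
    spacer_nt: int
    total_nt: int

    def __post_init__(self):
        starts = []
        acc = 0
        index = {}
        for i, tr in enumerate(self.circuit):
            starts.append(acc)
            index[(tr.edge_id, tr.duplex)] = i
            acc += tr.bp + self.spacer_nt
        object.__setattr__(self, "_starts", tuple(starts))
        object.__setattr__(self, "_index", index)

    # -- coordinate map ---------------------------------------------------

    @property
    def n_traversals(self) -> int:
        return len(self.circuit)

    def traversal_of(self, edge_id: int, duplex: int) -> int:
        return self._index[(edge_id, duplex)]

    def position_of(self, edge_id: int, duplex: int, offset: int) -> int:
        """Global position of duplex nucleotide ``offset`` (1..bp)."""
        i = self.traversal_of(edge_id, duplex)
        tr = self.circuit[i]
        if not 1 <= offset <= tr.bp:
            raise RoutingError(f"offset {offset} outside 1..{tr.bp}")
        return self._starts[i] + offset

    def spacer_position(self, transition_index: int, offset: int) -> int:
        if not 1 <= offset <= self.spacer_nt:
            raise RoutingError("spacer offset out of range")
        tr = self.circuit[transition_index]
        return self._starts[transition_index] + tr.bp + offset

    def locate(self, global_pos: int):
        """Inverse coordinate map.

        Returns ``("duplex", edge_id, duplex, offset)`` for paired positions
        or ``("spacer", transition_index, offset)`` for unpaired vertex
        spacer nucleotides.
        """
        if not 1 <= global_pos <= self.total_nt:
            raise RoutingError(
                f"position {global_pos} outside 1..{self.total_nt}"
            )
        i = bisect_right(self._starts, global_pos - 1) - 1
        tr = self.circuit[i]
        rel = global_pos - self._starts[i]
        if rel <= tr.bp:
            return ("duplex", tr.edge_id, tr.duplex, rel)
        return ("spacer", i, rel - tr.bp)

    def is_paired(self, global_pos: int) -> bool:
        return self.locate(global_pos)[0] == "duplex"

    def duplex_positions(self) -> list[int]:
        """All paired (duplex) global positions, ascending."""
        out = []
        for i, tr in enumerate(self.circuit):
            s = self._starts[i]
            out.extend(range(s + 1, s + tr.bp + 1))
        return out


def route_scaffold(
    mesh: PolyhedralMesh,
    plans: list[EdgePlan],
    tree: frozenset[int],
    spacer_nt: int = 0,
) -> ScaffoldRouting:
    """Route one closed scaffold strand through every duplex of every edge.

    Scaffold double crossovers sit on the non-tree edges (at the edge
    midpoint); ``spacer_nt`` unpaired nucleotides are inserted at each of
    the 2E vertex transitions.
    """
    if spacer_nt < 0:
        raise RoutingError("spacer_nt must be >= 0")
    bp_of = {p.edge_id: p.final_bp for p in plans}
    missing = set(range(mesh.n_edges)) - set(bp_of)
    if missing:
        raise RoutingError(f"plans missing for edges {sorted(missing)}")

    circuit = _eulerian_circuit(mesh, bp_of)

    # rotate so the circuit starts at duplex 0 of the lowest-id tree edge
    first_edge = min(tree)
    k = next(
        i for i, tr in enumerate(circuit)
        if tr.edge_id == first_edge and tr.duplex == 0
    )
    circuit = circuit[k:] + circuit[:k]

    total = sum(tr.bp for tr in circuit) + len(circuit) * spacer_nt
    crossovers = frozenset(range(mesh.n_edges)) - tree
    return ScaffoldRouting(
        circuit=tuple(circuit),
        crossover_edges=crossovers,
        spacer_nt=spacer_nt,
        total_nt=total,
    )


def routing_graph(mesh: PolyhedralMesh) -> nx.MultiGraph:
    """The doubled-edge multigraph the circuit runs on (for inspection)."""
    g = nx.MultiGraph()
    g.add_nodes_from(range(mesh.n_vertices))
    for eid, (u, v) in enumerate(mesh.edges):
        for d in (0, 1):
            g.add_edge(u, v, key=(eid, d))
    return g
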