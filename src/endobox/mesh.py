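"""Polyhedral meshes and B-form edge sizing for wireframe DNA design.

A wireframe nanostructure starts from a closed, consistently oriented
polyhedral mesh of genus 0.  Each mesh edge becomes a DX arm built from two
antiparallel duplexes, and the number of base pairs per edge must be a whole
number of double helical turns (a multiple of 21 bp at 10.5 bp/turn) so the
assembled arms are unstrained B-form DNA.  This module reads and validates
meshes, builds the canonical cube, applies the multiple-of-21 sizing rule,
and predicts physical dimensions from the helical rise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import ply_io

__all__ = [
    "MeshValidationError",
    "EdgeSizingWarning",
    "PolyhedralMesh",
    "EdgePlan",
    "DimensionReport",
    "load_and_validate_mesh",
    "build_cube_mesh",
    "write_mesh_ply",
    "size_edges",
    "round_to_half_turns",
    "predict_dimensions",
]

#: bp per full double turn of B-form DNA (2 x 10.5)
BP_PER_DOUBLE_TURN = 21

#: helical rise of B-form DNA, nm per base pair
DEFAULT_RISE_NM_PER_BP = 0.34


class MeshValidationError(ValueError):
    """Mesh is not a closed, consistently oriented genus-0 surface."""


class EdgeSizingWarning(UserWarning):
    """An edge needed an extension outside the usual {0, 5, 10, 11} set."""


@dataclass(frozen=True)
class PolyhedralMesh:
    """A validated closed polyhedral surface.

    ``edges`` are unordered vertex pairs sorted lexicographically by
    ``(min_vertex, max_vertex)``; an edge's id is its index in that tuple,
    which makes every downstream routing step deterministic.
    """

    vertices: np.ndarray                      # (V, 3) coordinates, nm
    faces: tuple[tuple[int, ...], ...]        # oriented vertex cycles
    edges: tuple[tuple[int, int], ...]        # sorted (u, v) pairs, id = index

    @classmethod
    def from_data(cls, vertices, faces) -> "PolyhedralMesh":
        vertices = np.asarray(vertices, dtype=float)
        faces = tuple(tuple(int(i) for i in f) for f in faces)
        edges = _validate(vertices, faces)
        return cls(vertices=vertices, faces=faces, edges=edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edge_id(self, u: int, v: int) -> int:
        return self.edges.index((min(u, v), max(u, v)))

    def edge_vector(self, edge_id: int) -> np.ndarray:
        u, v = self.edges[edge_id]
        return self.vertices[v] - self.vertices[u]

    def edge_length_nm(self, edge_id: int) -> float:
        return float(np.linalg.norm(self.edge_vector(edge_id)))

    def adjacency(self) -> dict[int, list[int]]:
        """Vertex adjacency with neighbor lists in ascending index order."""
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_vertices)}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for lst in adj.values():
            lst.sort()
        return adj

    def faces_of_edge(self, edge_id: int) -> tuple[int, ...]:
        u, v = self.edges[edge_id]
        hits = []
        for fi, face in enumerate(self.faces):
            for a, b in zip(face, face[1:] + face[:1]):
                if {a, b} == {u, v}:
                    hits.append(fi)
                    break
        return tuple(hits)

    def __eq__(self, other):
        if not isinstance(other, PolyhedralMesh):
            return NotImplemented
        return (
            np.array_equal(self.vertices, other.vertices)
            and self.faces == other.faces
            and self.edges == other.edges
        )

    def __hash__(self):  # frozen dataclass with ndarray field
        return hash((self.vertices.tobytes(), self.faces, self.edges))


def _validate(vertices: np.ndarray, faces) -> tuple[tuple[int, int], ...]:
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshValidationError("vertices must be an (V, 3) array")
    nv = len(vertices)
    if nv < 4 or len(faces) < 1:
        raise MeshValidationError("a closed surface needs at least 4 vertices")

    directed: dict[tuple[int, int], int] = {}
    used = set()
    for fi, face in enumerate(faces):
        if len(face) < 3:
            raise MeshValidationError(f"face {fi} has fewer than 3 vertices")
        if len(set(face)) != len(face):
            raise MeshValidationError(f"face {fi} repeats a vertex")
        for a, b in zip(face, face[1:] + face[:1]):
            if not (0 <= a < nv and 0 <= b < nv):
                raise MeshValidationError(f"face {fi} references missing vertex")
            if (a, b) in directed:
                raise MeshValidationError(
                    f"edge ({a}, {b}) traversed twice in the same direction "
                    "(non-manifold or inconsistently oriented)"
                )
            directed[(a, b)] = fi
            used.add(a)
    if used != set(range(nv)):
        raise MeshValidationError("mesh contains unreferenced vertices")

    undirected = sorted({(min(a, b), max(a, b)) for a, b in directed})
    for u, v in undirected:
        n_dir = ((u, v) in directed) + ((v, u) in directed)
        if n_dir != 2:
            raise MeshValidationError(
                f"edge ({u}, {v}) borders {n_dir} face(s); closed 2-manifold requires 2"
            )
    euler = nv - len(undirected) + len(faces)
    if euler != 2:
        raise MeshValidationError(
            f"Euler characteristic V-E+F = {euler}, expected 2 (genus 0)"
        )
    return tuple(undirected)


def load_and_validate_mesh(path) -> PolyhedralMesh:
    """Read a PLY file and return a validated :class:`PolyhedralMesh`."""
    vertices, faces = ply_io.read_ply(path)
    return PolyhedralMesh.from_data(vertices, faces)


def build_cube_mesh(edge_nm: float) -> PolyhedralMesh:
    """Axis-aligned cube centered at the origin with the given edge length."""
    if not edge_nm > 0:
        raise ValueError(f"edge_nm must be positive, got {edge_nm}")
    h = edge_nm / 2.0
    vertices = np.array(
        [
            [-h, -h, -h], [h, -h, -h], [h, h, -h], [-h, h, -h],
            [-h, -h, h], [h, -h, h], [h, h, h], [-h, h, h],
        ]
    )
    faces = [
        (0, 3, 2, 1),  # bottom, z = -h
        (4, 5, 6, 7),  # top
        (0, 1, 5, 4),  # y = -h
        (1, 2, 6, 5),  # x = +h
        (2, 3, 7, 6),  # y = +h
        (3, 0, 4, 7),  # x = -h
    ]
    return PolyhedralMesh.from_data(vertices, faces)


def write_mesh_ply(mesh: PolyhedralMesh, path, binary: bool = False) -> None:
    ply_io.write_ply(path, mesh.vertices, mesh.faces, binary=binary)


@dataclass(frozen=True)
class EdgePlan:
    """Base-pair budget for one DX edge after the multiple-of-21 correction."""

    edge_id: int
    raw_bp: int
    final_bp: int
    extension: int
    duplexes_per_edge: int = 2
    fallback: bool = False    # extension fell outside {0, 5, 10, 11}

    def __post_init__(self):
        if self.final_bp != self.raw_bp + self.extension:
            raise ValueError("final_bp must equal raw_bp + extension")
        if self.final_bp % BP_PER_DOUBLE_TURN != 0 or self.final_bp < BP_PER_DOUBLE_TURN:
            raise ValueError("final_bp must be a positive multiple of 21")


def round_to_half_turns(n_turns: float) -> int:
    """Round ``n_turns x 10.5`` bp to the nearest integer, half away from zero."""
    x = n_turns * 10.5
    return int(math.floor(x + 0.5))


def size_edges(mesh: PolyhedralMesh, target_bp_per_edge) -> list[EdgePlan]:
    """Assign each edge a final length that is a multiple of 21 bp.

    ``target_bp_per_edge`` is a single integer applied to all edges or a
    mapping ``edge_id -> bp``.  The extension is the smallest e >= 0 with
    ``(raw + e) % 21 == 0``; inputs derived from rounding N x 10.5 always
    yield e in {0, 10, 11} (e = 5 arises for remainder-16 inputs).  Any
    other extension is applied but flagged with :class:`EdgeSizingWarning`.
    """
    plans = []
    for eid in range(mesh.n_edges):
        if isinstance(target_bp_per_edge, (int, np.integer)):
            raw = int(target_bp_per_edge)
        else:
            try:
                raw = int(target_bp_per_edge[eid])
            except (KeyError, IndexError) as exc:
                raise ValueError(f"no target length for edge {eid}") from exc
        if raw < BP_PER_DOUBLE_TURN:
            raise ValueError(
                f"edge {eid}: target {raw} bp is below the 21 bp minimum"
            )
        ext = (-raw) % BP_PER_DOUBLE_TURN
        fallback = ext not in (0, 5, 10, 11)
        if fallback:
            warnings.warn(
                f"edge {eid}: remainder {raw % 21} closed by extension {ext}, "
                "outside the usual {0, 5, 10, 11}",
                EdgeSizingWarning,
                stacklevel=2,
            )
        plans.append(
            EdgePlan(edge_id=eid, raw_bp=raw, final_bp=raw + ext, extension=ext,
                     fallback=fallback)
        )
    return plans


@dataclass(frozen=True)
class DimensionReport:
    per_edge_nm: dict[int, float]
    bounding_box_nm: tuple[float, float, float] | None


def predict_dimensions(
    plans: list[EdgePlan],
    rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP,
    mesh: PolyhedralMesh | None = None,
) -> DimensionReport:
    """Physical edge lengths (edge_nm = final_bp x rise) and bounding box.

    The bounding box is reported when a mesh is supplied: the mesh is scaled
    so its mean edge length matches the mean predicted edge length.
    """
    if not plans:
        raise ValueError("plans must be non-empty")
    if not rise_nm_per_bp > 0:
        raise ValueError("rise must be positive")
    per_edge = {p.edge_id: p.final_bp * rise_nm_per_bp for p in plans}
    bbox = None
    if mesh is not None:
        mesh_lengths = [mesh.edge_length_nm(p.edge_id) for p in plans]
        scale = (sum(per_edge.values()) / len(per_edge)) / (
            sum(mesh_lengths) / len(mesh_lengths)
        )
        span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        bbox = tuple(float(s * scale) for s in span)
    return DimensionReport(per_edge_nm=per_edge, bounding_box_nm=bbox)
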