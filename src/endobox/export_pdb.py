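"""Coarse-grained 3D model of a design and PDB serialization.

One pseudo-atom (a phosphate proxy) is placed per nucleotide.  Each edge's
two duplexes are laid as parallel B-form helices along the mesh edge
vector, offset symmetrically from the edge midline; unpaired vertex spacers
are interpolated between the flanking duplex ends.  The defaults are
standard B-form constants: 3.4 A rise/bp, 34.3 deg twist/bp, 10 A helix
radius, 25 A center-to-center inter-duplex gap.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExportError",
    "GeometryConstants",
    "AtomRecord",
    "CoarseModel",
    "build_coarse_model",
    "write_pdb",
    "read_pdb",
]

_CHAIN_CHARS = string.ascii_uppercase + string.ascii_lowercase + string.digits


class ExportError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryConstants:
    rise_A: float = 3.4
    twist_deg: float = 34.3
    radius_A: float = 10.0
    duplex_gap_A: float = 25.0
    #: max extra backbone step length beyond the rise (crossover hops)
    backbone_slack_A: float = 45.0
    #: angular offset of the staple backbone around the helix, degrees
    minor_groove_deg: float = 150.0


@dataclass(frozen=True)
class AtomRecord:
    strand: str
    residue: int       # 1-based within the strand
    base: str
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class CoarseModel:
    records: tuple[AtomRecord, ...]
    geometry: GeometryConstants

    @property
    def n_atoms(self) -> int:
        return len(self.records)

    def coords(self) -> np.ndarray:
        return np.array([[r.x, r.y, r.z] for r in self.records])

    def bounding_box_A(self) -> tuple[float, float, float]:
        c = self.coords()
        return tuple((c.max(axis=0) - c.min(axis=0)).tolist())


def _edge_frame(mesh, edge_id):
    u, v = mesh.edges[edge_id]
    p0 = mesh.vertices[u] * 10.0   # nm -> A
    p1 = mesh.vertices[v] * 10.0
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length == 0:
        raise ExportError(f"edge {edge_id} has zero length")
    axis = axis / length
    ref = min(
        (np.eye(3)[i] for i in range(3)),
        key=lambda e: abs(float(np.dot(e, axis))),
    )
    n1 = np.cross(axis, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(axis, n1)
    return p0, axis, length, n1, n2


def build_coarse_model(design, geometry: GeometryConstants | None = None) -> CoarseModel:
    """One pseudo-atom per nucleotide of every strand of the design."""
    if design is None or not getattr(design, "scaffold_seq", ""):
        raise ExportError("design is not sequenced; nothing to export")
    if design.mesh is None:
        raise ExportError("design carries no mesh; cannot place coordinates")
    geo = geometry or GeometryConstants()
    twist = math.radians(geo.twist_deg)
    groove = math.radians(geo.minor_groove_deg)

    routing = design.routing
    frames = {}
    for tr in routing.circuit:
        if tr.edge_id not in frames:
            frames[tr.edge_id] = _edge_frame(design.mesh, tr.edge_id)

    def helix_point(edge_id, duplex, axial, bp, phase):
        p0, axis, length, n1, n2 = frames[edge_id]
        margin = (length - (bp - 1) * geo.rise_A) / 2.0
        center = (
            p0
            + axis * (margin + (axial - 1) * geo.rise_A)
            + n1 * (geo.duplex_gap_A / 2.0 * (1 if duplex else -1))
        )
        theta = twist * (axial - 1) + phase
        return center + geo.radius_A * (math.cos(theta) * n1 + math.sin(theta) * n2)

    # scaffold coordinates per global position
    pos_xyz: dict[int, np.ndarray] = {}
    for i, tr in enumerate(routing.circuit):
        fwd = tr.start_vertex < tr.end_vertex
        for off in range(1, tr.bp + 1):
            axial = off if fwd else tr.bp + 1 - off
            g = routing.position_of(tr.edge_id, tr.duplex, off)
            pos_xyz[g] = helix_point(tr.edge_id, tr.duplex, axial, tr.bp, 0.0)
    # spacers: straight-line interpolation across each vertex transition
    for i, tr in enumerate(routing.circuit):
        if routing.spacer_nt == 0:
            break
        nxt = routing.circuit[(i + 1) % len(routing.circuit)]
        a = pos_xyz[routing.position_of(tr.edge_id, tr.duplex, tr.bp)]
        b = pos_xyz[routing.position_of(nxt.edge_id, nxt.duplex, 1)]
        for k in range(1, routing.spacer_nt + 1):
            t = k / (routing.spacer_nt + 1)
            pos_xyz[routing.spacer_position(i, k)] = a + (b - a) * t

    records = []
    for uid, span, _num in design.strand_ids():
        for res, g in enumerate(range(span.start, span.end + 1), start=1):
            xyz = pos_xyz[g]
            records.append(
                AtomRecord(uid, res, design.scaffold_seq[g - 1],
                           float(xyz[0]), float(xyz[1]), float(xyz[2]))
            )
    for si, rec in enumerate(design.staples.staples):
        seq = design.staple_sequence(si)
        for res, g in enumerate(rec.footprint, start=1):
            kind, edge_id, duplex, off = routing.locate(g)
            tr = routing.circuit[routing.traversal_of(edge_id, duplex)]
            fwd = tr.start_vertex < tr.end_vertex
            axial = off if fwd else tr.bp + 1 - off
            xyz = helix_point(edge_id, duplex, axial, tr.bp, groove)
            records.append(
                AtomRecord(rec.name, res, seq[res - 1],
                           float(xyz[0]), float(xyz[1]), float(xyz[2]))
            )
    if not records:
        raise ExportError("empty model")
    return CoarseModel(records=tuple(records), geometry=geo)


def _strand_order(model: CoarseModel) -> list[str]:
    order = []
    for r in model.records:
        if not order or order[-1] != r.strand:
            if r.strand in order:
                raise ExportError(f"strand {r.strand!r} records are not contiguous")
            order.append(r.strand)
    return order


def write_pdb(model: CoarseModel, path) -> None:
    """Fixed-column PDB: one ATOM (P pseudo-atom) per nucleotide.

    Strands map to chain ids while the 62 chain characters last; larger
    designs fall back to blank chains with numbered segment identifiers.
    The strand-name <-> segment mapping rides in REMARK 300 lines so the
    file re-parses to an equal model.
    """
    if model.n_atoms == 0:
        raise ExportError("refusing to write an empty model")
    strands = _strand_order(model)
    use_chains = len(strands) <= len(_CHAIN_CHARS)
    seg_of = {s: f"{i:04d}" for i, s in enumerate(strands)}
    chain_of = {
        s: (_CHAIN_CHARS[i] if use_chains else " ") for i, s in enumerate(strands)
    }
    lines = []
    for i, s in enumerate(strands):
        lines.append(f"REMARK 300 STRAND {seg_of[s]} {s}")
    serial = 0
    prev = None
    for r in model.records:
        if prev is not None and prev != r.strand:
            serial += 1
            lines.append(f"TER   {serial:5d}")
        serial += 1
        res_name = ("D" + r.base).rjust(3)
        lines.append(
            f"ATOM  {serial % 100000:5d}  P   {res_name} "
            f"{chain_of[r.strand]}{r.residue % 10000:4d}    "
            f"{r.x:8.3f}{r.y:8.3f}{r.z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
            f"{seg_of[r.strand]:<4s} P"
        )
        prev = r.strand
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path, geometry: GeometryConstants | None = None) -> CoarseModel:
    """Parse a file written by :func:`write_pdb` back into a CoarseModel."""
    names: dict[str, str] = {}
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 300 STRAND"):
                parts = line.rstrip("\n").split(" ", 4)
                names[parts[3]] = parts[4]
            elif line.startswith("ATOM"):
                seg = line[72:76].strip()
                strand = names.get(seg, seg)
                records.append(
                    AtomRecord(
                        strand=strand,
                        residue=int(line[22:26]),
                        base=line[17:20].strip()[-1],
                        x=float(line[30:38]),
                        y=float(line[38:46]),
                        z=float(line[46:54]),
                    )
                )
    if not records:
        raise ExportError(f"no ATOM records in {path}")
    return CoarseModel(records=tuple(records), geometry=geometry or GeometryConstants())
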