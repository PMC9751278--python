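"""Restriction-site "can-lid" insertion and fluorophore/quencher labels.

The lid mechanism substitutes a restriction motif (canonically BamHI,
5'-GGATCC-3') into short scaffold strands of split modules, so that the
enzyme can later cut the assembled box open and T4 ligase can reseal it.
Substitution keeps every printed coordinate stable: bases are replaced in
place, never inserted.  FRET reporter dyes attach to the staples covering
designated scaffold bases -- the fluorophore stays on the box, the quencher
rides the lid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .assembly import build_assembly, separation_bp
from .seqplan import Design, SequenceError, reverse_complement
from .staples import Decoration, StapleSet

__all__ = [
    "LidError",
    "ContaminationError",
    "PlacementError",
    "LabelPair",
    "LidSpec",
    "screen_motif",
    "apply_lid",
    "check_pair_geometry",
    "anchor_edges",
    "anchor_common_faces",
]


class LidError(ValueError):
    pass


class ContaminationError(LidError):
    """The motif pre-exists in the gene or design."""


class PlacementError(LidError):
    """An anchor or label cannot be placed where requested."""


@dataclass(frozen=True)
class LabelPair:
    pair_id: int
    fluor_dye: str
    fluor_pos: int          # global scaffold position the fluorophore faces
    quencher_dye: str
    quencher_pos: int


@dataclass(frozen=True)
class LidSpec:
    enzyme_name: str = "BamHI"
    motif: str = "GGATCC"
    cut_offset_top: int = 1        # G^GATCC
    cut_offset_bottom: int = 5     # CCTAG^G  -> 4-nt 5' GATC overhangs
    site_anchors: tuple[tuple[int, int], ...] = ()
    label_pairs: tuple[LabelPair, ...] = ()

    def __post_init__(self):
        if len(self.motif) < 4:
            raise LidError("motif must be at least 4 nt")
        if not 1 <= self.cut_offset_top < len(self.motif):
            raise LidError("cut_offset_top outside motif")
        if not self.cut_offset_top <= self.cut_offset_bottom <= len(self.motif) - 1:
            raise LidError("cut_offset_bottom outside motif")
        for s, e in self.site_anchors:
            if e - s + 1 != len(self.motif):
                raise LidError(f"anchor {s}..{e} is not motif-sized")

    @property
    def overhang_nt(self) -> int:
        return self.cut_offset_bottom - self.cut_offset_top


def screen_motif(sequence: str, motif: str) -> list[int]:
    """1-based start positions where the motif occurs on either strand.

    Reverse-strand hits are reported at the 5' start of the matching window
    in the given strand's coordinates.  Overlapping occurrences count.  An
    empty list certifies the sequence as lid-eligible.
    """
    if len(motif) < 4:
        raise LidError("motif must be at least 4 nt")
    targets = {motif, reverse_complement(motif)}
    # reverse_complement validates the alphabet of the motif; check sequence
    from .seqplan import _check_alphabet

    _check_alphabet(sequence)
    w = len(motif)
    return [
        i + 1
        for i in range(len(sequence) - w + 1)
        if sequence[i: i + w] in targets
    ]


def _count_design_sites(scaffold_seq: str, motif: str) -> int:
    return len(screen_motif(scaffold_seq, motif))


def apply_lid(design: Design, lid: LidSpec) -> Design:
    """Substitute the motif at each anchor and attach the dye labels.

    Preconditions checked: the unit gene is motif-free on both strands,
    every anchor lies inside a short strand of a split module, and every
    anchor base is paired (staple-covered).  Afterwards the design contains
    exactly ``len(site_anchors)`` motif occurrences and no others.
    """
    if not lid.site_anchors:
        return replace(design, lid=lid)

    if screen_motif(design.unit.sequence, lid.motif):
        raise ContaminationError(
            f"unit gene already contains {lid.enzyme_name} site(s); "
            "screen or resynthesize the gene first"
        )

    seq = list(design.scaffold_seq)
    for start, end in lid.site_anchors:
        if not 1 <= start <= end <= len(seq):
            raise PlacementError(f"anchor {start}..{end} outside the scaffold")
        module, strand = design.msplan.strand_of(start)
        if strand.kind != "short":
            raise PlacementError(
                f"anchor {start}..{end} lies on {strand.name!r} "
                f"(module {module.numeral}), not on a short strand of a "
                "split module"
            )
        if not (strand.start <= start and end <= strand.end):
            raise PlacementError(
                f"anchor {start}..{end} crosses the boundary of {strand.name!r}"
            )
        for pos in range(start, end + 1):
            if design.staples.staple_at(pos) is None:
                raise PlacementError(
                    f"anchor base {pos} is unpaired; sites must be duplex"
                )
        seq[start - 1: end] = lid.motif
    new_seq = "".join(seq)

    n_sites = _count_design_sites(new_seq, lid.motif)
    if n_sites != len(lid.site_anchors):
        raise ContaminationError(
            f"lidded scaffold contains {n_sites} motif occurrence(s), "
            f"expected {len(lid.site_anchors)}"
        )

    staples = _place_labels(design.staples, lid, new_seq)
    return replace(design, scaffold_seq=new_seq, staples=staples, lid=lid)


def _place_labels(staples: StapleSet, lid: LidSpec, scaffold_seq: str) -> StapleSet:
    decos: dict[int, list[Decoration]] = {}
    for pair in lid.label_pairs:
        placements = [
            (pair.fluor_dye, pair.fluor_pos, "fluorophore"),
            (pair.quencher_dye, pair.quencher_pos, "quencher"),
        ]
        hit_staples = []
        for dye, pos, role in placements:
            hit = staples.staple_at(pos)
            if hit is None:
                raise PlacementError(
                    f"label {dye} targets unpaired scaffold base {pos}"
                )
            si, ni = hit
            hit_staples.append(si)
            decos.setdefault(si, []).append(
                Decoration(
                    dye=dye, nt_index=ni, role=role, pair_id=pair.pair_id,
                    scaffold_pos=pos,
                )
            )
        if hit_staples[0] == hit_staples[1]:
            raise PlacementError(
                f"pair {pair.pair_id}: fluorophore and quencher fall on the "
                "same staple; they must sit on different strands"
            )
    new = []
    for si, rec in enumerate(staples.staples):
        if si in decos:
            rec = replace(rec, decorations=tuple(decos[si]))
        new.append(rec)
    return StapleSet(staples=tuple(new))


@dataclass(frozen=True)
class GeometryCheck:
    pair_id: int
    separation_bp: int
    threshold_bp: int
    passed: bool


def check_pair_geometry(
    design: Design, pair: LabelPair, threshold_bp: int = 15
) -> GeometryCheck:
    """Measure a label pair's separation along the assembled duplex graph.

    Separation is the minimal number of base-pair steps (backbone steps cost
    1, base-pair rungs cost 0) between the two labeled staple nucleotides in
    the intact assembly.  Passes iff separation <= threshold.
    """
    assembly = build_assembly(design)
    nts = {}
    for role in ("fluorophore", "quencher"):
        hits = [
            lab for lab in assembly.labels
            if lab.pair_id == pair.pair_id and lab.role == role
        ]
        if not hits:
            raise LidError(f"pair {pair.pair_id}: {role} label not placed")
        nts[role] = (hits[0].strand, hits[0].index)
    sep = separation_bp(assembly, nts["fluorophore"], nts["quencher"])
    return GeometryCheck(
        pair_id=pair.pair_id,
        separation_bp=sep,
        threshold_bp=threshold_bp,
        passed=0 <= sep <= threshold_bp,
    )


def anchor_edges(design: Design, lid: LidSpec | None = None) -> dict[tuple[int, int], int]:
    """Map each site anchor to the mesh edge its duplex belongs to."""
    lid = lid or design.lid
    if lid is None:
        raise LidError("design has no lid")
    out = {}
    for start, end in lid.site_anchors:
        kind, *rest = design.routing.locate(start)
        if kind != "duplex":
            raise PlacementError(f"anchor start {start} falls in a spacer")
        out[(start, end)] = rest[0]
    return out


def anchor_common_faces(design: Design, lid: LidSpec | None = None) -> set[int]:
    """Mesh faces shared by the duplex edges of all site anchors.

    Non-empty means all sites sit on a single surface of the polyhedron.
    """
    edges = set(anchor_edges(design, lid).values())
    face_sets = [set(design.mesh.faces_of_edge(eid)) for eid in edges]
    common = face_sets[0]
    for fs in face_sets[1:]:
        common &= fs
    return common
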