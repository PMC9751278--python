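"""Staple generation for DX edges and module assignment.

Each edge holds two parallel duplexes whose scaffold strands are clamped by
staple strands.  Staples are laid per 21-bp block (one double turn): the
block is split at its 10|11 position and each staple clamps the same axial
half of both duplexes, swapping duplexes at the split -- an antiparallel
double crossover -- with nicks at the block boundaries, as far from the
crossover as the geometry allows.  Staples are 20 or 22 nt (one bp off two
half-turns, 2 x 10.5), inside the 20-60 nt synthesis window.

Axial coordinates run along the edge from its lower-numbered vertex, so the
staple pattern is a property of the edge, independent of the direction the
scaffold happens to traverse each duplex.  Every staple segment runs
antiparallel to the scaffold it covers: its footprint is listed in
descending scaffold-offset order.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace

from .routing import ScaffoldRouting
from .seqplan import roman_numeral

__all__ = [
    "StapleDesignError",
    "Decoration",
    "StapleSegment",
    "StapleRecord",
    "StapleSet",
    "generate_staples",
    "assign_staples_to_modules",
    "write_staple_table",
]

BLOCK_BP = 21
MIN_STAPLE_NT = 20
MAX_STAPLE_NT = 60


class StapleDesignError(ValueError):
    pass


@dataclass(frozen=True)
class Decoration:
    """A dye attached to one staple nucleotide."""

    dye: str
    nt_index: int        # 0-based index into the staple, 5'->3'
    role: str            # "fluorophore" | "quencher"
    pair_id: int
    scaffold_pos: int    # the scaffold base the labeled nucleotide pairs


@dataclass(frozen=True)
class StapleSegment:
    """A contiguous run on one duplex, in staple 5'->3' order.

    ``start_offset``/``end_offset`` are inclusive duplex offsets (the
    scaffold's 1..bp coordinate through that duplex); staples run
    antiparallel to the scaffold, so ``start_offset > end_offset``.
    """

    edge_id: int
    duplex: int
    start_offset: int
    end_offset: int

    @property
    def length(self) -> int:
        return abs(self.end_offset - self.start_offset) + 1

    @property
    def direction(self) -> int:
        """-1 when running against the scaffold (the antiparallel normal)."""
        return 1 if self.end_offset >= self.start_offset else -1


@dataclass(frozen=True)
class StapleRecord:
    name: str
    segments: tuple[StapleSegment, ...]
    footprint: tuple[int, ...]     # covered global scaffold positions, 5'->3'
    modules: frozenset[str] = frozenset()
    shared: bool = False
    decorations: tuple[Decoration, ...] = ()

    @property
    def length_nt(self) -> int:
        return len(self.footprint)


@dataclass(frozen=True)
class StapleSet:
    staples: tuple[StapleRecord, ...]

    def __post_init__(self):
        cover: dict[int, tuple[int, int]] = {}
        for si, rec in enumerate(self.staples):
            for ni, pos in enumerate(rec.footprint):
                if pos in cover:
                    raise StapleDesignError(
                        f"scaffold position {pos} covered by two staples"
                    )
                cover[pos] = (si, ni)
        object.__setattr__(self, "cover", cover)

    @property
    def total_nt(self) -> int:
        return sum(rec.length_nt for rec in self.staples)

    def staple_at(self, global_pos: int) -> tuple[int, int] | None:
        """(staple index, nt index) covering a scaffold position, if any."""
        return self.cover.get(global_pos)

    def by_name(self, name: str) -> StapleRecord:
        for rec in self.staples:
            if rec.name == name:
                return rec
        raise KeyError(name)


def _axial_to_offset(axial: int, bp: int, forward: bool) -> int:
    return axial if forward else bp + 1 - axial


def generate_staples(routing: ScaffoldRouting, plans) -> StapleSet:
    """Staples covering every paired scaffold nucleotide exactly once.

    Spacer nucleotides stay uncovered.  Raises if any edge is shorter than
    one 21-bp block or not block-aligned.
    """
    bp_of = {p.edge_id: p.final_bp for p in plans}
    # traversal direction per (edge, duplex): True if it runs with the axial
    # direction (low vertex -> high vertex)
    forward = {}
    vertices = {}
    for tr in routing.circuit:
        forward[(tr.edge_id, tr.duplex)] = tr.start_vertex < tr.end_vertex
        vertices[tr.edge_id] = tuple(sorted((tr.start_vertex, tr.end_vertex)))
        if tr.bp != bp_of.get(tr.edge_id):
            raise StapleDesignError(
                f"edge {tr.edge_id}: routing bp {tr.bp} != plan bp {bp_of.get(tr.edge_id)}"
            )

    staples = []
    for eid in sorted(bp_of):
        bp = bp_of[eid]
        if bp < BLOCK_BP:
            raise StapleDesignError(
                f"edge {eid}: {bp} bp is too short to staple (min {BLOCK_BP})"
            )
        if bp % BLOCK_BP != 0:
            raise StapleDesignError(
                f"edge {eid}: {bp} bp is not a multiple of {BLOCK_BP}"
            )
        a, b = vertices[eid]
        n_blocks = bp // BLOCK_BP
        counter = 0

        def half_segment(duplex: int, axial_lo: int, axial_hi: int) -> StapleSegment:
            fwd = forward[(eid, duplex)]
            offs = sorted(
                _axial_to_offset(ax, bp, fwd)
                for ax in range(axial_lo, axial_hi + 1)
            )
            return StapleSegment(eid, duplex, offs[-1], offs[0])  # descending

        for j in range(n_blocks):
            base = j * BLOCK_BP
            # each staple clamps one axial half of the block on both
            # duplexes, crossing over at the 10|11 split
            for axial_lo, axial_hi in (
                (base + 11, base + BLOCK_BP),   # upper half, 11 + 11 nt
                (base + 1, base + 10),          # lower half, 10 + 10 nt
            ):
                counter += 1
                segs = (
                    half_segment(0, axial_lo, axial_hi),
                    half_segment(1, axial_lo, axial_hi),
                )
                footprint = []
                for seg in segs:
                    for off in range(seg.start_offset, seg.end_offset - 1, -1):
                        footprint.append(
                            routing.position_of(seg.edge_id, seg.duplex, off)
                        )
                name = f"V^{a}_{b}({counter})"
                rec = StapleRecord(
                    name=name, segments=segs, footprint=tuple(footprint)
                )
                if not MIN_STAPLE_NT <= rec.length_nt <= MAX_STAPLE_NT:
                    raise StapleDesignError(
                        f"staple {name}: length {rec.length_nt} outside "
                        f"[{MIN_STAPLE_NT}, {MAX_STAPLE_NT}]"
                    )
                staples.append(rec)

    staple_set = StapleSet(staples=tuple(staples))
    paired = routing.duplex_positions()
    if staple_set.total_nt != len(paired) or set(staple_set.cover) != set(paired):
        raise StapleDesignError("staples do not exactly cover the paired scaffold")
    return staple_set


def assign_staples_to_modules(
    staple_set: StapleSet, module_boundaries: list[int]
) -> StapleSet:
    """Mark each staple with the modules its scaffold footprint touches.

    ``module_boundaries`` are the sorted global end positions of modules
    I, II, ... in traversal order; a staple touching two or more modules is
    an inter-module shared staple.
    """
    if not module_boundaries:
        raise StapleDesignError("module boundary list is empty")
    if list(module_boundaries) != sorted(module_boundaries):
        raise StapleDesignError("module boundaries must be sorted")
    if module_boundaries[0] < 1:
        raise StapleDesignError("module boundaries must be >= 1")
    last = module_boundaries[-1]

    out = []
    for rec in staple_set.staples:
        mods = set()
        for pos in rec.footprint:
            if pos > last:
                raise StapleDesignError(
                    f"staple {rec.name} covers position {pos} beyond the last "
                    f"module boundary {last}"
                )
            mods.add(roman_numeral(bisect_left(module_boundaries, pos) + 1))
        out.append(
            replace(rec, modules=frozenset(mods), shared=len(mods) >= 2)
        )
    return StapleSet(staples=tuple(out))


def write_staple_table(design, path) -> None:
    """Tab-separated staple listing (name, modules, shared, length, sequence,
    segment map), one row per staple."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(design.staples.staples):
        seg_map = ";".join(
            f"e{s.edge_id}.d{s.duplex}:{s.start_offset}-{s.end_offset}"
            for s in rec.segments
        )
        rows.append(
            {
                "name": rec.name,
                "modules": "+".join(sorted(rec.modules)) or "-",
                "shared": rec.shared,
                "length": rec.length_nt,
                "sequence": design.staple_sequence(i),
                "segments": seg_map,
                "labels": ";".join(
                    f"{d.dye}@{d.nt_index}" for d in rec.decorations
                ) or "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
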