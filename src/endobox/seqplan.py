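"""Multiscaffold sequence planning: tile a unit gene along the routed scaffold.

Instead of a single viral scaffold, the design repeats an endogenous gene as
many times as the routed length requires.  The routed scaffold is segmented
into modules (one gene copy each, numbered I, II, ... in traversal order);
the final module receives a trimmed copy, with the surplus removed
symmetrically from the gene's upstream and downstream ends.  Designated
modules can then be split into a main scaffold strand plus short strands --
the short strands are the ones that later receive restriction-site
substitutions to form the lid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .mesh import EdgePlan, PolyhedralMesh
    from .routing import ScaffoldRouting
    from .staples import StapleSet
    from .lid import LidSpec

__all__ = [
    "SequenceError",
    "GeneUnit",
    "StrandSpan",
    "ModuleSpan",
    "MultiscaffoldPlan",
    "Design",
    "roman_numeral",
    "load_gene_fasta",
    "plan_modules",
    "split_module_scaffolds",
    "apply_sequences",
    "complement",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
]


class SequenceError(ValueError):
    pass


def roman_numeral(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def complement(seq: str) -> str:
    _check_alphabet(seq)
    return seq.translate(_COMP)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise SequenceError(f"sequence contains non-ACGT letters: {sorted(bad)}")


@dataclass(frozen=True)
class GeneUnit:
    """The unit gene whose repeats form the scaffold."""

    id: str
    sequence: str

    def __post_init__(self):
        _check_alphabet(self.sequence)
        if len(self.sequence) < 21:
            raise SequenceError("gene unit must be at least 21 nt")

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_gene_fasta(path) -> GeneUnit:
    """Read the first record of a FASTA file as the unit gene."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return GeneUnit(id=rec.id, sequence=str(rec.seq).upper())
    raise SequenceError(f"no FASTA records in {path}")


@dataclass(frozen=True)
class StrandSpan:
    """One scaffold strand: a contiguous run of global positions."""

    name: str
    start: int      # global, 1-based, inclusive
    end: int
    kind: str = "main"   # "main" | "short"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ModuleSpan:
    numeral: str
    index: int          # 0-based
    start: int
    end: int
    strands: tuple[StrandSpan, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def main_strand(self) -> StrandSpan:
        mains = [s for s in self.strands if s.kind == "main"]
        if len(mains) != 1:
            raise SequenceError(f"module {self.numeral} has {len(mains)} main strands")
        return mains[0]

    @property
    def short_strands(self) -> tuple[StrandSpan, ...]:
        return tuple(s for s in self.strands if s.kind == "short")

    @property
    def is_split(self) -> bool:
        return len(self.strands) > 1


@dataclass(frozen=True)
class MultiscaffoldPlan:
    unit_id: str
    unit_length: int
    total_nt: int
    cycles: int
    trim_upstream_nt: int
    trim_downstream_nt: int
    modules: tuple[ModuleSpan, ...]

    def module_of(self, pos: int) -> ModuleSpan:
        for m in self.modules:
            if m.start <= pos <= m.end:
                return m
        raise SequenceError(f"position {pos} outside 1..{self.total_nt}")

    def strand_of(self, pos: int) -> tuple[ModuleSpan, StrandSpan]:
        m = self.module_of(pos)
        for s in m.strands:
            if s.start <= pos <= s.end:
                return m, s
        raise SequenceError(f"position {pos} not covered by any strand")  # pragma: no cover

    def module_boundaries(self) -> list[int]:
        return [m.end for m in self.modules]


def plan_modules(unit: GeneUnit, total_nt: int) -> MultiscaffoldPlan:
    """Segment 1..total_nt into gene-copy modules, trimming the last cycle.

    ``cycles = ceil(total_nt / unit.length)``; the first ``cycles - 1``
    modules are full gene copies and the last spans the remainder.  The
    trimmed surplus is removed half upstream, half downstream of the gene
    (odd surplus: the extra nucleotide comes off upstream).
    """
    L = unit.length
    if total_nt < L:
        raise SequenceError(f"total_nt {total_nt} shorter than the unit gene ({L} nt)")
    cycles = math.ceil(total_nt / L)
    trim = cycles * L - total_nt
    trim_up = (trim + 1) // 2
    trim_down = trim // 2

    modules = []
    pos = 1
    for i in range(cycles):
        span = L if i < cycles - 1 else total_nt - (cycles - 1) * L
        numeral = roman_numeral(i + 1)
        name = f"Scaffold-{numeral}"
        modules.append(
            ModuleSpan(
                numeral=numeral,
                index=i,
                start=pos,
                end=pos + span - 1,
                strands=(StrandSpan(name=name, start=pos, end=pos + span - 1),),
            )
        )
        pos += span
    return MultiscaffoldPlan(
        unit_id=unit.id,
        unit_length=L,
        total_nt=total_nt,
        cycles=cycles,
        trim_upstream_nt=trim_up,
        trim_downstream_nt=trim_down,
        modules=tuple(modules),
    )


def scaffold_sequence(plan: MultiscaffoldPlan, unit: GeneUnit) -> str:
    """Concrete scaffold letters for all positions 1..total_nt.

    Full modules carry the unit verbatim; the last module carries the unit
    with ``trim_upstream`` nt removed from its 5' end and ``trim_downstream``
    from its 3' end.  Vertex spacers are scaffold too, so they simply draw
    their letters from the same gene cycle.
    """
    parts = []
    for m in plan.modules:
        if m.index < plan.cycles - 1:
            parts.append(unit.sequence)
        else:
            seq = unit.sequence[
                plan.trim_upstream_nt: plan.unit_length - plan.trim_downstream_nt
            ]
            if len(seq) != m.length:  # pragma: no cover - arithmetic guard
                raise SequenceError("trimmed module length mismatch")
            parts.append(seq)
    return "".join(parts)


def split_module_scaffolds(
    plan: MultiscaffoldPlan,
    split_windows: Mapping[str, dict],
) -> MultiscaffoldPlan:
    """Split designated modules into named short strands plus one main strand.

    ``split_windows`` maps a module numeral to
    ``{"windows": [(start, end, name), ...], "main_name": str}`` with global
    coordinates.  The windows become short strands; the contiguous remainder
    of the module span becomes the main strand.  A fragmented remainder is
    an error.
    """
    new_modules = list(plan.modules)
    for numeral, spec in split_windows.items():
        idx = next((i for i, m in enumerate(new_modules) if m.numeral == numeral), None)
        if idx is None:
            raise SequenceError(f"no module {numeral!r}")
        m = new_modules[idx]
        windows = sorted(spec["windows"], key=lambda w: w[0])
        if not windows:
            raise SequenceError(f"module {numeral}: empty window list")
        for s, e, _name in windows:
            if not (m.start <= s <= e <= m.end):
                raise SequenceError(
                    f"module {numeral}: window {s}..{e} outside span {m.start}..{m.end}"
                )
        for (s1, e1, _), (s2, e2, _) in zip(windows, windows[1:]):
            if s2 <= e1:
                raise SequenceError(f"module {numeral}: overlapping windows")

        # remainder = module span minus the windows; must be one contiguous run
        covered = []
        cursor = m.start
        gaps = []
        for s, e, _ in windows:
            if s > cursor:
                gaps.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= m.end:
            gaps.append((cursor, m.end))
        if len(gaps) != 1:
            raise SequenceError(
                f"module {numeral}: main-strand remainder is not contiguous "
                f"({len(gaps)} runs)"
            )
        main_start, main_end = gaps[0]
        strands = [
            StrandSpan(name=name, start=s, end=e, kind="short")
            for s, e, name in windows
        ]
        strands.append(
            StrandSpan(
                name=spec.get("main_name", f"Scaffold-{m.index + 1}M"),
                start=main_start,
                end=main_end,
                kind="main",
            )
        )
        strands.sort(key=lambda s: s.start)
        new_modules[idx] = replace(m, strands=tuple(strands))
    return replace(plan, modules=tuple(new_modules))


@dataclass(frozen=True)
class Design:
    """A fully sequenced design bundle.

    Staple sequences are always derived from the current scaffold sequence
    (Watson-Crick complement at each covered position), so lid substitutions
    on the scaffold propagate to the covering staples automatically.
    """

    mesh: "PolyhedralMesh"
    plans: tuple["EdgePlan", ...]
    tree: frozenset[int]
    routing: "ScaffoldRouting"
    unit: GeneUnit
    msplan: MultiscaffoldPlan
    staples: "StapleSet"
    scaffold_seq: str
    lid: "LidSpec | None" = None

    def __post_init__(self):
        if len(self.scaffold_seq) != self.routing.total_nt:
            raise SequenceError(
                f"scaffold sequence length {len(self.scaffold_seq)} != "
                f"routed total {self.routing.total_nt}"
            )

    def scaffold_base(self, pos: int) -> str:
        return self.scaffold_seq[pos - 1]

    def staple_sequence(self, staple_index: int) -> str:
        rec = self.staples.staples[staple_index]
        return "".join(
            self.scaffold_seq[p - 1].translate(_COMP) for p in rec.footprint
        )

    def staple_sequences(self) -> dict[str, str]:
        return {
            rec.name: self.staple_sequence(i)
            for i, rec in enumerate(self.staples.staples)
        }

    def strand_ids(self) -> list[tuple[str, StrandSpan, str]]:
        """Unique scaffold strand ids: (unique_id, span, module numeral)."""
        out = []
        seen: dict[str, int] = {}
        for m in self.msplan.modules:
            for s in m.strands:
                uid = s.name
                if uid in seen or any(
                    s2.name == s.name
                    for m2 in self.msplan.modules
                    if m2.numeral != m.numeral
                    for s2 in m2.strands
                ):
                    uid = f"{s.name}({m.numeral})"
                seen[uid] = 1
                out.append((uid, s, m.numeral))
        return out

    def scaffold_strand_sequences(self) -> dict[str, str]:
        return {
            uid: self.scaffold_seq[s.start - 1: s.end]
            for uid, s, _m in self.strand_ids()
        }


def apply_sequences(
    plan: MultiscaffoldPlan,
    unit: GeneUnit,
    routing: "ScaffoldRouting",
    staples: "StapleSet",
    mesh: "PolyhedralMesh" = None,
    plans: tuple = (),
    tree: frozenset[int] = frozenset(),
) -> Design:
    """Attach concrete sequences to the routed, stapled design."""
    if plan.total_nt != routing.total_nt:
        raise SequenceError(
            f"plan covers {plan.total_nt} nt but routing has {routing.total_nt}"
        )
    seq = scaffold_sequence(plan, unit)
    return Design(
        mesh=mesh,
        plans=tuple(plans),
        tree=tree,
        routing=routing,
        unit=unit,
        msplan=plan,
        staples=staples,
        scaffold_seq=seq,
    )


def write_strands_fasta(design: Design, path) -> None:
    """All scaffold strands and staples, one FASTA record per strand."""
    with open(path, "w") as fh:
        for uid, seq in design.scaffold_strand_sequences().items():
            fh.write(f">{uid}\n{seq}\n")
        for name, seq in design.staple_sequences().items():
            fh.write(f">{name}\n{seq}\n")
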