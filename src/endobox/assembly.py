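"""Strand/base-pair graph of an assembled design.

The digestion and FRET machinery operates on a generic duplex assembly:
named strands (5'->3' nucleotide strings) plus a base-pair map between
nucleotides.  ``build_assembly`` derives one from a sequenced design;
small assemblies can also be built directly for focused simulations.
"""

from __future__ import annotations

from collections import OrderedDict, deque
from dataclasses import dataclass

__all__ = ["AssemblyError", "Label", "Assembly", "build_assembly", "separation_bp"]

Nt = tuple[str, int]  # (strand name, 0-based index)


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class Label:
    strand: str
    index: int
    dye: str
    role: str          # "fluorophore" | "quencher"
    pair_id: int


@dataclass(frozen=True)
class Assembly:
    strands: "OrderedDict[str, str]"
    pairs: tuple[tuple[Nt, Nt], ...]
    labels: tuple[Label, ...] = ()

    def __post_init__(self):
        pair_map: dict[Nt, Nt] = {}
        for a, b in self.pairs:
            for nt in (a, b):
                s, i = nt
                if s not in self.strands or not 0 <= i < len(self.strands[s]):
                    raise AssemblyError(f"pair references missing nucleotide {nt}")
            if a in pair_map or b in pair_map:
                raise AssemblyError(f"nucleotide paired twice: {a} / {b}")
            pair_map[a] = b
            pair_map[b] = a
        object.__setattr__(self, "pair_map", pair_map)

    @property
    def total_nt(self) -> int:
        return sum(len(s) for s in self.strands.values())

    def base(self, nt: Nt) -> str:
        return self.strands[nt[0]][nt[1]]


def build_assembly(design) -> Assembly:
    """Assembly of a sequenced (optionally lidded) design.

    Scaffold strands come from the multiscaffold plan (spacers included --
    they are scaffold, just unpaired); staples pair every duplex scaffold
    nucleotide.
    """
    strands: "OrderedDict[str, str]" = OrderedDict()
    pos_to_nt: dict[int, Nt] = {}
    for uid, span, _numeral in design.strand_ids():
        strands[uid] = design.scaffold_seq[span.start - 1: span.end]
        for i, pos in enumerate(range(span.start, span.end + 1)):
            pos_to_nt[pos] = (uid, i)

    labels = []
    pairs = []
    for si, rec in enumerate(design.staples.staples):
        strands[rec.name] = design.staple_sequence(si)
        for ni, pos in enumerate(rec.footprint):
            pairs.append((pos_to_nt[pos], (rec.name, ni)))
        for deco in rec.decorations:
            labels.append(
                Label(
                    strand=rec.name,
                    index=deco.nt_index,
                    dye=deco.dye,
                    role=deco.role,
                    pair_id=deco.pair_id,
                )
            )
    return Assembly(strands=strands, pairs=tuple(pairs), labels=tuple(labels))


def separation_bp(assembly: Assembly, a: Nt, b: Nt) -> int:
    """Minimal base-pair steps between two nucleotides.

    Walking one step along any strand backbone costs 1 bp; crossing a
    base-pair rung costs 0 (the partners sit at the same helical position).
    Returns -1 if the nucleotides are not connected.
    """
    if a == b:
        return 0
    dist = {a: 0}
    dq = deque([a])
    pair_map = assembly.pair_map
    while dq:
        cur = dq.popleft()
        d = dist[cur]
        s, i = cur
        neighbors = []
        mate = pair_map.get(cur)
        if mate is not None:
            neighbors.append((mate, 0))
        if i > 0:
            neighbors.append(((s, i - 1), 1))
        if i + 1 < len(assembly.strands[s]):
            neighbors.append(((s, i + 1), 1))
        for nxt, w in neighbors:
            nd = d + w
            if nxt not in dist or nd < dist[nxt]:
                dist[nxt] = nd
                if w == 0:
                    dq.appendleft(nxt)
                else:
                    dq.append(nxt)
    return dist.get(b, -1)
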