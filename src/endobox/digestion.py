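"""Restriction digestion, ligation, cargo loading and FRET state prediction.

Digestion is simulated at strand resolution on the assembly's strand/
base-pair graph.  A motif occurrence is cut only when fully duplex; the cut
severs both backbones at the enzyme's staggered offsets and dissolves the
base pairs of the short overhang (a 4-bp duplex does not survive), leaving
complementary 5' sticky ends.  T4 ligation reseals junctions -- original
junctions preferred -- restoring the pre-digest strand multiset exactly.
Cargo loading is a bookkeeping state change on an opened box.

Nucleotides are never created or destroyed: strands stay whole and the
state tracks severed backbone bonds and dissolved pairs, so conservation
holds by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

from .assembly import Assembly, build_assembly, separation_bp
from .lid import LidSpec
from .seqplan import Design, reverse_complement

__all__ = [
    "DigestionError",
    "StateError",
    "Cargo",
    "CutRecord",
    "StickyEnd",
    "DigestState",
    "digest",
    "ligate",
    "load_cargo",
    "fret_state",
    "assembly_yield",
]

log = logging.getLogger(__name__)

Nt = tuple[str, int]
Bond = tuple[str, int]          # backbone bond between index i and i+1
Pair = tuple[Nt, Nt]            # normalized: sorted


class DigestionError(ValueError):
    pass


class StateError(DigestionError):
    """Operation incompatible with the current box state."""


@dataclass(frozen=True)
class Cargo:
    name: str
    size_bp: int = 0
    markers: tuple[str, ...] = ()


@dataclass(frozen=True)
class CutRecord:
    site_id: int
    motif_start: Nt                      # primary reading: (strand, 0-based start)
    breaks: tuple[Bond, ...]
    dissolved: tuple[Pair, ...]
    overhang_seq: str

    @property
    def end_ids(self) -> tuple[int, int]:
        return (2 * self.site_id, 2 * self.site_id + 1)


@dataclass(frozen=True)
class StickyEnd:
    end_id: int
    site_id: int
    nts: tuple[Nt, ...]       # the single-stranded overhang nucleotides
    seq: str
    polarity: str = "5'"


def _norm(a: Nt, b: Nt) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DigestState:
    assembly: Assembly
    broken: frozenset[Bond] = frozenset()
    unpaired: frozenset[Pair] = frozenset()
    cuts: tuple[CutRecord, ...] = ()
    extra_pairs: frozenset[Pair] = frozenset()   # non-original religations
    cargo: Cargo | None = None

    # -- derived views ----------------------------------------------------

    @property
    def box_state(self) -> str:
        sealed = not self.broken and not self.unpaired
        base = "closed" if sealed else "open"
        return base + ("+cargo" if self.cargo is not None else "")

    def active_pairs(self) -> list[Pair]:
        out = [
            _norm(a, b)
            for a, b in self.assembly.pairs
            if _norm(a, b) not in self.unpaired
        ]
        out.extend(sorted(self.extra_pairs))
        return out

    def strand_pieces(self) -> dict[str, str]:
        """Current strand multiset; severed strands appear as named pieces."""
        pieces = {}
        for name, seq in self.assembly.strands.items():
            cuts = sorted(i for (s, i) in self.broken if s == name)
            if not cuts:
                pieces[name] = seq
                continue
            start = 0
            for c in cuts + [len(seq) - 1]:
                pieces[f"{name}[{start + 1}-{c + 1}]"] = seq[start: c + 1]
                start = c + 1
        return pieces

    def piece_of(self, nt: Nt) -> str:
        s, i = nt
        cuts = sorted(j for (n, j) in self.broken if n == s)
        if not cuts:
            return s
        start = 0
        for c in cuts:
            if i <= c:
                return f"{s}[{start + 1}-{c + 1}]"
            start = c + 1
        return f"{s}[{start + 1}-{len(self.assembly.strands[s])}]"

    def fragments(self) -> list[frozenset[str]]:
        """Connected components of the piece/pairing graph, sorted by size."""
        parent: dict[str, str] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[ry] = rx

        for name in self.strand_pieces():
            parent[name] = name
        for a, b in self.active_pairs():
            union(self.piece_of(a), self.piece_of(b))
        groups: dict[str, set[str]] = {}
        for name in parent:
            groups.setdefault(find(name), set()).add(name)
        return sorted(
            (frozenset(g) for g in groups.values()),
            key=lambda g: (sum(len(self.strand_pieces()[p]) for p in g), sorted(g)),
        )

    def fragment_nt(self, frag: frozenset[str]) -> int:
        pieces = self.strand_pieces()
        return sum(len(pieces[p]) for p in frag)

    def sticky_ends(self) -> list[StickyEnd]:
        """Open (unsealed) sticky ends, in end-id order."""
        out = []
        for cut in self.cuts:
            if not any(b in self.broken for b in cut.breaks):
                continue  # resealed
            s, i0 = cut.motif_start
            top, bottom = cut.end_ids
            w = len(cut.overhang_seq)
            # offsets of the overhang relative to the primary reading follow
            # from the dissolved pairs
            scaffold_side = tuple(
                sorted(nt for p in cut.dissolved for nt in p if nt[0] == s)
            )
            partner_side = tuple(
                sorted(nt for p in cut.dissolved for nt in p if nt[0] != s)
            )
            out.append(
                StickyEnd(
                    end_id=top, site_id=cut.site_id, nts=scaffold_side,
                    seq="".join(self.assembly.base(nt) for nt in scaffold_side),
                )
            )
            out.append(
                StickyEnd(
                    end_id=bottom, site_id=cut.site_id, nts=partner_side,
                    seq="".join(self.assembly.base(nt) for nt in partner_side),
                )
            )
        return out


def _as_state(obj) -> DigestState:
    if isinstance(obj, DigestState):
        return obj
    if isinstance(obj, Assembly):
        return DigestState(assembly=obj)
    if isinstance(obj, Design):
        return DigestState(assembly=build_assembly(obj))
    raise DigestionError(f"cannot digest object of type {type(obj).__name__}")


def _find_duplex_sites(state: DigestState, lid: LidSpec):
    """Fully duplex motif occurrences, deduplicated across the two strands.

    Returns ``{site_key: [(strand, start), ...]}`` with readings sorted.
    """
    motif = lid.motif
    w = len(motif)
    pair_map = dict(state.assembly.pair_map)
    for a, b in state.unpaired:
        pair_map.pop(a, None)
        pair_map.pop(b, None)
    def partner_run_ok(partners) -> bool:
        # the complementary bases must stack into one contiguous helix:
        # consecutive partners are backbone-adjacent, or meet at a nick in
        # the bottom strand (two different strands, at least one of them
        # ending there).  Anything else -- e.g. a staple whose sequence
        # happens to read the motif across a crossover onto another duplex
        # -- is not a cuttable site.
        for b1, b2 in zip(partners, partners[1:]):
            if b1[0] == b2[0] and abs(b1[1] - b2[1]) == 1:
                if (b1[0], min(b1[1], b2[1])) in state.broken:
                    return False
                continue
            l1 = len(state.assembly.strands[b1[0]])
            l2 = len(state.assembly.strands[b2[0]])
            if b1[0] != b2[0] and (
                b1[1] in (0, l1 - 1) or b2[1] in (0, l2 - 1)
            ):
                continue
            return False
        return True

    sites: dict[frozenset, list[Nt]] = {}
    for name, seq in state.assembly.strands.items():
        start = seq.find(motif)
        while start >= 0:
            nts = [(name, start + k) for k in range(w)]
            partners = [pair_map.get(nt) for nt in nts]
            if all(p is not None for p in partners) and partner_run_ok(partners):
                # backbone must be intact through the site on this strand
                if not any((name, start + k) in state.broken for k in range(w - 1)):
                    key = frozenset(_norm(nt, p) for nt, p in zip(nts, partners))
                    sites.setdefault(key, []).append((name, start))
            start = seq.find(motif, start + 1)
    return {k: sorted(v) for k, v in sites.items()}


def digest(obj, lid: LidSpec) -> DigestState:
    """Cut every fully duplex motif occurrence at the enzyme's offsets.

    Single-stranded occurrences are left alone.  Re-digesting an already
    digested state is a no-op (cut sites are no longer fully duplex).  The
    box opens as soon as unsealed cut scars exist; whether the cut pieces
    also separate into distinct fragments depends on the design's topology
    and is reported by :meth:`DigestState.fragments`.
    """
    state = _as_state(obj)
    if not state.assembly.pairs:
        raise DigestionError("assembly has no base pairing; assemble the design first")

    sites = _find_duplex_sites(state, lid)
    if not sites:
        return state

    pair_map = state.assembly.pair_map
    broken = set(state.broken)
    unpaired = set(state.unpaired)
    cuts = list(state.cuts)
    next_id = max((c.site_id for c in cuts), default=-1) + 1

    for key in sorted(sites, key=lambda k: sites[k][0]):
        readings = sites[key]
        s, i0 = readings[0]
        new_breaks = set()
        for rs, ri in readings:
            new_breaks.add((rs, ri + lid.cut_offset_top - 1))
        if len(readings) == 1:
            # partner strand is nicked inside the motif; derive its cut bond
            p1 = pair_map[(s, i0 + lid.cut_offset_bottom - 1)]
            p2 = pair_map[(s, i0 + lid.cut_offset_bottom)]
            if p1[0] == p2[0] and abs(p1[1] - p2[1]) == 1:
                new_breaks.add((p1[0], min(p1[1], p2[1])))
        dissolved = tuple(
            sorted(
                _norm((s, i0 + k), pair_map[(s, i0 + k)])
                for k in range(lid.cut_offset_top, lid.cut_offset_bottom)
            )
        )
        overhang = state.assembly.strands[s][
            i0 + lid.cut_offset_top: i0 + lid.cut_offset_bottom
        ]
        broken.update(new_breaks)
        unpaired.update(dissolved)
        cuts.append(
            CutRecord(
                site_id=next_id,
                motif_start=(s, i0),
                breaks=tuple(sorted(new_breaks)),
                dissolved=dissolved,
                overhang_seq=overhang,
            )
        )
        next_id += 1

    new_state = dc_replace(
        state,
        broken=frozenset(broken),
        unpaired=frozenset(unpaired),
        cuts=tuple(cuts),
    )
    log.info(
        "digest: %d site(s) cut, %d fragment(s), box %s",
        len(sites), len(new_state.fragments()), new_state.box_state,
    )
    return new_state


def ligate(state: DigestState, pairing: str = "original") -> DigestState:
    """Reseal complementary sticky ends.

    ``pairing="original"`` (default) rejoins each cut at its original
    junction, restoring the pre-digest strand multiset exactly.  With
    ``pairing="by-end-id"`` ends are matched greedily by ascending end id
    among complementary overhangs; a matched original junction is fully
    resealed, while a non-original match is annealed (overhang base pairs
    formed) without backbone resealing.
    """
    if pairing not in ("original", "by-end-id"):
        raise DigestionError(f"unknown pairing mode {pairing!r}")
    open_ends = state.sticky_ends()
    if not open_ends:
        log.warning("ligate: no compatible sticky ends; state unchanged")
        return state

    broken = set(state.broken)
    unpaired = set(state.unpaired)
    extra = set(state.extra_pairs)

    def reseal(cut: CutRecord):
        for b in cut.breaks:
            broken.discard(b)
        for p in cut.dissolved:
            unpaired.discard(p)

    if pairing == "original":
        for cut in state.cuts:
            if any(b in broken for b in cut.breaks):
                reseal(cut)
    else:
        ends = {e.end_id: e for e in open_ends}
        used = set()
        for eid in sorted(ends):
            if eid in used:
                continue
            e = ends[eid]
            sibling = eid ^ 1
            if sibling in ends and sibling not in used:
                cut = next(c for c in state.cuts if c.site_id == e.site_id)
                reseal(cut)
                used.update((eid, sibling))
                continue
            mate_id = next(
                (
                    fid for fid in sorted(ends)
                    if fid not in used and fid != eid
                    and ends[fid].seq == reverse_complement(e.seq)
                ),
                None,
            )
            if mate_id is None:
                continue
            mate = ends[mate_id]
            for k, nt in enumerate(e.nts):
                extra.add(_norm(nt, mate.nts[len(mate.nts) - 1 - k]))
            used.update((eid, mate_id))

    new_state = dc_replace(
        state,
        broken=frozenset(broken),
        unpaired=frozenset(unpaired),
        extra_pairs=frozenset(extra),
    )
    log.info("ligate: box %s", new_state.box_state)
    return new_state


def load_cargo(state: DigestState, cargo: Cargo) -> DigestState:
    """Record cargo inside an opened box (open -> open+cargo)."""
    if not state.box_state.startswith("open"):
        raise StateError(f"cannot load cargo into a {state.box_state} box")
    if state.cargo is not None:
        raise StateError(f"cargo {state.cargo.name!r} already loaded")
    return dc_replace(state, cargo=cargo)


def fret_state(
    state: DigestState, lid: LidSpec | None = None, threshold_bp: int = 15
) -> dict[int, str]:
    """Per label pair: ``"quenched"`` or ``"emitting"``.

    A pair is quenched iff both members sit in the same fragment of the
    current state AND their design separation (base-pair steps along the
    intact assembly) is within the threshold; otherwise the fluorophore
    emits.  A pair missing its quencher always emits.
    """
    labels = state.assembly.labels
    if not labels:
        raise DigestionError("no labels placed on this design")
    by_pair: dict[int, dict[str, Nt]] = {}
    for lab in labels:
        by_pair.setdefault(lab.pair_id, {})[lab.role] = (lab.strand, lab.index)

    frags = state.fragments()
    frag_of = {p: i for i, fr in enumerate(frags) for p in fr}

    out = {}
    for pid, roles in sorted(by_pair.items()):
        if "fluorophore" not in roles or "quencher" not in roles:
            out[pid] = "emitting"
            continue
        f, q = roles["fluorophore"], roles["quencher"]
        same = frag_of[state.piece_of(f)] == frag_of[state.piece_of(q)]
        sep = separation_bp(state.assembly, f, q)
        out[pid] = "quenched" if (same and 0 <= sep <= threshold_bp) else "emitting"
    return out


def assembly_yield(P: float, k: float, S: float) -> float:
    """Self-assembly yield Y = P / (k x S).

    P: weight of purified scaffold used for assembly; k: purification yield
    fraction (0 < k <= 1); S: starting scaffold weight.
    """
    if not (P > 0 and S > 0):
        raise ValueError("P and S must be positive")
    if not 0 < k <= 1:
        raise ValueError("k must be in (0, 1]")
    return P / (k * S)
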