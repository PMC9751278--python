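"""Seeded synthetic gene generation with forbidden-motif exclusion.

Stands in for an endogenous gene (such as the 1116-nt citrate synthase gene
of *B. subtilis* 168) so designs and tests need no sequence download.  The
generator draws an exact-count base multiset for the requested GC fraction,
shuffles it, then repairs any forbidden-motif hit by count-preserving base
swaps -- so the GC fraction is exact and motif exclusion holds on both
strands, including across the cyclic junction formed when the gene is
tiled end-to-end along a scaffold.
"""

from __future__ import annotations

import numpy as np

from .seqplan import GeneUnit, SequenceError, reverse_complement

__all__ = ["SynthesisError", "synth_gene"]


class SynthesisError(ValueError):
    pass


def _motif_hits(seq: str, motifs: list[str], circular: bool) -> list[tuple[int, int]]:
    """(start, width) of every forbidden hit, both strands, 0-based.

    For circular checks the window may wrap; starts are reported mod len(seq).
    """
    n = len(seq)
    hits = []
    for motif in motifs:
        targets = {motif, reverse_complement(motif)}
        w = len(motif)
        ext = seq + seq[: w - 1] if circular else seq
        for i in range(len(ext) - w + 1):
            if ext[i: i + w] in targets:
                hits.append((i % n, w))
    return hits


def synth_gene(
    length: int,
    gc_fraction: float = 0.44,
    forbidden_motifs=("GGATCC",),
    seed: int = 0,
    circular: bool = True,
    max_repair_rounds: int = 1000,
) -> GeneUnit:
    """Generate a motif-screened random gene of exact length and GC content.

    ``circular=True`` additionally forbids motifs spanning the end-to-start
    junction, which matters when the gene is tiled repeatedly.  Identical
    arguments give identical sequences.
    """
    if length < 21:
        raise SynthesisError(f"length {length} below the 21-nt minimum")
    if not 0.0 <= gc_fraction <= 1.0:
        raise SynthesisError("gc_fraction must lie in [0, 1]")
    motifs = [m.upper() for m in forbidden_motifs]
    for m in motifs:
        if len(m) > length:
            raise SynthesisError(f"motif {m!r} longer than the gene")

    rng = np.random.default_rng(seed)
    n_gc = round(gc_fraction * length)
    n_g = n_gc // 2
    n_c = n_gc - n_g
    n_at = length - n_gc
    n_a = n_at // 2
    n_t = n_at - n_a
    letters = np.array(list("G" * n_g + "C" * n_c + "A" * n_a + "T" * n_t))
    seq = list(rng.permutation(letters))

    for _ in range(max_repair_rounds):
        hits = _motif_hits("".join(seq), motifs, circular)
        if not hits:
            break
        start, w = hits[0]
        # swap one base inside the hit with a different base elsewhere;
        # counts (and hence GC) are preserved
        inside = int(start + rng.integers(w)) % length
        candidates = [
            j for j in range(length)
            if seq[j] != seq[inside] and not any(
                (s <= j < s + ww) or (s + ww > length and j < (s + ww) % length)
                for s, ww in hits
            )
        ]
        if not candidates:
            raise SynthesisError("motif exclusion infeasible at this composition")
        j = candidates[int(rng.integers(len(candidates)))]
        seq[inside], seq[j] = seq[j], seq[inside]
    else:
        raise SynthesisError(
            f"could not purge forbidden motifs in {max_repair_rounds} rounds"
        )

    return GeneUnit(
        id=f"synthetic-gene-L{length}-gc{gc_fraction:g}-seed{seed}",
        sequence="".join(seq),
    )
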