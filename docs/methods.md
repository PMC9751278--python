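# Methods

## The design problem

`endobox` designs wireframe DNA nanostructures in which the scaffold strand
is an *endogenous gene repeated as a multiscaffold* rather than a viral
single strand such as M13mp18.  The workflow follows the DAEDALUS family of
designers: a closed polyhedral mesh is turned into a DX wireframe (each
edge built from two antiparallel duplexes), a spanning tree fixes where the
scaffold double crossovers go, a closed Eulerian circuit routes one
conceptual scaffold strand through every duplex exactly once, and staples
complementary to the scaffold clamp the fold.  On top of that base the
package adds the pieces specific to gene-scaffolded "box" designs:
segmentation of the routed scaffold into gene-copy modules, splitting of
designated modules into main + short strands, substitution of restriction
sites into the short strands to form an enzyme-openable lid, FRET reporter
labels, and a strand-resolution digestion/ligation simulator.

## Edge sizing (the multiple-of-21 rule)

B-form DNA completes one helical turn every ~10.5 bp.  DX arms stay
unstrained when every edge holds a whole number of *double* turns, i.e.
when its length is a multiple of 21 bp.  `size_edges` therefore extends any
requested edge length by the smallest `e >= 0` with `(raw + e) % 21 == 0`.
Lengths produced by rounding `N x 10.5` always close with `e` in
{0, 10, 11}; a remainder of 16 closes with `e = 5`; every other remainder
is closed by the same smallest-extension rule but flagged with a warning,
since such inputs fall outside the usual design workflow.  Rounding of
`N x 10.5` is half-away-from-zero (`round_to_half_turns`), and the rule is
idempotent on its own output.

## Scaffold routing

The spanning tree is a breadth-first tree from vertex 0 with neighbors
visited in ascending index order; the non-tree edges (E - V + 1 of them,
the cycle-space rank) carry the scaffold double crossovers at their
midpoints.  Doubling every mesh edge (two duplexes) makes all vertex
degrees even, so an Eulerian circuit always exists on a connected mesh; it
is built with Hierholzer's algorithm using a fixed tie-break (lowest edge
id, duplex 0 before 1) and rotated so the circuit starts at the 5' end of
duplex 0 of the lowest-id tree edge.  All of this is deterministic:
identical inputs give byte-identical routings.

At each of the 2E vertex transitions the routing inserts a configurable
run of unpaired scaffold nucleotides (default 17 nt) that absorbs corner
geometry.  Global scaffold coordinates are 1-based;
`ScaffoldRouting.locate` and `position_of` are exact inverses.

### The canonical cube configuration

The canonical "gene-box" is a cube with 12 edges of 399 bp (19 double
turns), two duplexes per edge, and 17-nt spacers at all 24 transitions:

    24 x 399 + 24 x 17 = 9984 nt

A spacer-free 12-edge DX cube cannot reach 9984 nt with edges that are
multiples of 21 (9984 / 24 = 416, and 416 % 21 != 0); the 17-nt vertex
spacer is the minimal reconciliation of the two published constraints and
is explicitly configurable, including 0.  Coordinates printed for the
canonical design (site anchors, label positions) are interpreted in this
implementation's frame — the published design's own supplementary
coordinate conventions are not public, so numerical coincidence with them
is not expected and not claimed.

## Staples

The exact staple pattern of the original pipeline is unpublished, so the
package adopts a simple, fully specified rule.  Each 21-bp block of an
edge is split at its 10|11 position; one staple clamps the upper axial
half of both duplexes (11 + 11 = 22 nt), the other the lower half
(10 + 10 = 20 nt), crossing between duplexes at the split — an
antiparallel double crossover per block, with nicks at block boundaries,
maximally far from the crossover.  Both lengths are within 2 nt of
2 x 10.5 and inside the 20–60 nt synthesis window.  Every staple segment
runs antiparallel to the scaffold (footprints are stored in descending
duplex-offset order); every paired scaffold nucleotide is covered by
exactly one staple nucleotide, and spacers stay uncovered — both asserted
at generation time.

Staples are named `V^a_b(k)`: the k-th staple on the edge between vertices
a and b.  A staple is *shared* when its scaffold footprint touches two or
more modules.  Because crossover staples clamp both duplexes of an edge —
regions that can be far apart in global scaffold coordinates — a large
fraction of staples in the canonical build are shared (318 of 456); the
mechanism, not a particular census, is the tested contract.

## Gene tiling, modules, and splits

`plan_modules` tiles the unit gene (canonically 1116 nt) along the routed
total: `cycles = ceil(total / unit)` modules in traversal order, numbered
I, II, …; the last module receives the remainder (1056 nt for the
canonical box) and the surplus (60 nt) is trimmed half from the gene's
upstream and half from its downstream end (an odd surplus removes the
extra nucleotide upstream).  Spacers are scaffold, so they draw their
letters from the same gene cycle.

`split_module_scaffolds` turns designated modules into short strands
(the given windows) plus one contiguous main strand.  The canonical split
windows are design choices constrained by the published strand lengths:
module II sheds four shorts totalling 304 nt (80 + 84 + 60 + 80), leaving
an 812-nt Scaffold-2M; module IX sheds one 22-nt short (Scaffold-9α),
leaving a 1034-nt Scaffold-9M.  Each published site anchor lies inside a
site-bearing short strand; Scaffold-2α carries no site (three sites in
module II plus one in module IX give the published four).

## Lid and labels

Restriction sites are *substituted*, never inserted: printed coordinates
stay valid and strand lengths never change.  `apply_lid` requires the unit
gene to be motif-free on both strands, every anchor to sit inside a short
strand of a split module, and every anchor base to be staple-covered
(duplex).  After substitution the design must contain exactly as many
motif occurrences as anchors.  Fluorophores and quenchers attach to the
staple covering the stated scaffold base; the two members of a pair must
sit on different strands.

`check_pair_geometry` measures pair separation as minimal base-pair steps
on the strand/base-pair graph (backbone step = 1, base-pair rung = 0).
In this implementation's frame the canonical label coordinates measure
1354 and 193 bp — far above the ~13–15 bp an instrument-frame design
would show — because the published label positions presume routing
conventions that are not public.  The FRET mechanism is therefore
exercised on designs whose labels straddle a cut site (see tests), and the
canonical numbers are reported as measured.

## Digestion, ligation, cargo, FRET

The simulator works on a generic assembly: named 5'→3' strands plus a
base-pair map.  Nucleotides are never created or destroyed — a digest
state only records severed backbone bonds and dissolved base pairs, so
conservation holds by construction.

A motif occurrence is cut only when *fully duplex*: all bases paired and
the complementary bases stacked into one contiguous helix (consecutive
partners backbone-adjacent, or meeting at a bottom-strand nick).  The cut
severs the top strand after `cut_offset_top` (G^GATCC for BamHI) and the
bottom strand after `cut_offset_bottom` (CCTAG^G), and dissolves the base
pairs between the two cuts: a 4-bp overhang duplex is not stable, and its
dissociation is what actually severs a duplex.  Single-stranded
occurrences are never cut, and re-digesting a digested state is a no-op.

The box is *open* while unsealed cut scars exist and *closed* otherwise;
cargo loading (a bookkeeping record, not a routed strand) is allowed only
on an open box, and resealing a loaded box yields `closed+cargo`.  Whether
the cut pieces additionally separate into distinct fragments depends on
the design's topology and is reported honestly by the fragment enumerator:
on the canonical box the four cuts shed a ~147-nt lid-region subassembly
plus small scraps, while most of the structure stays connected through the
sister duplexes of the cut edges.  `ligate` reseals original junctions
(restoring the exact pre-digest strand multiset); matching ends by id,
with non-original matches annealed rather than backbone-sealed, is
available behind a flag.

A FRET pair is quenched iff both members are in the same fragment *and*
their design separation is within the threshold (default 15 bp); a pair
missing its quencher always emits.

The self-assembly yield helper implements `Y = P / (k x S)` with P the
purified scaffold weight used for assembly, k the purification yield
fraction, and S the starting scaffold weight.

## Coarse 3D model

One pseudo-atom (phosphate proxy) per nucleotide.  Each edge's duplexes
are parallel B-form helices (defaults: rise 3.4 Å/bp, twist 34.3°/bp,
radius 10 Å, 25 Å center-to-center gap) laid along the mesh edge vector
and centered on it; staple atoms sit 150° around the helix from the
scaffold; spacers interpolate linearly across vertices.  The PDB writer
maps strands to chain ids while the 62 chain characters last and otherwise
falls back to numbered segment identifiers, with the strand-name mapping
carried in REMARK 300 lines so files re-parse to an equal model (0.001 Å).

## Synthetic genes

`synth_gene` emulates a motif-screened endogenous gene: an exact-count
base multiset for the requested GC fraction (default 0.44, typical of a
low-GC Gram-positive genome) is shuffled and any forbidden-motif hit is
repaired by count-preserving swaps, on both strands and across the cyclic
end-to-start junction (the junction matters because the gene is tiled
end-to-end along the scaffold).  GC content is exact by construction;
output is a deterministic function of the arguments.  The generator does
not emulate codon structure, local composition bias, or repeats of a real
gene — tests passing on synthetic genes certify the design arithmetic and
the simulator, not sequence-dependent folding behaviour.

The pipeline re-screens the fully tiled scaffold (which adds the trimmed
module's junction) and redraws the gene from a derived seed in the
astronomically rare case a junction hit appears, with bounded retries.

## Problem sizes and determinism

The canonical build is small by construction — 9984 scaffold nt, 456
staples, ~19.6k pseudo-atoms — and the whole pipeline runs in well under a
second; property suites run on the cube, tetrahedron, and octahedron with
edge lengths up to a few hundred bp.  All randomness flows through
explicit integer seeds; the full pipeline is byte-identical for identical
config + seed.

## Known limitations

- Routing is not sequence-symmetry-aware and does not optimize staple
  thermodynamics (melting temperatures, sequence symmetry) — out of scope.
- The published design's own coordinate frame (its "cube_fork" mesh and
  supplementary strand tables) is not public; printed global coordinates
  are honored as configuration, but face-membership of the four sites and
  instrument-frame label distances are not reproduced in this frame.
- Digestion is all-or-nothing per duplex site; enzyme units, kinetics,
  star activity, and partial digestion are not modeled.
- Cargo encapsulation efficiency and transformation efficiency are
  experimental quantities with no computational counterpart here.
- Meshes must be genus-0, closed, and consistently oriented; reinforced
  (honeycomb/square-lattice) edges are not supported.
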