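# endobox

Design toolkit for wireframe DNA nanostructures whose scaffold is an
**endogenous gene repeated as a multiscaffold** — and for the
restriction-enzyme "can-lid" mechanism that lets such a nanostructure be
opened, loaded with cargo, and resealed.

Classic DNA origami folds one long viral single strand (M13mp18) with
hundreds of staples.  Gene-scaffolded boxes instead tile an organism's own
gene — e.g. the 1116-nt citrate synthase gene of *Bacillus subtilis* 168 —
repeatedly along the routed scaffold of a DX wireframe polyhedron, so the
material is endogenous double-stranded DNA amplifiable by PCR.  `endobox`
is for nucleic-acid nanotechnologists who want to design such structures
and simulate their enzyme-driven opening in silico.

## What it does

- **Mesh geometry** — read/validate/write PLY polyhedra (closed,
  consistently oriented, genus 0), build the canonical cube, and size
  every DX edge to a whole number of B-form double turns: edges are
  extended by the smallest `e` with `(L + e) mod 21 = 0` (10.5 bp/turn,
  so 21 bp per double turn).
- **Scaffold routing** — BFS spanning tree + Hierholzer Eulerian circuit
  through both duplexes of every edge; scaffold double crossovers on the
  non-tree edges; configurable unpaired spacers at vertex transitions;
  exact 1-based global coordinates.
- **Staples** — antiparallel crossover staples per 21-bp block with nicks
  far from crossovers, lengths within 2 nt of n x 10.5 in [20, 60];
  module assignment with inter-module shared-staple flags.
- **Multiscaffold planning** — tile the gene `ceil(total/unit)` times,
  trim the last cycle symmetrically, split designated modules into main +
  short strands (the canonical box: Scaffold-2M 812 nt + four shorts,
  Scaffold-9M 1034 nt + one short).
- **Lid & labels** — screen the gene for the enzyme motif (BamHI,
  5'-GGATCC-3'), substitute the motif into short-strand windows in place,
  attach Cy3/BHQ2 dye pairs to the covering staples, and measure pair
  separations on the duplex/crossover graph.
- **Digestion / ligation / FRET** — strand-resolution simulation: duplex
  sites are cut with 4-nt 5' GATC overhangs, overhang pairs dissolve,
  fragments are enumerated, T4 ligation reseals original junctions
  exactly, cargo loading follows an open -> open+cargo -> closed+cargo
  state machine, and FRET pairs report quenched/emitting.  Includes the
  self-assembly yield formula `Y = P / (k x S)`.
- **Export** — design bundles as JSON, strand FASTA, staple TSV, and a
  coarse-grained PDB model (one pseudo-atom per nucleotide, B-form
  helical geometry).

## Worked example

```python
from endobox import canonical_config, run_pipeline, digest, ligate

bundle = run_pipeline(canonical_config(seed=7))
design = bundle.design

print("scaffold total:", design.routing.total_nt, "nt")
print("modules:", [(m.numeral, m.length) for m in design.msplan.modules])
mod2 = design.msplan.modules[1]
print("module II strands:", [(s.name, s.length) for s in mod2.strands])

state = digest(design, design.lid)
print("cut sites:", len(state.cuts), "| sticky ends:", len(state.sticky_ends()),
      "| box:", state.box_state)
sealed = ligate(state)
print("after T4 ligation:", sealed.box_state)
```

prints

```
scaffold total: 9984 nt
modules: [('I', 1116), ('II', 1116), ('III', 1116), ('IV', 1116), ('V', 1116), ('VI', 1116), ('VII', 1116), ('VIII', 1116), ('IX', 1056)]
module II strands: [('Scaffold-2α', 80), ('Scaffold-2β', 84), ('Scaffold-2γ', 60), ('Scaffold-2δ', 80), ('Scaffold-2M', 812)]
cut sites: 4 | sticky ends: 8 | box: open
after T4 ligation: closed
```

Reading: the cube routes 24 duplexes of 399 bp plus 24 seventeen-nt vertex
spacers (9984 nt); nine gene copies tile it, the ninth trimmed to 1056 nt;
module II is split into four short lid strands plus an 812-nt main strand;
the four BamHI sites all cut, leaving eight GATC sticky ends and an open
box that T4 ligase restores exactly.

The same run is available from a shell:

```sh
endobox design --seed 7 -o design.json
endobox digest design.json
endobox export pdb design.json -o box.pdb
```

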