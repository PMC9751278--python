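"""Gene tiling, module segmentation, splits, and sequence application."""

import pytest

from endobox.mesh import build_cube_mesh, size_edges
from endobox.routing import compute_spanning_tree, route_scaffold
from endobox.seqplan import (
    GeneUnit,
    SequenceError,
    load_gene_fasta,
    plan_modules,
    reverse_complement,
    scaffold_sequence,
    split_module_scaffolds,
)
from endobox.staples import generate_staples
from endobox.synth import synth_gene


def oracle_plan(unit_len, total):
    """Independent arithmetic oracle for module spans and trim."""
    import math

    cycles = math.ceil(total / unit_len)
    spans = [unit_len] * (cycles - 1) + [total - (cycles - 1) * unit_len]
    trim = cycles * unit_len - total
    return spans, trim


class TestPlanModules:
    def test_canonical_nine_modules_and_sixty_trim(self):
        unit = synth_gene(1116, seed=1)
        plan = plan_modules(unit, 9984)
        spans = [m.length for m in plan.modules]
        assert spans == [1116] * 8 + [1056]
        assert plan.trim_upstream_nt + plan.trim_downstream_nt == 60
        assert (plan.trim_upstream_nt, plan.trim_downstream_nt) == (30, 30)

    @pytest.mark.parametrize(
        "unit_len,total", [(100, 100), (100, 250), (21, 100), (50, 449)]
    )
    def test_spans_match_arithmetic_oracle(self, unit_len, total):
        unit = synth_gene(max(unit_len, 21), seed=3)
        unit = GeneUnit("u", unit.sequence[:unit_len]) if unit_len >= 21 else unit
        plan = plan_modules(unit, total)
        spans, trim = oracle_plan(unit.length, total)
        assert [m.length for m in plan.modules] == spans
        assert plan.trim_upstream_nt + plan.trim_downstream_nt == trim
        # partition property: modules tile 1..total contiguously
        pos = 1
        for m in plan.modules:
            assert m.start == pos
            pos = m.end + 1
        assert pos == total + 1

    def test_odd_trim_puts_extra_upstream(self):
        unit = synth_gene(21, seed=0)
        plan = plan_modules(unit, 41)  # trim 1
        assert (plan.trim_upstream_nt, plan.trim_downstream_nt) == (1, 0)

    def test_total_below_unit_rejected(self):
        with pytest.raises(SequenceError):
            plan_modules(synth_gene(100, seed=0), 99)


class TestScaffoldSequence:
    def test_tiling_repeats_the_unit(self):
        unit = synth_gene(21, seed=5)
        plan = plan_modules(unit, 42)
        assert scaffold_sequence(plan, unit) == unit.sequence * 2

    def test_position_1117_restarts_the_gene_cycle(self, canonical_design):
        d = canonical_design
        assert d.unit.length == 1116
        # module II starts a fresh gene copy (lid may have substituted a few
        # bases downstream, position 1117 itself is untouched)
        assert d.scaffold_seq[1116] == d.unit.sequence[0]

    def test_last_module_is_the_symmetrically_trimmed_gene(self, canonical_design):
        d = canonical_design
        mod9 = d.msplan.modules[-1]
        got = d.scaffold_seq[mod9.start - 1: mod9.end]
        want = d.unit.sequence[30:-30]
        # identical except at the module-IX lid anchor (8945..8950)
        masked = {p - mod9.start for p in range(8945, 8951)}
        assert all(
            g == w for i, (g, w) in enumerate(zip(got, want)) if i not in masked
        )
        assert len(got) == len(want) == 1056

    def test_unsplit_module_sequence_equals_gene_cycle(self, canonical_design):
        d = canonical_design
        mod5 = d.msplan.modules[4]
        assert d.scaffold_seq[mod5.start - 1: mod5.end] == d.unit.sequence


class TestStapleComplementarity:
    def test_staples_are_reverse_complements_over_their_footprints(self):
        mesh = build_cube_mesh(13.6)
        plans = size_edges(mesh, 42)
        tree = compute_spanning_tree(mesh)
        routing = route_scaffold(mesh, plans, tree, spacer_nt=4)
        staples = generate_staples(routing, plans)
        unit = synth_gene(routing.total_nt, seed=9)
        from endobox.seqplan import apply_sequences

        design = apply_sequences(
            plan_modules(unit, routing.total_nt), unit, routing, staples, mesh=mesh
        )
        comp = dict(zip("ACGT", "TGCA"))
        for i, rec in enumerate(design.staples.staples):
            seq = design.staple_sequence(i)
            # Watson-Crick complement at every covered position, written
            # 5'->3' against the scaffold (descending offsets per segment)
            for ch, p in zip(seq, rec.footprint):
                assert ch == comp[design.scaffold_seq[p - 1]]
            for seg in rec.segments:
                assert seg.start_offset > seg.end_offset

    def test_complement_involution(self):
        s = "ACGTTGCA"
        assert reverse_complement(reverse_complement(s)) == s


class TestSplits:
    def test_canonical_module_ii_split_gives_812_main(self, canonical_design):
        mod2 = canonical_design.msplan.modules[1]
        assert mod2.main_strand.name == "Scaffold-2M"
        assert mod2.main_strand.length == 812
        assert [s.length for s in mod2.short_strands] == [80, 84, 60, 80]
        assert sum(s.length for s in mod2.strands) == mod2.length

    def test_canonical_module_ix_split_gives_1034_main(self, canonical_design):
        mod9 = canonical_design.msplan.modules[-1]
        assert mod9.main_strand.name == "Scaffold-9M"
        assert mod9.main_strand.length == 1034
        assert [s.length for s in mod9.short_strands] == [22]

    def test_seven_full_length_main_scaffolds(self, canonical_design):
        mains = [
            m.main_strand for m in canonical_design.msplan.modules if not m.is_split
        ]
        assert len(mains) == 7
        assert all(s.length == 1116 for s in mains)

    def test_window_outside_module_rejected(self):
        unit = synth_gene(1116, seed=1)
        plan = plan_modules(unit, 9984)
        with pytest.raises(SequenceError, match="outside"):
            split_module_scaffolds(
                plan, {"II": {"windows": [(500, 600, "x")], "main_name": "m"}}
            )

    def test_overlapping_windows_rejected(self):
        unit = synth_gene(1116, seed=1)
        plan = plan_modules(unit, 9984)
        with pytest.raises(SequenceError, match="overlap"):
            split_module_scaffolds(
                plan,
                {"II": {"windows": [(1117, 1200, "a"), (1190, 1300, "b")],
                        "main_name": "m"}},
            )

    def test_fragmented_remainder_rejected(self):
        unit = synth_gene(1116, seed=1)
        plan = plan_modules(unit, 9984)
        with pytest.raises(SequenceError, match="contiguous"):
            split_module_scaffolds(
                plan, {"II": {"windows": [(1200, 1300, "mid")], "main_name": "m"}}
            )

    def test_split_round_trip_reconstructs_module_sequence(self, canonical_bundle):
        """Merging a split module's strands in coordinate order reproduces the
        gene cycle wherever no lid substitution applies (module IX short
        strand carries the only module-IX substitution)."""
        d = canonical_bundle.design
        mod2 = d.msplan.modules[1]
        merged = "".join(
            d.scaffold_seq[s.start - 1: s.end] for s in mod2.strands
        )
        assert len(merged) == 1116
        # outside the three site anchors the merged sequence is the gene
        anchors = [(s - mod2.start, e - mod2.start) for s, e in
                   d.lid.site_anchors if mod2.start <= s <= mod2.end]
        masked = set()
        for a, b in anchors:
            masked.update(range(a, b + 1))
        same = [merged[i] == d.unit.sequence[i] for i in range(1116)
                if i not in masked]
        assert all(same)


class TestFasta:
    def test_gene_fasta_round_trip(self, tmp_path):
        unit = synth_gene(210, seed=4)
        p = tmp_path / "gene.fa"
        p.write_text(f">{unit.id}\n{unit.sequence}\n")
        again = load_gene_fasta(p)
        assert again == unit

    def test_empty_fasta_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(SequenceError):
            load_gene_fasta(p)

    def test_alphabet_violation_rejected(self):
        with pytest.raises(SequenceError):
            GeneUnit("bad", "ACGTNNNACGTACGTACGTAC")
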