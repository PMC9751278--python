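"""Digestion/ligation state machine, fragment release, FRET, and yield."""

from collections import OrderedDict
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_toy_duplex
from endobox.assembly import Assembly, build_assembly
from endobox.digestion import (
    Cargo,
    DigestState,
    DigestionError,
    StateError,
    assembly_yield,
    digest,
    fret_state,
    ligate,
    load_cargo,
)
from endobox.lid import LidSpec
from endobox.seqplan import reverse_complement


def multi_site_duplex(n_sites):
    """A linear duplex with n motif sites, bottom strand nicked per 21 nt."""
    seg = "ACGTTACCAGTCAGT"  # 15 nt, motif-free, no CCTAGG
    top = (seg + "GGATCC") * n_sites + seg + "ACAGTT"  # trailing full block
    staples = OrderedDict()
    pairs = []
    # bottom strand as 21-nt staples aligned to (seg + site) repeats
    for k in range(0, len(top) // 21):
        window = top[21 * k: 21 * (k + 1)]
        name = f"b{k}"
        staples[name] = reverse_complement(window)
        for i in range(21):
            pairs.append((("top", 21 * k + i), (name, 20 - i)))
    strands = OrderedDict([("top", top)])
    strands.update(staples)
    return Assembly(strands=strands, pairs=tuple(pairs))


class TestDigest:
    def test_toy_duplex_cut_releases_two_fragments(self, toy_duplex):
        asm, lid = toy_duplex
        state = digest(asm, lid)
        assert len(state.cuts) == 1
        frags = state.fragments()
        assert len(frags) == 2
        assert state.box_state == "open"
        ends = state.sticky_ends()
        assert [e.seq for e in ends] == ["GATC", "GATC"]

    def test_design_with_zero_sites_unchanged(self):
        asm = multi_site_duplex(0)
        lid = LidSpec()
        state = digest(asm, lid)
        assert len(state.cuts) == 0
        assert len(state.fragments()) >= 1
        assert state.box_state == "closed"

    def test_single_stranded_motif_not_cut(self):
        # motif present but completely unpaired (plus one unrelated pair so
        # the assembly counts as assembled)
        asm = Assembly(
            strands=OrderedDict(
                [("loop", "TTTTGGATCCTTTTTTTTAAAAAAAA"),
                 ("clamp", "TTTTTTTT")]
            ),
            pairs=tuple((("loop", 18 + i), ("clamp", 7 - i)) for i in range(8)),
        )
        state = digest(asm, LidSpec())
        assert len(state.cuts) == 0

    def test_unassembled_bundle_rejected(self):
        asm = Assembly(strands=OrderedDict([("top", "AAGGATCCTT")]), pairs=())
        with pytest.raises(DigestionError, match="pairing"):
            digest(asm, LidSpec())

    def test_digest_idempotent(self, toy_duplex):
        asm, lid = toy_duplex
        once = digest(asm, lid)
        twice = digest(once, lid)
        assert twice.cuts == once.cuts
        assert twice.broken == once.broken

    def test_canonical_box_cuts_all_four_sites_and_opens(self, canonical_design):
        d = canonical_design
        state = digest(d, d.lid)
        assert len(state.cuts) == 4
        assert len(state.sticky_ends()) == 8
        assert state.box_state == "open"
        # the cuts land on the site-bearing short strands
        cut_strands = {c.motif_start[0] for c in state.cuts}
        assert cut_strands == {
            "Scaffold-2β", "Scaffold-2γ", "Scaffold-2δ", "Scaffold-9α"
        }
        # this frame's lid region sheds sub-assemblies: fragment count grows
        assert len(state.fragments()) > 1

    def test_fragment_count_monotone_under_digest(self, canonical_design):
        d = canonical_design
        before = DigestState(assembly=build_assembly(d))
        after = digest(before, d.lid)
        assert len(after.fragments()) >= len(before.fragments())


class TestLigate:
    def test_digest_then_ligate_is_identity_on_strands(self, toy_duplex):
        asm, lid = toy_duplex
        pristine = DigestState(assembly=asm)
        back = ligate(digest(pristine, lid))
        assert back.strand_pieces() == pristine.strand_pieces()
        assert back.box_state == "closed"
        assert len(back.fragments()) == len(pristine.fragments())

    def test_ligate_on_intact_design_is_noop(self, toy_duplex):
        asm, _lid = toy_duplex
        state = DigestState(assembly=asm)
        assert ligate(state) == state

    def test_partial_state_leaves_junction_open(self, canonical_design):
        d = canonical_design
        state = digest(d, d.lid)
        # drop one cut record: its scar can no longer be resealed
        partial = replace(state, cuts=state.cuts[:-1])
        sealed = ligate(partial)
        assert sealed.box_state == "open"
        assert len(sealed.broken) > 0

    def test_fragment_count_non_increasing_under_ligate(self, canonical_design):
        d = canonical_design
        cut = digest(d, d.lid)
        sealed = ligate(cut)
        assert len(sealed.fragments()) <= len(cut.fragments())

    def test_by_end_id_pairing_reseals_originals(self, toy_duplex):
        asm, lid = toy_duplex
        state = ligate(digest(asm, lid), pairing="by-end-id")
        assert state.box_state == "closed"


class TestConservationProperty:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(n_sites=st.integers(1, 4), reseal=st.booleans())
    def test_nucleotides_conserved_through_digest_ligate(self, n_sites, reseal):
        asm = multi_site_duplex(n_sites)
        lid = LidSpec()
        total = asm.total_nt
        state = digest(asm, lid)
        assert len(state.cuts) == n_sites
        assert sum(len(s) for s in state.strand_pieces().values()) == total
        if reseal:
            state = ligate(state)
            assert sum(len(s) for s in state.strand_pieces().values()) == total
            assert state.strand_pieces() == DigestState(assembly=asm).strand_pieces()


class TestStateMachine:
    def test_open_load_seal_cycle(self, toy_duplex):
        asm, lid = toy_duplex
        opened = digest(asm, lid)
        cargo = Cargo(name="pX461", size_bp=9288, markers=("AmpR", "eGFP"))
        loaded = load_cargo(opened, cargo)
        assert loaded.box_state == "open+cargo"
        sealed = ligate(loaded)
        assert sealed.box_state == "closed+cargo"
        assert sealed.cargo == cargo

    def test_loading_closed_box_rejected(self, toy_duplex):
        asm, _lid = toy_duplex
        closed = DigestState(assembly=asm)
        with pytest.raises(StateError, match="closed"):
            load_cargo(closed, Cargo(name="pCas9", size_bp=9326))

    def test_double_loading_rejected(self, toy_duplex):
        asm, lid = toy_duplex
        opened = load_cargo(digest(asm, lid), Cargo("pY094", 10463))
        with pytest.raises(StateError, match="already"):
            load_cargo(opened, Cargo("pX461", 9288))

    def test_canonical_box_supports_loading(self, canonical_design):
        d = canonical_design
        opened = digest(d, d.lid)
        loaded = load_cargo(opened, Cargo("pX461", 9288, ("AmpR", "eGFP")))
        sealed = ligate(loaded)
        assert sealed.box_state == "closed+cargo"


class TestFret:
    def test_truth_table_on_toy_design(self, toy_duplex):
        """Intact -> quenched; digested -> emitting; resealed -> quenched."""
        asm, lid = toy_duplex
        intact = DigestState(assembly=asm)
        assert fret_state(intact, lid) == {1: "quenched"}
        opened = digest(intact, lid)
        assert fret_state(opened, lid) == {1: "emitting"}
        resealed = ligate(opened)
        assert fret_state(resealed, lid) == {1: "quenched"}

    def test_pair_without_quencher_emits(self):
        asm, lid = make_toy_duplex(with_labels=True)
        lone = replace(
            asm, labels=tuple(l for l in asm.labels if l.role == "fluorophore")
        )
        assert fret_state(DigestState(assembly=lone), lid) == {1: "emitting"}

    def test_no_labels_rejected(self):
        asm, lid = make_toy_duplex(with_labels=False)
        with pytest.raises(DigestionError, match="label"):
            fret_state(DigestState(assembly=asm), lid)

    def test_no_spontaneous_quenching_after_digest(self, canonical_design):
        """An emitting pair can only flip back via fragment reunion."""
        d = canonical_design
        intact = DigestState(assembly=build_assembly(d))
        opened = digest(intact, d.lid)
        before = fret_state(intact, d.lid)
        after = fret_state(opened, d.lid)
        for pid, st_ in after.items():
            if before[pid] == "emitting":
                assert st_ == "emitting"


class TestYield:
    def test_formula(self):
        assert assembly_yield(35, 0.5, 100) == pytest.approx(0.7)

    def test_identity_when_purified_equals_k_times_start(self):
        assert assembly_yield(0.42 * 80, 0.42, 80) == pytest.approx(1.0)

    @pytest.mark.parametrize("P,k,S", [(10, 0, 10), (0, 0.5, 10), (10, 0.5, 0),
                                       (10, -0.1, 10), (10, 1.5, 10)])
    def test_invalid_inputs_rejected(self, P, k, S):
        with pytest.raises(ValueError):
            assembly_yield(P, k, S)
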