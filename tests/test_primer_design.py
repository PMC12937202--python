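import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import nn_tm_reference, wallace_recount
from snap_pcr.diagnostics import build_column_profiles, find_diagnostic_sites
from snap_pcr.primer_design import (
    DesignConfig,
    PanelInfeasibleError,
    Primer,
    PrimerPanel,
    assemble_panel,
    design_species_reverse,
    design_universal_forward,
    dimer_score,
    gc_content,
    panel_from_json,
    panel_from_tsv,
    panel_to_json,
    panel_to_tsv,
    species_consensus,
    tm_nearest_neighbor,
    tm_wallace,
)
from snap_pcr.seqio import SequenceRecord, SpeciesAlignment, revcomp

# Published panel bundled as example data (sequence -> expected Wallace Tm
# recomputed independently in the tests below).
COFORWARD = "AATGTTATTGTGACTGCTCATGC"
R_OST = "AAGAAGGAGGTAGCAACCAG"


class TestGcTm:
    def test_gc_extremes(self):
        assert gc_content("GGCC") == 1.0
        assert gc_content("ATAT") == 0.0

    def test_gc_of_printed_forward(self):
        # count G+C in the 23-mer by an independent recount
        expected = sum(1 for c in COFORWARD if c in "GC") / len(COFORWARD)
        assert gc_content(COFORWARD) == pytest.approx(expected)
        assert gc_content(COFORWARD) == pytest.approx(9 / 23)

    def test_wallace_trivial(self):
        assert tm_wallace("ACGT") == 12
        assert tm_wallace("AAAA") == 8

    def test_wallace_of_printed_reverse(self):
        assert tm_wallace(R_OST) == wallace_recount(R_OST) == 60

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_wallace_matches_recount(self, seq):
        assert tm_wallace(seq) == wallace_recount(seq)

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            gc_content("ACGN")
        with pytest.raises(ValueError):
            tm_wallace("AC-T")


class TestTmNearestNeighbor:
    def test_salt_monotonicity(self):
        seq = "ACGTGCTAGCTAGGCTAACG"
        assert tm_nearest_neighbor(seq, na_mM=100) > tm_nearest_neighbor(seq, na_mM=50)

    def test_gc_rich_above_at_rich(self):
        assert tm_nearest_neighbor("G" * 10) > tm_nearest_neighbor("A" * 10)

    def test_too_short(self):
        with pytest.raises(ValueError):
            tm_nearest_neighbor("ACGTACG")

    def test_agrees_with_reference_implementation(self):
        rng = random.Random(42)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(20))
            assert tm_nearest_neighbor(seq, 50, 250) == pytest.approx(
                nn_tm_reference(seq, 50, 250), abs=0.5
            )


class TestDimerScore:
    def test_full_register_complement(self):
        assert dimer_score("AAAA", "TTTT") == 4

    def test_no_self_pairs(self):
        assert dimer_score("AAAA", "AAAA") == 0

    def test_partial_overlap(self):
        # 3' of p complements 3' of q over 3 bases in one register
        assert dimer_score("GGGAAA", "CCCTTT") >= 3

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=15),
        st.text(alphabet="ACGT", min_size=1, max_size=15),
    )
    def test_symmetric(self, a, b):
        assert dimer_score(a, b) == dimer_score(b, a)


@pytest.fixture
def conserved_aln():
    """Two species, one long shared stretch plus a diagnostic tail."""
    shared = "ATGCATTGACCGTTAGGCATCGATCGTTAGCA"  # 32 conserved columns
    a_tail = "TTTTACGATCGATTGACCAGGCTAACGT"
    b_tail = "TTTTACGATCGATTGACCAGGCTAACGA"  # differs at final column
    return SpeciesAlignment(
        records=(
            SequenceRecord(id="a", residues=shared + a_tail, species="A"),
            SequenceRecord(id="b", residues=shared + b_tail, species="B"),
        )
    )


class TestDesignUniversalForward:
    def test_candidates_lie_inside_windows(self, conserved_aln):
        cfg = DesignConfig(tm_min=40, tm_max=80, gc_min=0.1, gc_max=0.9)
        windows = [(1, 32)]
        cands = design_universal_forward(conserved_aln, windows, cfg)
        assert cands
        for p in cands:
            assert p.orientation == "forward"
            assert 1 <= p.footprint[0] and p.footprint[1] <= 32
            assert p.sequence == conserved_aln.records[0].residues[
                p.footprint[0] - 1 : p.footprint[1]
            ]

    def test_no_window_long_enough(self, conserved_aln):
        cfg = DesignConfig()
        assert design_universal_forward(conserved_aln, [], cfg) == []

    def test_ranking_deterministic(self, conserved_aln):
        cfg = DesignConfig(tm_min=40, tm_max=80, gc_min=0.1, gc_max=0.9)
        a = design_universal_forward(conserved_aln, [(1, 32)], cfg)
        b = design_universal_forward(conserved_aln, [(1, 32)], cfg)
        assert [p.name for p in a] == [p.name for p in b]
        mid = cfg.tm_mid
        devs = [abs(p.tm_wallace - mid) for p in a]
        assert devs == sorted(devs)


class TestDesignSpeciesReverse:
    def test_toy_footprint_and_offsets(self, toy_alignment):
        """Toy target C: anchoring at diagnostic column 4 with length 5 gives
        plus-strand footprint [4,8]; the primer is revcomp of C's consensus
        over those columns, its 3' base complements the allele at column 4,
        and both diagnostic columns (4 and 8) land at offsets 0 and 4."""
        profiles = build_column_profiles(toy_alignment)
        sites = find_diagnostic_sites(profiles, "C")
        cfg = DesignConfig(
            primer_len_min=5, primer_len_max=5,
            tm_min=0, tm_max=100, gc_min=0.0, gc_max=1.0,
        )
        cands = design_species_reverse(toy_alignment, "C", sites, cfg)
        by_footprint = {p.footprint: p for p in cands}
        p = by_footprint[(4, 8)]
        # C's record is ACGCACGA; columns 4..8 = CACGA
        assert p.sequence == revcomp("CACGA") == "TCGTG"
        assert p.diagnostic_offsets == (0, 4)
        # 3' base pairs the target allele at the anchor column 4 (allele C)
        assert p.sequence[-1] == revcomp("C")

    def test_no_sites_no_candidates(self, toy_alignment):
        cfg = DesignConfig()
        assert design_species_reverse(toy_alignment, "C", [], cfg) == []

    def test_all_candidates_3prime_anchored(self, toy_alignment):
        profiles = build_column_profiles(toy_alignment)
        sites = find_diagnostic_sites(profiles, "C")
        cfg = DesignConfig(
            primer_len_min=3, primer_len_max=6,
            tm_min=0, tm_max=100, gc_min=0.0, gc_max=1.0,
        )
        for p in design_species_reverse(toy_alignment, "C", sites, cfg):
            assert 0 in p.diagnostic_offsets
            anchor = p.footprint[0]
            allele = next(s.target_allele for s in sites if s.column == anchor)
            assert p.sequence[-1] == revcomp(allele)


class TestPrimerInvariants:
    def test_footprint_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            Primer(name="x", sequence="ACGT", orientation="forward", footprint=(1, 3))

    def test_reverse_needs_terminal_anchor(self):
        with pytest.raises(ValueError, match="3'-terminal"):
            Primer(
                name="x", sequence="ACGT", orientation="reverse",
                footprint=(1, 4), diagnostic_offsets=(1, 2),
            )


def _mk_rev(name, species, seq, start):
    return Primer(
        name=name, sequence=seq, orientation="reverse", target_species=species,
        footprint=(start, start + len(seq) - 1), tm_wallace=tm_wallace(seq),
        gc=gc_content(seq), diagnostic_offsets=(0,),
    )


def _mk_fwd(seq, start=1):
    return Primer(
        name="F", sequence=seq, orientation="forward",
        footprint=(start, start + len(seq) - 1),
        tm_wallace=tm_wallace(seq), gc=gc_content(seq),
    )


class TestAssemblePanel:
    def test_separation_infeasibility_reported(self):
        cfg = DesignConfig(min_separation=25, min_amplicon=50, max_amplicon=500)
        fwd = _mk_fwd("AAGAAGAAGAAGAAGAAG")
        r1 = _mk_rev("r1", "X", "AAGAAGAAGAAGAAGAAG", 83)   # size 100
        r2 = _mk_rev("r2", "Y", "AAGAAGAAGAAGAAGAAG", 93)   # size 110
        with pytest.raises(PanelInfeasibleError) as exc:
            assemble_panel([fwd], {"X": [r1], "Y": [r2]}, cfg)
        assert exc.value.constraint == "min_separation"

    def test_single_species_single_candidate(self):
        cfg = DesignConfig(min_amplicon=50, max_amplicon=500)
        fwd = _mk_fwd("AAGAAGAAGAAGAAGAAG")
        r1 = _mk_rev("r1", "X", "AAGAAGAAGAAGAAGAAG", 83)
        panel = assemble_panel([fwd], {"X": [r1]}, cfg)
        assert panel.expected_sizes == {"X": 100}

    def test_printed_ladder_separation(self):
        # smallest pairwise difference among the published sizes
        sizes = [162, 227, 275, 307, 527]
        diffs = sorted(
            b - a for i, a in enumerate(sizes) for b in sizes[i + 1 :]
        )
        assert diffs[0] == 32
        PrimerPanel(  # the published ladder satisfies the default separation
            forward=_mk_fwd("AAGAAGAAGAAGAAGAAG"),
            reverses={
                f"s{i}": _mk_rev(f"r{i}", f"s{i}", "AAGAAGAAGAAGAAGAAG", 100 + i)
                for i in range(5)
            },
            expected_sizes={f"s{i}": s for i, s in enumerate(sizes)},
            min_separation=32,
        )

    def test_panel_separation_invariant_enforced(self):
        with pytest.raises(ValueError, match="min_separation"):
            PrimerPanel(
                forward=_mk_fwd("AAGAAGAAGAAGAAGAAG"),
                reverses={
                    "X": _mk_rev("r1", "X", "AAGAAGAAGAAGAAGAAG", 83),
                    "Y": _mk_rev("r2", "Y", "AAGAAGAAGAAGAAGAAG", 93),
                },
                expected_sizes={"X": 100, "Y": 110},
                min_separation=25,
            )


class TestPanelSerialization:
    def _panel(self):
        return PrimerPanel(
            forward=_mk_fwd("AAGAAGAAGAAGAAGAAG"),
            reverses={"X": _mk_rev("r1", "X", "AAGAAGAAGAAGAAGAAG", 83)},
            expected_sizes={"X": 100},
            min_separation=25,
        )

    def test_json_roundtrip(self):
        p = self._panel()
        q = panel_from_json(panel_to_json(p))
        assert q.forward.sequence == p.forward.sequence
        assert q.reverses["X"].footprint == (83, 100)
        assert q.expected_sizes == {"X": 100}

    def test_tsv_roundtrip_sequences(self):
        p = self._panel()
        q = panel_from_tsv(panel_to_tsv(p))
        assert q.forward.sequence == p.forward.sequence
        assert q.reverses["X"].sequence == p.reverses["X"].sequence
        assert q.expected_sizes == {"X": 100}

    def test_bundled_example_panel_loads(self):
        from snap_pcr import example_panel_path

        panel = panel_from_tsv(example_panel_path().read_text())
        assert len(panel.reverses) == 5
        assert sorted(panel.expected_sizes.values()) == [162, 227, 275, 307, 527]
        assert panel.forward.sequence == COFORWARD


class TestSpeciesConsensus:
    def test_majority_and_gap(self):
        aln = SpeciesAlignment(
            records=(
                SequenceRecord(id="a1", residues="ACG-", species="X"),
                SequenceRecord(id="a2", residues="ACT-", species="X"),
                SequenceRecord(id="a3", residues="ACTA", species="X"),
                SequenceRecord(id="b", residues="ACGT", species="Y"),
            )
        )
        assert species_consensus(aln, "X") == "ACT-"
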