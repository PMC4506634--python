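import logging

import numpy as np
import pytest

from mtseq import (
    Alphabet,
    AlphabetError,
    PanelSpec,
    SequenceRecord,
    SharedHit,
    design_antisense,
    exclusivity_filter,
    extend,
    find_multitarget,
    format_gapmer,
    locate_hits,
    shared_cells,
    simulate_panel,
    tile,
    verify_hits,
)
from mtseq.seqio import RegionAnnotation
from _oracle import brute_force_hits, random_instance

MOTIF = "KVLGSGAFGTVYKG"  # a published multitarget kinase peptide


def prot(rid, seq):
    return SequenceRecord(rid, seq, Alphabet.PROTEIN)


class TestTile:
    def test_sliding_all_phases(self):
        cells = tile(prot("p", "ABCDE".replace("B", "C")), 4)  # "ACCDE"
        assert [(c.seq, c.offset) for c in cells] == [("ACCD", 0), ("CCDE", 1)]

    def test_block_mode(self):
        cells = tile(prot("p", "ACCDE"), 4, mode="block")
        assert [(c.seq, c.offset) for c in cells] == [("ACCD", 0)]

    def test_exact_length_single_cell(self, dna):
        cells = tile(dna("ACGTACGTACGT"), 12)
        assert len(cells) == 1 and cells[0].offset == 0

    def test_short_record_warns_empty(self, dna, caplog):
        with caplog.at_level(logging.WARNING):
            assert tile(dna("ACGT"), 12) == []
        assert "shorter" in caplog.text

    def test_ambiguous_cells_skipped(self, dna):
        cells = tile(dna("ACGTNACGTACGTA"), 12)
        # every 12-mer window containing the N is dropped
        assert [c.offset for c in cells] == []
        cells = tile(dna("NACGTACGTACGTA"), 12)
        assert [c.offset for c in cells] == [1, 2]


class TestSharedCells:
    def test_published_peptide_shared_by_three(self):
        targets = [
            prot("T1", MOTIF + "WWWW"),
            prot("T2", "YYYY" + MOTIF),
            prot("T3", MOTIF + "HHHH"),
        ]
        shared = shared_cells(targets, 4)
        expected = {MOTIF[i : i + 4] for i in range(len(MOTIF) - 3)}
        assert expected <= set(shared)
        for w in expected:
            assert {tid for tid, _ in shared[w]} == {"T1", "T2", "T3"}

    def test_no_common_cell_empty(self, dna):
        targets = [dna("A" * 20, "a"), dna("C" * 20, "b")]
        assert shared_cells(targets, 12) == {}

    def test_repeat_in_one_target_counts_once_for_membership(self):
        targets = [prot("T1", "KVLG" + "WWWW" + "KVLG"), prot("T2", "HHKVLGHH")]
        shared = shared_cells(targets, 4)
        occs = shared["KVLG"]
        assert len(occs) == 3
        assert {tid for tid, _ in occs} == {"T1", "T2"}

    def test_min_targets_below_two_rejected(self, dna):
        with pytest.raises(ValueError):
            shared_cells([dna("ACGT" * 5, "a"), dna("ACGT" * 5, "b")], 12, min_targets=1)


class TestExtend:
    def test_seed_grows_to_embedded_motif(self, dna):
        embed = "TTGATGGGGAACTTGG"
        targets = [
            dna("CCCCC" + embed + "AAAAA", "t1"),
            dna("GGGGG" + embed + "CCCCC", "t2"),
            dna(embed + "ACACACAC", "t3"),
        ]
        hit = extend("TGATGGGGAACT", targets)
        assert hit.seq == embed
        assert hit.n_targets == 3

    def test_already_maximal_unchanged(self, dna):
        targets = [dna("AAAACGCGCGCGTTTT", "t1"), dna("CCCCGCGCGCGCAAAA", "t2")]
        hit = extend("CGCGCGCG", targets)
        # flanks disagree between the two targets in both directions
        for tid, off in hit.members:
            assert hit.seq in dict((r.id, r.seq) for r in targets)[tid]

    def test_result_is_maximal(self, dna):
        rng = np.random.default_rng(12)
        motif = "ACGTTGCAGGTCA"
        seqs = {}
        for tid in ("a", "b", "c"):
            flank1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            flank2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            seqs[tid] = flank1 + motif + flank2
        targets = [dna(s, t) for t, s in seqs.items()]
        hit = extend(motif[:12], targets)
        members = {tid for tid, _ in hit.members}
        for c in "ACGT":
            assert not all((c + hit.seq) in seqs[t] for t in members)
            assert not all((hit.seq + c) in seqs[t] for t in members)


class TestExclusivity:
    def _hit(self, seq):
        return SharedHit(seq, (("T1", 0), ("T2", 3)))

    def test_absent_hit_retained_exclusive(self, dna):
        kept = exclusivity_filter([self._hit("KVLG")], [prot("B1", "HHHHWWWW")])
        assert len(kept) == 1 and kept[0].exclusive is True

    def test_present_hit_removed(self):
        kept = exclusivity_filter([self._hit("KVLG")], [prot("B1", "WWKVLGWW")])
        assert kept == []

    def test_empty_background_retains_with_caveat(self, caplog):
        with caplog.at_level(logging.WARNING):
            kept = exclusivity_filter([self._hit("KVLG")], [])
        assert len(kept) == 1 and "unscreened" in caplog.text

    def test_both_strands_screens_reverse_complement(self, dna):
        hit = SharedHit("AACCGGTA", (("T1", 0), ("T2", 0)))
        bg = [dna("TTTACCGGTTTT", "B1")]  # contains revcomp TACCGGTT
        assert exclusivity_filter([hit], bg, both_strands=False)
        assert exclusivity_filter([hit], bg, both_strands=True) == []


class TestGapmerDesign:
    @pytest.mark.parametrize(
        "core,expected",
        [
            ("TTGATGGGGAACTTGG", "+T*+T*+G*A*T*G*G*G*G*A*A*C*T*+T*+G*+G"),
            ("GCCAAGCCAAAGTC", "+G*+C*+C*A*A*G*C*C*A*A*A*+G*+T*+C"),
        ],
    )
    def test_published_renderings(self, core, expected):
        assert format_gapmer(core, 3, 3) == expected

    def test_single_base_no_separators(self):
        assert format_gapmer("A", 0, 0) == "A"

    def test_wings_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            format_gapmer("ACGT", 3, 3)

    def test_stripping_marks_reconstructs_core(self):
        core = "TTGATGGGGAACTTGG"
        rendered = format_gapmer(core, 3, 3)
        assert rendered.replace("+", "").replace("*", "") == core

    def test_antisense_is_reverse_complement_of_hit(self):
        hit = SharedHit("CCAAGTTCCCCATCAA", (("T1", 0), ("T2", 5)))
        design = design_antisense(hit)
        assert design.core == "TTGATGGGGAACTTGG"
        assert design.rendered == "+T*+T*+G*A*T*G*G*G*G*A*A*C*T*+T*+G*+G"
        assert not design.over_length

    def test_over_length_flagged(self, caplog):
        hit = SharedHit("A" * 18, (("T1", 0), ("T2", 0)))
        with caplog.at_level(logging.WARNING):
            design = design_antisense(hit)
        assert design.over_length and "potency" in caplog.text

    def test_palindromic_hit_core_equals_hit(self):
        hit = SharedHit("GGATCC", (("T1", 0), ("T2", 0)))
        assert design_antisense(hit).core == "GGATCC"

    def test_protein_hit_rejected(self):
        with pytest.raises(AlphabetError):
            design_antisense(SharedHit("KVLG", (("T1", 0), ("T2", 0))))


class TestLocateHits:
    def _ann(self):
        return [RegionAnnotation("T1", 200, 1340, 800)]

    def _hits_with_counts(self, n5, nc, n3):
        members = (
            [("T1", 0)] * n5 + [("T1", 300)] * nc + [("T1", 1600)] * n3
        )
        return [SharedHit("ACGTACGTACGT", tuple(members))]

    def test_per_nt_uniform_counts_give_equal_proportions(self):
        loc = locate_hits(self._hits_with_counts(200, 1340, 800), self._ann())
        for region in ("UTR5", "CDS", "UTR3"):
            assert loc.proportions[region] == pytest.approx(1 / 3)

    def test_all_in_3utr(self):
        loc = locate_hits(self._hits_with_counts(0, 0, 8), self._ann())
        assert loc.proportions == pytest.approx({"UTR5": 0.0, "CDS": 0.0, "UTR3": 1.0})

    def test_worked_example_arithmetic(self):
        loc = locate_hits(self._hits_with_counts(5, 13, 40), self._ann())
        rates = (5 / 200, 13 / 1340, 40 / 800)
        total = sum(rates)
        assert loc.per_nt_rate["UTR5"] == pytest.approx(rates[0])
        assert loc.per_nt_rate["CDS"] == pytest.approx(rates[1])
        assert loc.per_nt_rate["UTR3"] == pytest.approx(rates[2])
        assert loc.proportions["UTR5"] == pytest.approx(rates[0] / total)
        assert loc.proportions["CDS"] == pytest.approx(rates[1] / total)
        assert loc.proportions["UTR3"] == pytest.approx(rates[2] / total)

    def test_offset_beyond_annotation_named(self):
        hits = [SharedHit("ACGTACGTACGT", (("T1", 5000),))]
        with pytest.raises(ValueError, match="T1"):
            locate_hits(hits, self._ann())


class TestFindMultitarget:
    def test_planted_exclusive_motif_recovered(self, dna):
        spec = PanelSpec(
            n_targets=10, n_background=6, seq_length=400,
            planted_motifs={"ACGTTGCAGGTCAGGA": ("T1", "T4", "T7", "T9")},
            alphabet=Alphabet.DNA, seed=0,
        )
        targets, background, truth = simulate_panel(spec, seed=101)
        hits = find_multitarget(targets, background)
        assert len(hits) == 1
        assert hits[0].seq == "ACGTTGCAGGTCAGGA"
        assert {tid for tid, _ in hits[0].members} == {"T1", "T4", "T7", "T9"}
        assert hits[0].exclusive is True

    def test_motif_in_background_kills_hit(self, dna):
        motif = "ACGTTGCAGGTCAGGA"
        spec = PanelSpec(
            n_targets=6, n_background=2, seq_length=300,
            planted_motifs={motif: ("T1", "T2", "T3")}, seed=0,
        )
        targets, background, _ = simulate_panel(spec, seed=55)
        spoiled = background + [SequenceRecord("B99", "G" * 100 + motif + "C" * 100)]
        assert find_multitarget(targets, spoiled) == []

    def test_overlapping_target_background_ids_rejected(self, dna):
        t = [dna("ACGT" * 10, "X1"), dna("TGCA" * 10, "X2")]
        with pytest.raises(ValueError, match="disjoint"):
            find_multitarget(t, [dna("ACGT" * 10, "X1")])

    def test_invariant_to_target_order(self):
        rng = np.random.default_rng(77)
        targets, background, cell = random_instance(rng, Alphabet.PROTEIN)
        a = find_multitarget(targets, background, cell_size=cell)
        b = find_multitarget(list(reversed(targets)), background, cell_size=cell)
        assert [(h.seq, h.members) for h in a] == [(h.seq, h.members) for h in b]

    def test_sliding_superset_of_block(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            targets, background, cell = random_instance(rng, Alphabet.DNA)
            sliding = {h.seq for h in find_multitarget(targets, background, cell_size=cell)}
            block = {
                h.seq
                for h in find_multitarget(targets, background, cell_size=cell, mode="block")
            }
            assert block <= sliding

    @pytest.mark.parametrize("alphabet", [Alphabet.DNA, Alphabet.PROTEIN])
    def test_matches_brute_force_oracle(self, alphabet):
        rng = np.random.default_rng(1 if alphabet is Alphabet.DNA else 2)
        for _ in range(8):
            targets, background, cell = random_instance(rng, alphabet)
            hits = find_multitarget(targets, background, cell_size=cell)
            expected = brute_force_hits(targets, background, cell)
            assert {h.seq: h.members for h in hits} == expected
            verify_hits(hits, targets, background)

    def test_two_member_subhit_reported_alongside_broader_hit(self, dna):
        # a core shared by 3 targets plus a longer version shared by only 2
        core = "ACGTTGCAGGTC"
        longer = core + "TTTT"
        targets = [
            dna("CC" + longer + "GGCCAAGGCCAAGG", "t1"),
            dna("AA" + longer + "CCGGTTCCGGTTCC", "t2"),
            dna("GG" + core + "AGAGAGAGAGAGAG", "t3"),
        ]
        hits = find_multitarget(targets, [])
        seqs = {h.seq: h.n_targets for h in hits}
        assert seqs[core] == 3
        assert any(s.startswith(longer) for s in seqs)
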