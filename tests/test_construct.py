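import numpy as np
import pytest

import oracles
from spacerforge import (
    CloningKit,
    GenomeSequence,
    GenomicInterval,
    design_repair_template,
    design_spacer_primers,
    digest,
    generate_genome,
    predict_edited_locus,
    revcomp,
    simulate_gibson,
)
from spacerforge.cli import expected_plasmid
from spacerforge.construct import (
    AmbiguousOverlapError,
    DEFAULT_ENZYMES,
    EnzymeSiteError,
    InsufficientFlankError,
    KitError,
    MissingOverlapError,
    rotations_equal,
)
from spacerforge.seqio import AlphabetError

from conftest import random_spacer


class TestCloningKit:
    def test_toy_kit_invariants(self, kit):
        assert kit.repeat1 != kit.repeat2
        assert len(kit.repeat1) == len(kit.repeat2) == 33
        assert kit.backbone is not None
        for anchor in (kit.repeat1, kit.repeat2, kit.upstream_anneal,
                       kit.downstream_anneal):
            assert kit.backbone.count(anchor) == 1

    def test_identical_repeats_rejected(self):
        with pytest.raises(KitError):
            CloningKit(repeat1="ACGTAC", repeat2="ACGTAC",
                       upstream_anneal="A" * 10, downstream_anneal="C" * 10)

    def test_duplicate_anchor_in_backbone_rejected(self):
        with pytest.raises(KitError):
            CloningKit(repeat1="ACGTAC", repeat2="AGGTAC",
                       upstream_anneal="TTTTTTTTTT", downstream_anneal="CCCCCCCCCC",
                       backbone="TTTTTTTTTT" + "ACGTAC" * 2 + "AGGTAC" + "CCCCCCCCCC"
                                + "CATATGTTCGAA")


class TestSpacerPrimers:
    def test_overhangs_carry_the_spacer(self, kit):
        spacer = "ACGTACGTACGTACGTACGTACGTACGTACGTAC"
        ps = design_spacer_primers(spacer, kit)
        assert spacer in ps.spacer_fwd
        assert revcomp(spacer) in ps.spacer_rev
        assert ps.spacer_fwd.endswith(kit.repeat2)
        assert ps.spacer_rev.endswith(revcomp(kit.repeat1))
        assert ps.fixed_fwd == kit.upstream_anneal
        assert ps.fixed_rev == revcomp(kit.downstream_anneal)

    def test_deterministic(self, kit):
        spacer = "ACGTACGTACGTACGTACGTACGTACGTACGTAC"
        assert design_spacer_primers(spacer, kit) == design_spacer_primers(spacer, kit)

    def test_digestion_site_in_spacer_flagged_not_fatal(self, kit):
        spacer = "TTCGAA" + "ACGTACGTACGTACGTACGTACGTACGT"
        ps = design_spacer_primers(spacer, kit)
        assert any("BstBI" in w for w in ps.warnings)

    def test_ambiguous_or_wrong_length_spacer_rejected(self, kit):
        with pytest.raises(AlphabetError):
            design_spacer_primers("N" * 34, kit)
        with pytest.raises(Exception):
            design_spacer_primers("ACGT", kit)


class TestDigest:
    def test_hand_cut_two_enzymes(self):
        frags = digest("AAACATATGCCCTTCGAAGGG", ["CATATG", "TTCGAA"])
        # cuts at the recognition-site start offsets 3 and 12
        assert frags == ["CATATGCCC", "TTCGAAGGGAAA"]

    def test_single_cutter_linearizes(self):
        frags = digest("AAACATATGCCC", ["CATATG"])
        assert frags == ["CATATGCCCAAA"]

    def test_absent_enzyme_raises(self):
        with pytest.raises(EnzymeSiteError):
            digest("AAACATATGCCC", ["TTCGAA"])

    def test_minus_strand_site_detected(self):
        # BsaI GGTCTC present only as its reverse complement GAGACC
        frags = digest("AAAGAGACCCCCTTTTT", ["GGTCTC"])
        assert len(frags) == 1 and len(frags[0]) == 17

    def test_cut_positions_cover_both_strand_occurrences(self):
        circle = "AAAGGTCTCAAAAGAGACCAAAA"
        frags = digest(circle, ["GGTCTC"])
        assert len(frags) == 2
        assert sum(len(f) for f in frags) == len(circle)


class TestGibson:
    def test_two_fragment_circle(self):
        out = simulate_gibson(["GGGGTTTTAAAA"], ["AAAACCCCGGGG"], 4)
        assert rotations_equal(out, "AAAACCCCGGGGTTTT")

    def test_no_shared_terminus_raises(self):
        with pytest.raises(MissingOverlapError):
            simulate_gibson(["TTTTGGGG"], ["AAAACCCC"], 4)

    def test_ambiguous_junction_raises(self):
        with pytest.raises(AmbiguousOverlapError):
            simulate_gibson(["CCCCTTTT", "CCCCAAAA"], ["AAAACCCC"], 4)

    def test_round_trip_matches_string_surgery(self, kit, rng):
        sites = [kit.enzymes[e] for e in kit.digestion_enzymes]
        for _ in range(25):
            spacer = random_spacer(rng)
            ps = design_spacer_primers(spacer, kit)
            frags = digest(kit.backbone, sites)
            retained = [f for f in frags if kit.upstream_anneal in f]
            assert len(retained) == 1
            assembled = simulate_gibson([ps.fragment_a, ps.fragment_b],
                                        retained, kit.min_overlap)
            assert rotations_equal(assembled, expected_plasmid(kit, spacer))
            # the assembled plasmid carries repeat1+spacer+repeat2 exactly once
            doubled = assembled + assembled
            insert = kit.repeat1 + spacer + kit.repeat2
            assert doubled.count(insert) == 1


class TestRepairTemplate:
    def _genome(self, seed=40, n=10_000):
        return generate_genome(n, gc=0.6, seed=seed, record_id="chr")

    def test_arithmetic_with_cargo(self, rng):
        g = self._genome()
        cargo = random_spacer(rng, length=51)
        d = design_repair_template(g, GenomicInterval("chr", 4000, 6000),
                                   arm_len=1000, cargo=cargo)
        assert d.left_arm == g.seq[3000:4000]
        assert d.right_arm == g.seq[6000:7000]
        assert d.junction_seq == d.left_arm + cargo + d.right_arm
        assert len(d.edited_locus) == 10_000 - 2000 + 51

    def test_pure_deletion(self):
        g = self._genome()
        d = design_repair_template(g, GenomicInterval("chr", 4000, 6000))
        assert d.junction_seq == d.left_arm + d.right_arm
        assert len(d.edited_locus) == 8000

    def test_insufficient_flank_reports_max_feasible(self):
        g = self._genome()
        with pytest.raises(InsufficientFlankError, match="500"):
            design_repair_template(g, GenomicInterval("chr", 500, 6000),
                                   arm_len=1000)

    def test_enzyme_screening_matches_oracle(self, rng):
        g = self._genome(seed=41)
        for start in (2000, 4000, 7000):
            d = design_repair_template(g, GenomicInterval("chr", start, start + 800),
                                       arm_len=600)
            assert list(d.enzyme_violations) == \
                oracles.enzyme_hits(d.junction_seq, dict(DEFAULT_ENZYMES))

    def test_hindiii_site_in_arm_reported(self):
        seq = "G" * 3000 + "AAGCTT" + "G" * 7000
        g = GenomeSequence("chr", seq)
        d = design_repair_template(g, GenomicInterval("chr", 4000, 6000),
                                   arm_len=1000)
        assert ("HindIII", 0) in d.enzyme_violations  # arm starts at offset 3000

    def test_strand_consistency(self, rng):
        g = self._genome(seed=42)
        n = len(g)
        iv = GenomicInterval("chr", 4000, 6000)
        d = design_repair_template(g, iv, arm_len=700)
        grc = GenomeSequence("chr", revcomp(g.seq))
        mirrored = GenomicInterval("chr", n - iv.end, n - iv.start)
        drc = design_repair_template(grc, mirrored, arm_len=700)
        assert drc.junction_seq == revcomp(d.junction_seq)


class TestPredictEditedLocus:
    def test_window_zero_is_the_cargo(self, rng):
        g = generate_genome(10_000, gc=0.6, seed=43, record_id="chr")
        cargo = random_spacer(rng, length=51)
        d = design_repair_template(g, GenomicInterval("chr", 4000, 6000),
                                   cargo=cargo)
        w = predict_edited_locus(g, d, window=0)
        assert w.seq == cargo and not w.truncated

    def test_window_contains_cargo_once_and_slices_back(self, rng):
        g = generate_genome(10_000, gc=0.9, seed=44, record_id="chr")
        cargo = "ATATATATATATATATATATATATATATATATATATATATATATATATATA"[:51]
        d = design_repair_template(g, GenomicInterval("chr", 4000, 6000),
                                   cargo=cargo)
        w = predict_edited_locus(g, d, window=200)
        assert w.seq.count(cargo) == 1
        assert d.edited_locus[w.start:w.end] == w.seq

    def test_oversized_window_truncates_with_flag(self):
        g = generate_genome(5_000, gc=0.6, seed=45, record_id="chr")
        d = design_repair_template(g, GenomicInterval("chr", 2000, 3000),
                                   arm_len=500)
        w = predict_edited_locus(g, d, window=10_000)
        assert w.truncated and w.seq == d.edited_locus
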