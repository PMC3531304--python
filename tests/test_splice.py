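"""Fused-reference construction, spliced alignment and junction checks."""

import numpy as np
import pytest

from _oracles import orf_oracle, spliced_oracle
from chimeraseq._seqs import random_dna, revcomp
from chimeraseq.alignment import Block, spliced_alignment
from chimeraseq.discovery import ChimeraCandidate, Locus
from chimeraseq.formats_io import GenomeStore
from chimeraseq.splice import (
    build_fused_reference,
    check_junction,
    check_reading_frame,
    spliced_align,
    splice_signals,
)


def _candidate(l5, l3, junction_q=4):
    return ChimeraCandidate("m", l5, l3, junction_q, 0)


class TestFusedReference:
    def test_plus_plus_flank_zero_concatenation(self):
        genome = GenomeStore({"c1": "AAAACCCCGGGGTTTT", "c2": "ACGTACGTACGTACGT"})
        cand = _candidate(Locus("c1", "+", 0, 4), Locus("c2", "+", 4, 8))
        fused = build_fused_reference(genome, cand, flank=0)
        assert fused.seq == "AAAA" + "ACGT"
        assert fused.boundary == 4

    def test_minus_strand_segment_reverse_complemented(self):
        genome = GenomeStore({"c1": "AACGTTTT", "c2": "ACGTACGT"})
        cand = _candidate(Locus("c1", "-", 0, 4), Locus("c2", "+", 0, 4))
        fused = build_fused_reference(genome, cand, flank=0)
        assert fused.seq[:4] == revcomp("AACG") == "CGTT"

    def test_coordinate_map_roundtrip(self):
        rng = np.random.default_rng(5)
        genome = GenomeStore({"c1": random_dna(rng, 4000), "c2": random_dna(rng, 4000)})
        cand = _candidate(Locus("c1", "-", 1000, 1600), Locus("c2", "+", 2000, 2500))
        fused = build_fused_reference(genome, cand, flank=100)
        for f in rng.integers(0, len(fused.seq), size=100):
            seg = fused.segments[0] if f < fused.boundary else fused.segments[1]
            g = seg.fused_to_genomic(int(f))
            assert seg.genomic_to_fused(g) == int(f)

    def test_locus_outside_genome_errors(self):
        genome = GenomeStore({"c1": "ACGT" * 100})
        with pytest.raises(ValueError):
            build_fused_reference(genome, _candidate(
                Locus("c1", "+", 0, 4), Locus("c9", "+", 0, 4)))


class TestSplicedAlign:
    def test_planted_two_exon_case(self):
        rng = np.random.default_rng(0)
        eA, eB = random_dna(rng, 120), random_dna(rng, 140)
        target = eA + "GT" + random_dna(rng, 50) + "AG" + eB
        res = spliced_align(eA + eB, target)
        assert res.status == "ok"
        spans = [(b.q_start, b.q_end, b.t_start, b.t_end) for b in res.blocks]
        assert spans == [(0, 120, 0, 120), (120, 260, 174, 314)]

    def test_identity_single_block(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 200)
        res = spliced_align(seq, seq)
        assert len(res.blocks) == 1 and res.blocks[0].length == 200

    def test_matches_bruteforce_oracle_with_mismatch(self):
        rng = np.random.default_rng(2)
        eA, eB = random_dna(rng, 150), random_dna(rng, 150)
        target = eA + random_dna(rng, 60) + eB
        q = list(eA + eB)
        q[77] = {"A": "C"}.get(q[77], "A")
        q = "".join(q)
        res = spliced_align(q, target)
        score, blocks = spliced_oracle(q, target)
        assert res.score == score
        assert [(b.q_start, b.q_end, b.t_start, b.t_end) for b in res.blocks] == blocks

    def test_unalignable_query_fails_not_raises(self):
        res = spliced_align("A" * 100, "C" * 400)
        assert res.status == "failed"

    def test_short_query_precondition(self):
        with pytest.raises(ValueError):
            spliced_align("ACGTACGTACG", "ACGT" * 100, seed_len=12)


class TestCheckJunction:
    FUSED = type("F", (), {"boundary": 500})()

    def _blocks(self, spans):
        return [Block(q0, q1, t0, t1, 0) for q0, q1, t0, t1 in spans]

    def test_precise(self):
        blocks = self._blocks([(0, 403, 50, 453), (403, 800, 600, 997)])
        assert check_junction(blocks, _candidate(None, None, 403), self.FUSED)

    def test_query_gap(self):
        blocks = self._blocks([(0, 400, 50, 450), (405, 800, 600, 995)])
        assert not check_junction(blocks, _candidate(None, None, 403), self.FUSED)

    def test_query_overlap(self):
        blocks = self._blocks([(0, 406, 50, 456), (403, 800, 600, 997)])
        assert not check_junction(blocks, _candidate(None, None, 403), self.FUSED)


class TestSpliceSignals:
    def _fused(self, seq, boundary):
        return type("F", (), {"seq": seq, "boundary": boundary})()

    def test_canonical(self):
        seq = "AAAA" + "GT" + "CCCC" + "AG" + "TTTT"
        fused = self._fused(seq, 8)
        blocks = [Block(0, 4, 0, 4, 0), Block(4, 8, 12, 16, 0)]
        assert splice_signals(fused, blocks) == ("GT", "AG", True, None)

    def test_gc_ag_not_canonical(self):
        seq = "AAAA" + "GC" + "CCCC" + "AG" + "TTTT"
        fused = self._fused(seq, 8)
        blocks = [Block(0, 4, 0, 4, 0), Block(4, 8, 12, 16, 0)]
        donor, acceptor, canonical, _ = splice_signals(fused, blocks)
        assert (donor, acceptor, canonical) == ("GC", "AG", False)

    def test_minus_strand_genomic_ct_ac_reads_canonical(self):
        """A minus-strand partner showing CT..AC on the genomic plus strand
        carries GT..AG after orientation by the fused reference."""
        rng = np.random.default_rng(3)
        exon2, exon1 = random_dna(rng, 60), random_dna(rng, 60)
        plus = exon2 + "CT" + random_dna(rng, 40) + "AC" + exon1
        genome = GenomeStore({"c1": plus, "c2": random_dna(rng, 200)})
        cand = _candidate(Locus("c1", "-", 0, len(plus)), Locus("c2", "+", 0, 100), 120)
        fused = build_fused_reference(genome, cand, flank=0)
        transcript = revcomp(exon1) + revcomp(exon2)
        res = spliced_align(transcript, fused.seq)
        signals = [(fused.seq[b1.t_end:b1.t_end + 2], fused.seq[b2.t_start - 2:b2.t_start])
                   for b1, b2 in zip(res.blocks, res.blocks[1:])]
        assert ("GT", "AG") in signals

    def test_no_context_flag(self):
        fused = self._fused("AAAATTTT", 4)
        blocks = [Block(0, 4, 0, 4, 0), Block(4, 8, 4, 8, 0)]
        donor, acceptor, canonical, flag = splice_signals(fused, blocks)
        assert (donor, acceptor, canonical) == ("NN", "NN", False)
        assert flag == "no-context"


class TestReadingFrame:
    def test_orf_spanning_whole_transcript(self):
        seq = "ATG" + "GCT" * 30 + "TAA"
        assert check_reading_frame(seq, 45)

    def test_stops_before_junction_in_every_frame(self):
        rng = np.random.default_rng(4)
        left = random_dna(rng, 30) + "TAAATAAATAA"
        right = "ATG" + "GCA" * 40 + "TGA"
        seq = left + right
        assert not check_reading_frame(seq, len(left))

    def test_longest_of_two_orfs_decides(self):
        seq = "ATG" + "GCT" * 5 + "TAA" + "ATG" + "GCT" * 40 + "TAA"
        junction = len(seq) // 2
        spans = orf_oracle(seq)
        longest = max(spans, key=lambda s: (s[1] - s[0], -s[0]))
        assert check_reading_frame(seq, junction) == (longest[0] < junction < longest[1])

    def test_agrees_with_sixframe_oracle_on_random_sequences(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            seq = random_dna(rng, 300)
            jq = int(rng.integers(10, 290))
            spans = orf_oracle(seq)
            if not spans:
                expected = False
            else:
                s, e = max(spans, key=lambda x: (x[1] - x[0], -x[0]))
                expected = s < jq < e
            assert check_reading_frame(seq, jq) == expected


class TestVerifyDriver:
    def test_clean_plants_verified_decoys_named(self, pipeline0):
        truth = pipeline0["study"].chimeras.truth
        for v in pipeline0["verified"]:
            label = truth[v.candidate.mrna_id].decoy_label
            if label in (None, "est", "starts"):
                assert v.passed, (v.candidate.mrna_id, v.reason)
                assert v.check.canonical and v.check.donor == "GT" and v.check.acceptor == "AG"
            elif label == "splice":
                assert not v.passed and v.reason == "splice"
                assert v.check.donor == "GC" and v.check.aligned_precisely
            elif label == "frame":
                assert not v.passed and v.reason == "frame"
                assert v.check.canonical and not v.check.frame_ok
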