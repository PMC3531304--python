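"""Read QC, ungapped genome mapping, junction-reference construction,
junction-read calling, validation and coverage."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import hamming_map_oracle
from chimeraseq._seqs import random_dna, revcomp
from chimeraseq.formats_io import GenomeStore, ReadRecord
from chimeraseq.junctions import (
    JunctionHit,
    JunctionParams,
    JunctionRef,
    build_junction_refs,
    call_junction_reads,
    coverage_profile,
    map_genome,
    qc_trim,
    validate_events,
)


def _read(seq, rid="r1", sample="s1", qual=35):
    return ReadRecord(rid, sample, seq, [qual] * len(seq))


class TestQcTrim:
    def test_101nt_right_trimmed_to_76(self):
        read = _read("A" * 101)
        out = qc_trim([read], 76)
        assert len(out) == 1 and out[0].seq == "A" * 76 and len(out[0].qual) == 76

    def test_mean_phred_below_20_removed(self):
        assert qc_trim([_read("ACGT" * 19, qual=19)], 76) == []

    def test_good_76nt_unchanged(self):
        read = _read("ACGT" * 19, qual=30)
        assert qc_trim([read], 76) == [read]

    def test_short_read_removed(self):
        assert qc_trim([_read("A" * 50)], 76) == []

    def test_min_mode(self):
        read = ReadRecord("r", "s", "A" * 76, [35] * 75 + [10])
        assert qc_trim([read], 76, qc_mode="min") == []
        assert qc_trim([read], 76, qc_mode="mean") == [read]


class TestJunctionGeometry:
    def test_paper_parameterisation(self):
        p = JunctionParams(read_length=76, min_overhang=5)
        assert p.ref_length == 142
        assert p.fusion_offset == 71
        assert p.last_start_1based == 67

    def test_49nt_cohort(self):
        p = JunctionParams(read_length=49, min_overhang=5)
        assert p.ref_length == 88 and p.fusion_offset == 44

    def test_read_length_must_exceed_twice_overhang(self):
        with pytest.raises(ValueError):
            JunctionParams(read_length=10, min_overhang=5)

    @given(L=st.integers(20, 150), k=st.integers(1, 10))
    def test_geometry_formulas_hold_for_all_parameterisations(self, L, k):
        if L <= 2 * k:
            return
        p = JunctionParams(read_length=L, min_overhang=k)
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 4 * L)
        refs = build_junction_refs({"e": seq}, {"e": 2 * L}, p)
        assert len(refs[0].seq) == 2 * (L - k)
        assert refs[0].fusion_offset == L - k
        assert p.last_start_1based == L - 2 * k + 1

    def test_toy_chimera(self):
        p = JunctionParams(read_length=4, min_overhang=1)
        refs = build_junction_refs({"e": "AAAACCCC"}, {"e": 4}, p)
        assert refs[0].seq == "AAACCC" and refs[0].fusion_offset == 3

    def test_short_side_clipped_and_flagged(self):
        p = JunctionParams(read_length=76, min_overhang=5)
        refs = build_junction_refs({"e": "A" * 50 + "C" * 200}, {"e": 50}, p)
        assert refs[0].clipped and refs[0].fusion_offset == 50


class TestMapGenome:
    def _genome(self, seed=0, n=30_000):
        rng = np.random.default_rng(seed)
        return GenomeStore({"c1": random_dna(rng, n)}), rng

    def test_verbatim_read_unique(self):
        g, _ = self._genome()
        read = _read(g["c1"][5000:5076])
        assert map_genome([read], g, 2)["r1"].status == "unique"

    def test_two_copy_repeat_multi(self):
        rng = np.random.default_rng(1)
        unit = random_dna(rng, 100)
        g = GenomeStore({"c1": random_dna(rng, 12_000) + unit + random_dna(rng, 5000)
                         + unit + random_dna(rng, 5000)})
        read = _read(unit[10:86])
        assert map_genome([read], g, 2)["r1"].status == "multi"

    def test_junction_spanning_read_unmapped(self):
        """A read crossing a planted trans-junction has no contiguous
        genomic source (checked against the brute-force Hamming oracle)."""
        rng = np.random.default_rng(2)
        g = GenomeStore({"c1": random_dna(rng, 15_000), "c2": random_dna(rng, 15_000)})
        chimera = g["c1"][1000:1400] + g["c2"][5000:5400]
        read = _read(chimera[400 - 40 : 400 + 36])
        res = map_genome([read], g, 2)["r1"]
        assert res.status == "unmapped"
        assert hamming_map_oracle(read.seq, g.sequences, 2) == []

    def test_reverse_strand_hit_found(self):
        g, _ = self._genome(3)
        read = _read(revcomp(g["c1"][8000:8076]))
        res = map_genome([read], g, 2)["r1"]
        assert res.status == "unique" and res.hits[0][2] == "-"

    def test_equals_bruteforce_scan(self):
        rng = np.random.default_rng(4)
        g = GenomeStore({"c1": random_dna(rng, 20_000), "c2": random_dna(rng, 10_000)})
        reads = []
        for i in range(40):
            chrom = "c1" if rng.random() < 0.5 else "c2"
            pos = int(rng.integers(0, len(g[chrom]) - 60))
            s = list(g[chrom][pos : pos + 60])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(60))
                s[p] = "ACGT"[rng.integers(4)]
            reads.append(_read("".join(s), rid=f"r{i}"))
        res = map_genome(reads, g, 2)
        for r in reads:
            assert sorted(res[r.read_id].hits) == hamming_map_oracle(r.seq, g.sequences, 2)

    def test_short_read_fallback_equals_bruteforce(self):
        rng = np.random.default_rng(5)
        g = GenomeStore({"c1": random_dna(rng, 12_000)})
        read = _read(g["c1"][100:130])  # 30 nt < 3 * k, exhaustive path
        res = map_genome([read], g, 1)["r1"]
        assert sorted(res.hits) == hamming_map_oracle(read.seq, g.sequences, 1)


class TestCallJunctionReads:
    P = JunctionParams(read_length=76, min_overhang=5)

    def _refs(self, seed=0, n=1):
        rng = np.random.default_rng(seed)
        return [JunctionRef(f"e{i}", random_dna(rng, 142), 71) for i in range(n)]

    def test_start_67_is_junction_read(self):
        refs = self._refs()
        read = _read(refs[0].seq[66 : 66 + 76])
        hits, shared = call_junction_reads([read], refs, self.P)
        assert hits[0].start_1based == 67 and hits[0].mismatches == 0

    def test_start_68_would_not_fit_window(self):
        refs = self._refs()
        # only 75 nt remain after position 68; stack windows end at 67
        read = _read(refs[0].seq[66 : 66 + 76][1:] + "A")
        hits, _ = call_junction_reads([read], refs, self.P)
        assert all(h.start_1based <= 67 for h in hits)

    def test_start_1_is_junction_read(self):
        refs = self._refs()
        read = _read(refs[0].seq[:76])
        hits, _ = call_junction_reads([read], refs, self.P)
        assert hits[0].start_1based == 1

    def test_mismatch_cap(self):
        refs = self._refs()
        s = list(refs[0].seq[:76])
        for p in (10, 30, 50):
            s[p] = {"A": "C"}.get(s[p], "A")
        hits, _ = call_junction_reads([_read("".join(s))], refs, self.P)
        assert hits == []

    def test_reverse_orientation_called(self):
        refs = self._refs()
        read = _read(revcomp(refs[0].seq[20:96]))
        hits, _ = call_junction_reads([read], refs, self.P)
        assert hits[0].start_1based == 21

    def test_tie_between_refs_flagged_shared(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 142)
        refs = [JunctionRef("e0", seq, 71), JunctionRef("e1", seq, 71)]
        read = _read(seq[10:86])
        hits, shared = call_junction_reads([read], refs, self.P)
        assert hits == [] and shared == [("r1", ("e0", "e1"))]

    def test_clipped_refs_excluded(self):
        refs = [JunctionRef("e0", "A" * 100, 50, clipped=True)]
        assert call_junction_reads([_read("A" * 76)], refs, self.P) == ([], [])


class TestValidateEvents:
    P = JunctionParams()

    def _hits(self, starts_samples):
        return [JunctionHit(f"r{i}", s, "e", st_, 0)
                for i, (st_, s) in enumerate(starts_samples)]

    def test_one_start_one_sample_not_validated(self):
        res = validate_events(self._hits([(10, "s1")] * 3), self.P)
        assert not res["e"].validated

    def test_three_starts_validated(self):
        res = validate_events(self._hits([(10, "s1"), (11, "s1"), (12, "s1")]), self.P)
        assert res["e"].validated

    def test_three_samples_validated(self):
        res = validate_events(self._hits([(10, "s1"), (10, "s2"), (10, "s3")]), self.P)
        assert res["e"].validated

    @given(st.integers(0, 8))
    def test_monotone_in_added_hits(self, extra):
        base = self._hits([(10, "s1"), (11, "s1"), (12, "s1")])
        more = base + [JunctionHit(f"x{i}", "s9", "e", 20 + i, 0) for i in range(extra)]
        assert validate_events(more, self.P)["e"].validated


class TestCoverage:
    P = JunctionParams(read_length=76, min_overhang=5)

    def test_single_read(self):
        counts = coverage_profile([(0, 76)], [], 200, 100, self.P)
        assert counts[:76].sum() == 76 and counts[76:].sum() == 0

    def test_no_reads_all_zero(self):
        assert coverage_profile([], [], 100, 50, self.P).sum() == 0

    def test_junction_hit_projected(self):
        hit = JunctionHit("r", "s", "e", 1, 0)  # ref start 1 -> transcript jq-71
        counts = coverage_profile([], [hit], 400, 200, self.P)
        assert counts[129] == 1 and counts[128] == 0 and counts[204] == 1

    def test_trough_at_junction_under_parent_excess(self):
        """1:5 chimera:parent mixture leaves a coverage trough at the
        junction; the junction-position count matches the binomial
        expectation from chimera reads alone within 3 sd."""
        rng = np.random.default_rng(7)
        tlen, jq, L = 800, 400, 76
        n_chim, n_parent = 200, 1000
        chim_starts = rng.integers(0, tlen - L + 1, n_chim)
        # parent reads share the 5' sequence only; project those fully
        # inside the shared prefix
        parent_starts = rng.integers(0, tlen - L + 1, n_parent)
        parent_iv = [(int(s), int(s) + L) for s in parent_starts if s + L <= jq]
        chim_iv = [(int(s), int(s) + L) for s in chim_starts]
        counts = coverage_profile(chim_iv + parent_iv, [], tlen, jq, self.P)
        p_cov = L / (tlen - L + 1)
        exp_j = n_chim * p_cov
        sd_j = np.sqrt(n_chim * p_cov * (1 - p_cov))
        assert abs(counts[jq] - exp_j) <= 3 * sd_j
        assert counts[jq] < counts[200]  # trough vs parent-covered flank
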