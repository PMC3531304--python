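"""Properties of the synthetic-data generator: determinism, canonical
introns, truth consistency, read and EST planting."""

import numpy as np
import pytest

from chimeraseq._seqs import revcomp
from chimeraseq.discovery import DiscoveryParams, pair_partners
from chimeraseq.est import est_support
from chimeraseq.formats_io import GenomeStore
from chimeraseq.simulate import (
    default_samples,
    make_genome,
    make_region_pairs,
    plant_chimeras,
    plant_genes,
    plant_region_motifs,
    simulate_ests,
    simulate_reads,
    simulate_study,
    CTCF_LIKE_CONSENSUS,
)


class TestMakeGenome:
    def test_deterministic_per_seed(self):
        g1 = make_genome(seed=5)
        g2 = make_genome(seed=5)
        assert g1.sequences == g2.sequences
        assert make_genome(seed=6).sequences != g1.sequences

    def test_gc_zero_gives_at_only(self):
        g = make_genome(n_chrom=1, lengths=[12_000], gc=0.0, seed=0)
        assert set(g[next(iter(g))]) <= {"A", "T"}

    def test_lengths_honoured_exactly(self):
        g = make_genome(n_chrom=2, lengths=[15_000, 11_000], seed=1)
        assert sorted(g.lengths.values()) == [11_000, 15_000]

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            make_genome(n_chrom=1, lengths=[5_000], seed=0)


class TestPlantGenes:
    def test_all_introns_canonical_and_transcripts_rederivable(self):
        genome, genes, beds = plant_genes(make_genome(seed=2), n_genes=6, seed=3)
        for gene, bed in zip(genes, beds):
            for gs, ge in gene.gaps:
                intron = genome[gene.chrom][gs:ge]
                if gene.strand == "-":
                    intron = revcomp(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"
            # independent splice oracle from the BED record
            parts = [genome[bed.chrom][s:e] for s, e in bed.blocks]
            expected = "".join(parts)
            if bed.strand == "-":
                expected = revcomp(expected)
            assert gene.transcript == expected

    def test_minus_strand_transcript_is_reverse_complement_splice(self):
        genome, genes, _ = plant_genes(make_genome(seed=4), n_genes=8, seed=5)
        minus = [g for g in genes if g.strand == "-"]
        assert minus
        g = minus[0]
        spliced_plus = "".join(genome[g.chrom][s:e] for s, e in g.exons)
        assert g.transcript == revcomp(spliced_plus)


class TestPlantChimeras:
    def test_clean_g0_passes_pairing_and_decoys_fail(self):
        genome, chim = plant_chimeras(make_genome(seed=6), seed=7)
        params = DiscoveryParams()
        by_query = {}
        for r in chim.psl_records:
            by_query.setdefault(r.qName, []).append(r)
        cand, reason = pair_partners(by_query["c01"], params)
        assert reason is None and cand.gap_overlap == 0
        # the gap decoy fails exactly the junction-gap rule
        from chimeraseq.discovery import filter_alignments
        kept = filter_alignments(by_query["d_gap"], params)
        assert pair_partners(kept, params) == (None, "gap")

    def test_truth_covers_all_classes_and_orders(self):
        _, chim = plant_chimeras(make_genome(seed=8), seed=9)
        clean = [chim.truth[c] for c in chim.clean_ids]
        assert {t.fusion_class for t in clean} == {
            "inter_chromosomal", "intra_inter_strand", "intra_intra_strand"}
        orders = {t.order_type for t in clean if t.fusion_class == "intra_intra_strand"}
        assert orders == {"partner5_downstream", "nested_3p_in_5p",
                          "nested_5p_in_3p", "colinear_readthrough"}
        labels = {t.decoy_label for t in chim.truth.values() if t.decoy_label}
        assert labels == {"identity", "length", "gap", "splice", "frame", "est", "starts"}

    def test_mitochondrial_partner_present(self):
        _, chim = plant_chimeras(make_genome(seed=10), seed=11)
        assert any(t.partner3.chrom == "chrM" or t.partner5.chrom == "chrM"
                   for t in chim.truth.values())


class TestSimulateReads:
    def _tiny(self, error_rate=0.0, seed=12):
        rng = np.random.default_rng(0)
        from chimeraseq._seqs import random_dna
        seq = random_dna(rng, 600)
        samples = default_samples()[:2]
        abundances = {s.sample_id: {"t": 50} for s in samples}
        return simulate_reads({"t": seq}, samples, abundances,
                              error_rate=error_rate, seed=seed, junctions={"t": 300})

    def test_requested_depth_exact(self):
        reads, _ = self._tiny()
        assert all(len(v) == 50 for v in reads.values())

    def test_deterministic(self):
        r1, t1 = self._tiny()
        r2, t2 = self._tiny()
        assert r1 == r2 and t1 == t2

    def test_truth_window_matches_definition(self):
        reads, truth = self._tiny()
        jq, k = 300, 5
        for (tid, sid), lst in truth.items():
            eff = 76
            for rid, start in lst:
                assert start <= jq - k and start + eff >= jq + k

    def test_junction_read_count_near_binomial_expectation(self):
        rng = np.random.default_rng(0)
        from chimeraseq._seqs import random_dna
        seq = random_dna(rng, 600)
        samples = default_samples()[:1]
        n = 2000
        abundances = {samples[0].sample_id: {"t": n}}
        _, truth = simulate_reads({"t": seq}, samples, abundances, seed=13,
                                  junctions={"t": 300})
        n_j = sum(len(v) for v in truth.values())
        p = 67 / (600 - 76 + 1)  # valid starts / possible starts
        exp, sd = n * p, np.sqrt(n * p * (1 - p))
        assert abs(n_j - exp) <= 3 * sd


class TestSimulateEsts:
    def _run(self, n_spanning):
        rng = np.random.default_rng(1)
        from chimeraseq._seqs import random_dna
        seq = random_dna(rng, 800)
        ests, truth = simulate_ests({"c": seq}, {"c": 400}, n_spanning=n_spanning,
                                    n_non_spanning=2, seed=14)
        support, _ = est_support({"c": seq}, {"c": 400}, ests)
        return support["c"], truth["c"]

    def test_three_spanning_supported(self):
        sup, _ = self._run(3)
        assert sup.supported and sup.n_spanning == 3

    def test_two_spanning_unsupported(self):
        sup, _ = self._run(2)
        assert not sup.supported

    def test_non_spanning_never_counted(self):
        sup, (spanning, non_spanning) = self._run(3)
        assert not (set(non_spanning) & set(sup.spanning_est_ids))


class TestPlantRegionMotifs:
    def test_fraction_one_all_planted_and_offsets_exact(self):
        pairs = make_region_pairs(10, 600, seed=15)
        pairs, offsets = plant_region_motifs(pairs, fraction=1.0, seed=16,
                                             max_mismatches=0)
        w = len(CTCF_LIKE_CONSENSUS)
        assert len(offsets) == 10
        for p in pairs:
            o5, o3 = offsets[p.chimera_id]
            assert p.seq5[o5:o5 + w] == CTCF_LIKE_CONSENSUS
            assert p.seq3[o3:o3 + w] == CTCF_LIKE_CONSENSUS

    def test_fraction_zero_is_decoy_set(self):
        pairs = make_region_pairs(5, 600, seed=17)
        _, offsets = plant_region_motifs(pairs, fraction=0.0, seed=18)
        assert offsets == {}

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            plant_region_motifs([], motif_consensus="ACGT", seed=0)


class TestStudyDeterminism:
    def test_same_seed_identical_outputs(self):
        a = simulate_study(seed=21, error_rate=0.001, mean_reads=20,
                           n_background_genes=2)
        b = simulate_study(seed=21, error_rate=0.001, mean_reads=20,
                           n_background_genes=2)
        assert a.genome.sequences == b.genome.sequences
        assert a.chimeras.chimera_seqs == b.chimeras.chimera_seqs
        assert a.chimeras.psl_records == b.chimeras.psl_records
        assert a.reads == b.reads
        assert a.ests == b.ests
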