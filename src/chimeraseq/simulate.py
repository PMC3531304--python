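"""Seeded, truth-annotated synthetic data for the whole pipeline.

The generator emulates the study design the pipeline targets: a
multi-chromosome genome (one large chromosome hosting a distant colinear
gene pair, plus a small mitochondrion-like chromosome), multi-exon genes
whose introns all carry GT..AG boundaries on the transcribed strand,
planted chimeric mRNAs of every fusion class and intra-strand ordering
type, decoy candidates each violating exactly one downstream filter,
single-end read cohorts (eleven "liver" individuals, five male and six
female, three of them sequenced at 101 nt to exercise right-trimming to
76 nt; three "muscle" breed pools at 49 nt), EST fragments spanning or
deliberately missing fusion junctions, and a CTCF-like consensus planted
into paired upstream regions.

Every operation is deterministic given its seed, and a
:class:`SimulatedStudy` carries the complete truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seqs import random_dna, revcomp
from .discovery import Locus
from .formats_io import (
    AlignmentRecord,
    Bed12Record,
    GenomeStore,
    Pfm,
    ReadRecord,
)
from .motifs import RegionPair

__all__ = [
    "GeneModel",
    "ChimeraTruth",
    "ChimeraSet",
    "SampleSpec",
    "SimulatedStudy",
    "CTCF_LIKE_CONSENSUS",
    "make_genome",
    "plant_genes",
    "plant_chimeras",
    "default_classes_spec",
    "default_samples",
    "draw_abundances",
    "simulate_reads",
    "simulate_ests",
    "make_region_pairs",
    "plant_region_motifs",
    "default_pfm_library",
    "simulate_study",
]

#: CTCF-like zinc-finger consensus used as the planted shared motif (19 nt)
CTCF_LIKE_CONSENSUS = "TGGCCACCAGGGGGCGCTA"

_DEFAULT_CHROMS = {"chr1": 300_000, "chr2": 200_000, "chr3": 1_500_000, "chrM": 16_000}
_MARGIN = 3_000
_SPACING = 4_500
_READTHROUGH_SEPARATION = 1_100_000
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Genome scaffolding


class _Builder:
    """Mutable genome wrapper used while planting features."""

    def __init__(self, genome: GenomeStore) -> None:
        self.seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    def get(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end].decode()

    def write(self, chrom: str, pos: int, seq: str) -> None:
        self.seqs[chrom][pos : pos + len(seq)] = seq.encode()

    def finalize(self) -> GenomeStore:
        return GenomeStore({c: b.decode() for c, b in self.seqs.items()})


@dataclass
class GeneModel:
    """A planted multi-exon gene; exon blocks ascend genomically."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcript: str = ""

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def gaps(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def transcription_positions(self) -> list[int]:
        """Genomic position of every transcript base, in transcription order."""
        if self.strand == "+":
            return [p for s, e in self.exons for p in range(s, e)]
        return [p for s, e in reversed(self.exons) for p in range(e - 1, s - 1, -1)]

    def derive_transcript(self, builder: _Builder) -> str:
        parts = [builder.get(self.chrom, s, e) for s, e in self.exons]
        seq = "".join(parts)
        self.transcript = revcomp(seq) if self.strand == "-" else seq
        return self.transcript

    def prefix_blocks(self, n_tx_exons: int) -> list[tuple[int, int]]:
        """Genomic blocks of the first ``n_tx_exons`` transcribed exons."""
        if self.strand == "+":
            return self.exons[:n_tx_exons]
        return self.exons[len(self.exons) - n_tx_exons :]

    def suffix_blocks(self, n_tx_exons: int) -> list[tuple[int, int]]:
        if self.strand == "+":
            return self.exons[len(self.exons) - n_tx_exons :]
        return self.exons[:n_tx_exons]


def _set_intron_signal(
    builder: _Builder, gene: GeneModel, tx_intron_idx: int, donor: str = "GT", acceptor: str = "AG"
) -> None:
    """Write donor/acceptor dinucleotides of a transcription-order intron."""
    gaps = gene.gaps
    gap_idx = tx_intron_idx if gene.strand == "+" else len(gaps) - 1 - tx_intron_idx
    gs, ge = gaps[gap_idx]
    if gene.strand == "+":
        builder.write(gene.chrom, gs, donor)
        builder.write(gene.chrom, ge - 2, acceptor)
    else:
        builder.write(gene.chrom, ge - 2, revcomp(donor))
        builder.write(gene.chrom, gs, revcomp(acceptor))


def _edit_gap_base(
    builder: _Builder, gene: GeneModel, tx_intron_idx: int, offset: int, base: str
) -> None:
    """Write one base inside a transcription-order intron.

    ``offset`` is in transcribed orientation: >= 0 counts from the donor
    end, negative from the acceptor end (-1 is the last intron base).
    """
    gaps = gene.gaps
    gap_idx = tx_intron_idx if gene.strand == "+" else len(gaps) - 1 - tx_intron_idx
    gs, ge = gaps[gap_idx]
    t = offset if offset >= 0 else (ge - gs) + offset
    if gene.strand == "+":
        builder.write(gene.chrom, gs + t, base)
    else:
        builder.write(gene.chrom, ge - 1 - t, _COMP[base])


def _plant_gene(
    builder: _Builder,
    name: str,
    chrom: str,
    strand: str,
    start: int,
    exon_sizes: list[int],
    intron_sizes: list[int],
) -> GeneModel:
    exons = []
    pos = start
    for i, size in enumerate(exon_sizes):
        exons.append((pos, pos + size))
        pos += size
        if i < len(intron_sizes):
            pos += intron_sizes[i]
    gene = GeneModel(name, chrom, strand, exons)
    for i in range(len(intron_sizes)):
        _set_intron_signal(builder, gene, i)
    return gene


class _Allocator:
    def __init__(self, lengths: dict[str, int], avoid: list[GeneModel] | None = None) -> None:
        self.lengths = lengths
        self.cursors = {c: _MARGIN for c in lengths}
        for g in avoid or []:
            self.cursors[g.chrom] = max(self.cursors[g.chrom], g.end + _SPACING)

    def alloc(self, chrom: str, span: int) -> int:
        start = self.cursors[chrom]
        if start + span > self.lengths[chrom] - _MARGIN:
            raise ValueError(f"gene placement failed on {chrom}")
        self.cursors[chrom] = start + span + _SPACING
        return start

    def reserve(self, chrom: str, end: int) -> None:
        self.cursors[chrom] = max(self.cursors[chrom], end + _SPACING)


def make_genome(
    n_chrom: int = 4,
    lengths: list[int] | None = None,
    gc: float = 0.42,
    seed: int = 0,
    names: list[str] | None = None,
) -> GenomeStore:
    """Random i.i.d. genome; deterministic per seed; lengths must be >= 10 kb."""
    if lengths is None:
        pairs = list(_DEFAULT_CHROMS.items())[:n_chrom]
    else:
        names = names or [f"chr{i + 1}" for i in range(n_chrom)]
        pairs = list(zip(names, lengths))
    if len(pairs) != n_chrom:
        raise ValueError("lengths/names disagree with n_chrom")
    if any(n < 10_000 for _, n in pairs):
        raise ValueError("chromosome lengths must be at least 10 kb")
    rng = np.random.default_rng(seed)
    return GenomeStore({name: random_dna(rng, n, gc) for name, n in pairs})


def plant_genes(
    genome: GenomeStore,
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int = 0,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
) -> tuple[GenomeStore, list[GeneModel], list[Bed12Record]]:
    """Plant background multi-exon genes with canonical GT..AG introns."""
    rng = np.random.default_rng(seed)
    builder = _Builder(genome)
    alloc = _Allocator(genome.lengths)
    genes = []
    for i in range(n_genes):
        exon_sizes = [int(rng.integers(180, 260)) for _ in range(exons_per_gene)]
        intron_sizes = [int(rng.integers(120, 180)) for _ in range(exons_per_gene - 1)]
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        span = sum(exon_sizes) + sum(intron_sizes)
        start = alloc.alloc(chrom, span)
        genes.append(_plant_gene(builder, f"gene{i:02d}", chrom, strand, start, exon_sizes, intron_sizes))
    for g in genes:
        g.derive_transcript(builder)
    return builder.finalize(), genes, [_gene_bed(g) for g in genes]


def _gene_bed(gene: GeneModel) -> Bed12Record:
    return Bed12Record(
        chrom=gene.chrom,
        start=gene.start,
        end=gene.end,
        name=gene.name,
        strand=gene.strand,
        block_sizes=[e - s for s, e in gene.exons],
        block_starts=[s - gene.start for s, e in gene.exons],
    )


# ---------------------------------------------------------------------------
# Chimera planting


@dataclass
class ChimeraTruth:
    chimera_id: str
    decoy_label: str | None  # None for clean plants
    fusion_class: str
    order_type: str
    junction_q: int
    gap_overlap: int
    canonical: bool | None
    partner5: Locus
    partner3: Locus
    motif_offsets: tuple[int, int] | None = None


@dataclass
class ChimeraSet:
    chimera_seqs: dict[str, str]
    junctions: dict[str, int]
    psl_records: list[AlignmentRecord]
    truth: dict[str, ChimeraTruth]
    partner_genes: dict[str, tuple[GeneModel, GeneModel]]
    bed_records: list[Bed12Record]

    @property
    def clean_ids(self) -> list[str]:
        return sorted(c for c, t in self.truth.items() if t.decoy_label is None)

    @property
    def decoy_ids(self) -> list[str]:
        return sorted(c for c, t in self.truth.items() if t.decoy_label is not None)


def default_classes_spec() -> list[dict]:
    """The default study conditions: 20 clean chimeras covering every
    fusion class and intra-strand ordering type (in roughly the skewed
    proportions real intra-strand events show), plus 7 decoys violating
    one filter each."""
    spec: list[dict] = []
    inter = [("chr1", "+", "chr2", "+"), ("chr1", "+", "chr2", "-"),
             ("chr1", "-", "chr2", "+"), ("chr1", "-", "chr2", "-"),
             ("chr1", "+", "chrM", "+")]
    for i, (ca, sa, cb, sb) in enumerate(inter):
        spec.append({"name": f"c{i + 1:02d}", "class": "inter_chromosomal",
                     "A": (ca, sa), "B": (cb, sb)})
    strands = [("+", "-"), ("-", "+"), ("+", "-"), ("-", "+"), ("+", "-"), ("-", "+")]
    for i, (sa, sb) in enumerate(strands):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        spec.append({"name": f"c{i + 6:02d}", "class": "intra_inter_strand",
                     "A": (chrom, sa), "B": (chrom, sb)})
    for i in range(5):
        strand = "-" if i == 4 else "+"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        spec.append({"name": f"c{i + 12:02d}", "class": "intra_intra_strand",
                     "order": "partner5_downstream", "A": (chrom, strand), "B": (chrom, strand)})
    spec.append({"name": "c17", "class": "intra_intra_strand", "order": "nested_3p_in_5p",
                 "A": ("chr1", "+"), "B": ("chr1", "+")})
    spec.append({"name": "c18", "class": "intra_intra_strand", "order": "nested_3p_in_5p",
                 "A": ("chr2", "-"), "B": ("chr2", "-")})
    spec.append({"name": "c19", "class": "intra_intra_strand", "order": "nested_5p_in_3p",
                 "A": ("chr1", "+"), "B": ("chr1", "+")})
    spec.append({"name": "c20", "class": "intra_intra_strand", "order": "colinear_readthrough",
                 "A": ("chr3", "+"), "B": ("chr3", "+")})
    decoys = [("identity", "inter_chromosomal", ("chr1", "+"), ("chr2", "+")),
              ("length", "inter_chromosomal", ("chr2", "+"), ("chr1", "+")),
              ("gap", "intra_inter_strand", ("chr1", "+"), ("chr1", "-")),
              ("splice", "intra_inter_strand", ("chr2", "+"), ("chr2", "-")),
              ("frame", "inter_chromosomal", ("chr1", "-"), ("chr2", "+")),
              ("est", "intra_inter_strand", ("chr1", "-"), ("chr1", "+")),
              ("starts", "inter_chromosomal", ("chr2", "-"), ("chr1", "+"))]
    for label, cls, a, b in decoys:
        spec.append({"name": f"d_{label}", "class": cls, "A": a, "B": b, "decoy": label})
    return spec


def _plant_orf(get, set_base, start: int, end: int) -> None:
    """Open a reading frame at ``start`` and scrub in-frame stops up to ``end``.

    Rewriting a stop codon's third base to C (TAA->TAC, TAG->TAC, TGA->TGC)
    never creates a new stop.
    """
    set_base(start, "A")
    set_base(start + 1, "T")
    set_base(start + 2, "G")
    for p in range(start + 3, end - 2, 3):
        if get(p) + get(p + 1) + get(p + 2) in _STOPS:
            set_base(p + 2, "C")


def plant_chimeras(
    genome: GenomeStore,
    classes_spec: list[dict] | None = None,
    seed: int = 0,
    avoid: list[GeneModel] | None = None,
) -> tuple[GenomeStore, ChimeraSet]:
    """Plant one dedicated partner-gene pair per requested chimera.

    Clean chimeras take the first two transcribed exons of gene A and the
    last two of gene B, joining at an exon boundary so the trans-junction
    inherits a GT donor from A and an AG acceptor from B.  A long open
    reading frame is written across the junction so the frame check holds,
    and the transcript bases adjacent to the junction are fixed so the
    spliced alignment cannot slide the junction by one base.  Decoys are
    identical except for their single programmed violation.
    """
    rng = np.random.default_rng(seed)
    spec = classes_spec if classes_spec is not None else default_classes_spec()
    builder = _Builder(genome)
    alloc = _Allocator(genome.lengths, avoid=avoid)

    chimera_seqs: dict[str, str] = {}
    junctions: dict[str, int] = {}
    psl: list[AlignmentRecord] = []
    truth: dict[str, ChimeraTruth] = {}
    partner_genes: dict[str, tuple[GeneModel, GeneModel]] = {}
    all_genes: list[GeneModel] = []

    for entry in spec:
        name = entry["name"]
        cls = entry["class"]
        order = entry.get("order", "not_applicable")
        label = entry.get("decoy")
        (chrom_a, strand_a), (chrom_b, strand_b) = entry["A"], entry["B"]

        exon_a = [int(rng.integers(200, 241)) for _ in range(3)]
        exon_b = [int(rng.integers(200, 241)) for _ in range(3)]
        intron_a, intron_b = [150, 150], [150, 150]
        emb_exons = [150, 150, 150]
        emb_introns = [60, 60]

        if order == "nested_3p_in_5p":
            big = 0 if strand_a == "+" else 1
            intron_a = [1500, 150] if big == 0 else [150, 1500]
            span_a = sum(exon_a) + sum(intron_a)
            start_a = alloc.alloc(chrom_a, span_a)
            gene_a = _plant_gene(builder, f"{name}.A", chrom_a, strand_a, start_a, exon_a, intron_a)
            gs, _ = gene_a.gaps[big]
            gene_b = _plant_gene(builder, f"{name}.B", chrom_b, strand_b, gs + 200,
                                 emb_exons, emb_introns)
        elif order == "nested_5p_in_3p":
            intron_b = [150, 1500]
            span_b = sum(exon_b) + sum(intron_b)
            start_b = alloc.alloc(chrom_b, span_b)
            gene_b = _plant_gene(builder, f"{name}.B", chrom_b, strand_b, start_b, exon_b, intron_b)
            gs, _ = gene_b.gaps[1]
            gene_a = _plant_gene(builder, f"{name}.A", chrom_a, strand_a, gs + 200,
                                 emb_exons, emb_introns)
        elif order == "colinear_readthrough":
            start_a = alloc.alloc(chrom_a, sum(exon_a) + sum(intron_a))
            gene_a = _plant_gene(builder, f"{name}.A", chrom_a, strand_a, start_a, exon_a, intron_a)
            start_b = gene_a.end + _READTHROUGH_SEPARATION
            gene_b = _plant_gene(builder, f"{name}.B", chrom_b, strand_b, start_b, exon_b, intron_b)
            alloc.reserve(chrom_b, gene_b.end)
        elif order == "partner5_downstream":
            # 5' partner downstream of the 3' partner in transcription direction
            if strand_a == "+":
                start_b = alloc.alloc(chrom_b, sum(exon_b) + sum(intron_b))
                gene_b = _plant_gene(builder, f"{name}.B", chrom_b, strand_b, start_b, exon_b, intron_b)
                start_a = alloc.alloc(chrom_a, sum(exon_a) + sum(intron_a))
                gene_a = _plant_gene(builder, f"{name}.A", chrom_a, strand_a, start_a, exon_a, intron_a)
            else:
                start_a = alloc.alloc(chrom_a, sum(exon_a) + sum(intron_a))
                gene_a = _plant_gene(builder, f"{name}.A", chrom_a, strand_a, start_a, exon_a, intron_a)
                start_b = alloc.alloc(chrom_b, sum(exon_b) + sum(intron_b))
                gene_b = _plant_gene(builder, f"{name}.B", chrom_b, strand_b, start_b, exon_b, intron_b)
        else:
            start_a = alloc.alloc(chrom_a, sum(exon_a) + sum(intron_a))
            gene_a = _plant_gene(builder, f"{name}.A", chrom_a, strand_a, start_a, exon_a, intron_a)
            start_b = alloc.alloc(chrom_b, sum(exon_b) + sum(intron_b))
            gene_b = _plant_gene(builder, f"{name}.B", chrom_b, strand_b, start_b, exon_b, intron_b)
        all_genes.extend([gene_a, gene_b])

        n5 = n3 = 2  # transcribed exons contributed by each partner
        pos_a = gene_a.transcription_positions()
        pos_b = gene_b.transcription_positions()
        exa = [e - s for s, e in gene_a.prefix_blocks(n5)]
        exb = [e - s for s, e in gene_b.suffix_blocks(n3)]
        prefix_len = sum(exa)
        suffix_len = sum(exb)
        jq = prefix_len if label != "length" else 99

        def get_base(t: int) -> str:
            if t < jq:
                g = pos_a[t]
                base = builder.get(gene_a.chrom, g, g + 1)
                return base if gene_a.strand == "+" else _COMP[base]
            g = pos_b[len(pos_b) - suffix_len + (t - jq)]
            base = builder.get(gene_b.chrom, g, g + 1)
            return base if gene_b.strand == "+" else _COMP[base]

        def set_base(t: int, base: str) -> None:
            if t < jq:
                g, gene = pos_a[t], gene_a
            else:
                g, gene = pos_b[len(pos_b) - suffix_len + (t - jq)], gene_b
            builder.write(gene.chrom, g, base if gene.strand == "+" else _COMP[base])

        total = jq + suffix_len
        if label in (None, "splice", "frame", "est", "starts"):
            set_base(jq, "C")  # junction-slide guard on the 3' side
            if label == "frame":
                stops = "TAAATAAATAA"  # in-frame stop in all three frames
                for i, ch in enumerate(stops):
                    set_base(jq - 11 + i, ch)
                _plant_orf(get_base, set_base, jq + 3, total - 3)
            else:
                set_base(jq - 1, "C")  # guard on the 5' side
                _plant_orf(get_base, set_base, 3, total - 3)
            if label == "splice":
                _set_intron_signal(builder, gene_a, n5 - 1, donor="GC")
            # Junction reads must come from no contiguous genomic locus even
            # at the minimal 5 nt overhang.  The junction-slide guards already
            # force one mismatch against each partner's intron edge; editing
            # the free intron bases beyond the GT/AG signals forces three
            # more on each side, so an ungapped <=2-mismatch genome mapping
            # across the junction is impossible.
            def _other(b: str) -> str:
                return "A" if b != "A" else "C"

            for i in range(2, 5):  # vs the donor-side continuation in gene A
                _edit_gap_base(builder, gene_a, n5 - 1, i, _other(get_base(jq + i)))
            for i in range(3, 6):  # vs the acceptor-side continuation in gene B
                _edit_gap_base(builder, gene_b, 0, -i, _other(get_base(jq - i)))

        gene_a.derive_transcript(builder)
        gene_b.derive_transcript(builder)
        prefix = gene_a.transcript[:jq]
        suffix = gene_b.transcript[len(gene_b.transcript) - suffix_len :]
        insert = random_dna(rng, 11) if label == "gap" else ""
        seq = prefix + insert + suffix
        qsize = len(seq)
        q3_start = jq + len(insert)

        tsize_a = len(genome[chrom_a])
        tsize_b = len(genome[chrom_b])
        if label == "length":
            block = gene_a.prefix_blocks(1)[0]
            blocks5 = [(block[0], block[0] + 99)] if strand_a == "+" else [(block[1] - 99, block[1])]
        else:
            blocks5 = gene_a.prefix_blocks(n5)
        rec5 = _psl_record(name, qsize, 0, jq, gene_a, blocks5, tsize_a,
                           mismatches=22 if label == "identity" else 0)
        rec3 = _psl_record(name, qsize, q3_start, qsize, gene_b, gene_b.suffix_blocks(n3), tsize_b)
        psl.extend([rec5, rec3])

        locus5 = Locus(gene_a.chrom, gene_a.strand, blocks5[0][0], blocks5[-1][1])
        b3 = gene_b.suffix_blocks(n3)
        locus3 = Locus(gene_b.chrom, gene_b.strand, b3[0][0], b3[-1][1])
        canonical: bool | None
        if label in ("identity", "length", "gap"):
            canonical = None
        else:
            canonical = label != "splice"
        chimera_seqs[name] = seq
        junctions[name] = jq
        truth[name] = ChimeraTruth(
            chimera_id=name,
            decoy_label=label,
            fusion_class=cls,
            order_type=order if cls == "intra_intra_strand" else "not_applicable",
            junction_q=jq,
            gap_overlap=len(insert),
            canonical=canonical,
            partner5=locus5,
            partner3=locus3,
        )
        partner_genes[name] = (gene_a, gene_b)

    bed = [_gene_bed(g) for g in all_genes]
    return builder.finalize(), ChimeraSet(chimera_seqs, junctions, psl, truth, partner_genes, bed)


def _psl_record(
    qname: str,
    qsize: int,
    qstart: int,
    qend: int,
    gene: GeneModel,
    blocks: list[tuple[int, int]],
    tsize: int,
    mismatches: int = 0,
) -> AlignmentRecord:
    sizes = [e - s for s, e in blocks]
    if sum(sizes) != qend - qstart:
        raise ValueError("blocks disagree with query span")
    if gene.strand == "+":
        qstarts, cur = [], qstart
        for sz in sizes:
            qstarts.append(cur)
            cur += sz
    else:
        qstarts = []
        for i, sz in enumerate(sizes):
            plus_end = qstart + sum(sizes[i + 1 :]) + sz
            qstarts.append(qsize - plus_end)
    rec = AlignmentRecord(
        qName=qname,
        qSize=qsize,
        qStart=qstart,
        qEnd=qend,
        tName=gene.chrom,
        tSize=tsize,
        tStart=blocks[0][0],
        tEnd=blocks[-1][1],
        strand=gene.strand,
        blockSizes=sizes,
        qStarts=qstarts,
        tStarts=[s for s, _ in blocks],
        matches=(qend - qstart) - mismatches,
        mismatches=mismatches,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Read and EST simulation


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str  # male/female or breed name
    cohort: str  # liver | muscle
    raw_length: int
    trimmed_length: int


def default_samples() -> list[SampleSpec]:
    """The default cohort: 11 liver individuals (5 male, 6 female; three
    sequenced at 101 nt) and 3 muscle breed pools at 49 nt."""
    samples = []
    for i in range(1, 12):
        group = "male" if i <= 5 else "female"
        raw = 101 if i >= 9 else 76
        samples.append(SampleSpec(f"liver{i:02d}", group, "liver", raw, 76))
    for i, breed in enumerate(["wuzhishan", "tongcheng", "landrace"], start=1):
        samples.append(SampleSpec(f"muscle{i:02d}", breed, "muscle", 49, 49))
    return samples


def draw_abundances(
    transcript_ids: list[str],
    samples: list[SampleSpec],
    seed: int = 0,
    mean_reads: float = 120.0,
    cv_by_cohort: dict[str, float] | None = None,
) -> dict[str, dict[str, int]]:
    """Per-sample read counts with log-normal across-sample dispersion.

    The log-normal sigma per cohort is chosen so the programmed CV of
    counts across samples matches the cohort target (57% liver, 35%
    muscle by default).
    """
    cv_by_cohort = cv_by_cohort or {"liver": 0.57, "muscle": 0.35}
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, int]] = {}
    for sample in samples:
        sigma = math.sqrt(math.log(1 + cv_by_cohort[sample.cohort] ** 2))
        counts = {}
        for tid in sorted(transcript_ids):
            mult = math.exp(rng.normal(-sigma**2 / 2, sigma))
            counts[tid] = max(1, int(round(mean_reads * mult)))
        out[sample.sample_id] = counts
    return out


def simulate_reads(
    transcripts: dict[str, str],
    samples: list[SampleSpec],
    abundances: dict[str, dict[str, int]],
    error_rate: float = 0.0,
    seed: int = 0,
    junctions: dict[str, int] | None = None,
    min_overhang: int = 5,
    forced_junction_plan: dict[str, list[tuple[str, int]]] | None = None,
    avoid_window_ids: set[str] | None = None,
) -> tuple[dict[str, list[ReadRecord]], dict[tuple[str, str], list[tuple[str, int]]]]:
    """Uniform-start single-end reads with substitution errors.

    Per (sample, transcript) exactly the requested number of reads is
    produced.  The truth table records, per (transcript, sample), every
    read whose post-trim span overlaps the fusion point by at least
    ``min_overhang`` on both sides.  Transcripts in ``avoid_window_ids``
    have their random read starts rejection-sampled out of the junction
    window; ``forced_junction_plan`` adds reads at exact transcript starts
    (used to program under-validated decoys).
    """
    rng = np.random.default_rng(seed)
    junctions = junctions or {}
    avoid_window_ids = avoid_window_ids or set()
    forced_junction_plan = forced_junction_plan or {}
    bases = np.array(list("ACGT"))
    reads: dict[str, list[ReadRecord]] = {s.sample_id: [] for s in samples}
    truth: dict[tuple[str, str], list[tuple[str, int]]] = {}

    def emit(sample: SampleSpec, tid: str, start: int, idx: int) -> None:
        L = sample.raw_length
        frag = list(transcripts[tid][start : start + L])
        if error_rate > 0:
            errs = np.nonzero(rng.random(L) < error_rate)[0]
            for p in errs:
                choices = [b for b in "ACGT" if b != frag[p]]
                frag[p] = choices[rng.integers(3)]
        qual = [int(q) for q in rng.integers(33, 41, size=L)]
        read_id = f"{sample.sample_id}.{tid}.{idx}"
        reads[sample.sample_id].append(ReadRecord(read_id, sample.sample_id, "".join(frag), qual))
        if tid in junctions:
            jq, eff = junctions[tid], sample.trimmed_length
            if jq + min_overhang - eff <= start <= jq - min_overhang:
                truth.setdefault((tid, sample.sample_id), []).append((read_id, start))

    for sample in samples:
        plan = abundances.get(sample.sample_id, {})
        for tid in sorted(plan):
            L = sample.raw_length
            tlen = len(transcripts[tid])
            if tlen < L:
                raise ValueError(f"transcript {tid} shorter than read length {L}")
            jq = junctions.get(tid)
            lo = hi = None
            if jq is not None:
                lo, hi = jq + min_overhang - sample.trimmed_length, jq - min_overhang
            for idx in range(plan[tid]):
                while True:
                    start = int(rng.integers(0, tlen - L + 1))
                    if tid in avoid_window_ids and lo is not None and lo <= start <= hi:
                        continue
                    break
                emit(sample, tid, start, idx)
            for fidx, (sid, start) in enumerate(forced_junction_plan.get(tid, [])):
                if sid == sample.sample_id:
                    emit(sample, tid, start, 10_000 + fidx)
    return reads, truth


def simulate_ests(
    chimeras: dict[str, str],
    junctions: dict[str, int],
    n_spanning: int = 4,
    n_non_spanning: int = 2,
    seed: int = 0,
    min_flank: int = 20,
    spanning_overrides: dict[str, int] | None = None,
) -> tuple[dict[str, str], dict[str, tuple[list[str], list[str]]]]:
    """EST fragments per chimera: spanning ones cover >= ``min_flank`` nt
    on both sides of the junction, non-spanning ones stop short of the
    right flank.  Half the fragments are emitted reverse-complemented
    (ESTs are unstranded)."""
    rng = np.random.default_rng(seed)
    overrides = spanning_overrides or {}
    ests: dict[str, str] = {}
    truth: dict[str, tuple[list[str], list[str]]] = {}
    for tid in sorted(chimeras):
        seq, jq = chimeras[tid], junctions[tid]
        spanning, non_spanning = [], []
        for i in range(overrides.get(tid, n_spanning)):
            a = max(0, jq - min_flank - int(rng.integers(20, 120)))
            b = min(len(seq), jq + min_flank + int(rng.integers(20, 120)))
            frag = seq[a:b]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            est_id = f"est.{tid}.sp{i}"
            ests[est_id] = frag
            spanning.append(est_id)
        for i in range(n_non_spanning):
            a = max(0, jq - 150 - int(rng.integers(0, 60)))
            b = jq + int(rng.integers(0, min_flank))  # < min_flank on the 3' side
            frag = seq[a:b]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            est_id = f"est.{tid}.ns{i}"
            ests[est_id] = frag
            non_spanning.append(est_id)
        truth[tid] = (spanning, non_spanning)
    return ests, truth


# ---------------------------------------------------------------------------
# Motif planting


def make_region_pairs(n: int, length: int = 1000, seed: int = 0, gc: float = 0.42) -> list[RegionPair]:
    """Random upstream/upstream region pairs for standalone motif studies."""
    rng = np.random.default_rng(seed)
    return [
        RegionPair(f"pair{i:02d}", "upstream", "upstream",
                   random_dna(rng, length, gc), random_dna(rng, length, gc))
        for i in range(n)
    ]


def _mutated_site(consensus: str, rng: np.random.Generator, max_mismatches: int = 1) -> str:
    """Consensus with at most one substitution, placed in the outer four
    positions of either end (motif cores are the conserved part, so edge
    positions carry the variability)."""
    site = list(consensus)
    if max_mismatches >= 1 and rng.random() < 0.8:
        w = len(consensus)
        edge = [*range(4), *range(w - 4, w)]
        p = edge[int(rng.integers(len(edge)))]
        site[p] = [b for b in "ACGT" if b != site[p]][int(rng.integers(3))]
    return "".join(site)


def plant_region_motifs(
    region_pairs: list[RegionPair],
    motif_consensus: str = CTCF_LIKE_CONSENSUS,
    fraction: float = 1.0,
    seed: int = 0,
    max_mismatches: int = 1,
) -> tuple[list[RegionPair], dict[str, tuple[int, int]]]:
    """Insert the consensus (<= 1 mismatch per site) into both members of
    the chosen fraction of pairs; returns the pairs and truth offsets."""
    if not (10 <= len(motif_consensus) <= 30):
        raise ValueError("consensus width must be in [10, 30]")
    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(region_pairs)))
    offsets: dict[str, tuple[int, int]] = {}
    w = len(motif_consensus)
    for pair in region_pairs[:n_plant]:
        o5 = int(rng.integers(0, len(pair.seq5) - w + 1))
        o3 = int(rng.integers(0, len(pair.seq3) - w + 1))
        pair.seq5 = pair.seq5[:o5] + _mutated_site(motif_consensus, rng, max_mismatches) + pair.seq5[o5 + w :]
        pair.seq3 = pair.seq3[:o3] + _mutated_site(motif_consensus, rng, max_mismatches) + pair.seq3[o3 + w :]
        offsets[pair.chimera_id] = (o5, o3)
    return region_pairs, offsets


def default_pfm_library(seed: int = 0, counts_per_column: int = 20) -> list[Pfm]:
    """Small synthetic PFM library (stand-in for a curated TFBS
    collection): one CTCF-like profile built from the planted consensus
    plus unrelated synthetic profiles."""
    consensi = {
        "SYN_CTCF": CTCF_LIKE_CONSENSUS,
        "SYN_TATA": "CTATAAAAGGCG",
        "SYN_CAAT": "AGCCAATCAGAG",
        "SYN_GC": "TGGGCGGGGCTT",
        "SYN_EBOX": "AACAGCTGTTCC",
        "SYN_AT": "TTATTTTAATTTAA",
    }
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pfms = []
    for motif_id, cons in consensi.items():
        counts = np.full((4, len(cons)), 1.0)
        for col, base in enumerate(cons):
            counts[base_idx[base], col] = counts_per_column - 3
        pfms.append(Pfm(motif_id, counts))
    return pfms


# ---------------------------------------------------------------------------
# Full-study orchestration


@dataclass
class SimulatedStudy:
    genome: GenomeStore
    background_genes: list[GeneModel]
    chimeras: ChimeraSet
    samples: list[SampleSpec]
    abundances: dict[str, dict[str, int]]
    reads: dict[str, list[ReadRecord]]
    read_truth: dict[tuple[str, str], list[tuple[str, int]]]
    ests: dict[str, str]
    est_truth: dict[str, tuple[list[str], list[str]]]
    bed_records: list[Bed12Record] = field(default_factory=list)


def _plant_upstream_motifs(
    genome: GenomeStore,
    chimeras: ChimeraSet,
    fraction: float = 0.5,
    seed: int = 0,
    up_window: int = 2000,
) -> GenomeStore:
    """Write the CTCF-like consensus into the upstream windows of both
    partners for a fraction of the clean chimeras (truth offsets recorded
    on the chimera set, in transcription-direction coordinates)."""
    rng = np.random.default_rng(seed)
    builder = _Builder(genome)
    w = len(CTCF_LIKE_CONSENSUS)
    clean = chimeras.clean_ids
    chosen = clean[: int(round(fraction * len(clean)))]
    for cid in chosen:
        t = chimeras.truth[cid]
        offs = []
        for locus in (t.partner5, t.partner3):
            off = int(rng.integers(200, up_window - w - 200))
            site = _mutated_site(CTCF_LIKE_CONSENSUS, rng)
            if locus.strand == "+":
                g_lo = locus.start - up_window
                builder.write(locus.chrom, g_lo + off, site)
            else:
                g_hi = locus.end + up_window
                builder.write(locus.chrom, g_hi - off - w, revcomp(site))
            offs.append(off)
        t.motif_offsets = (offs[0], offs[1])
    return builder.finalize()


def simulate_study(
    seed: int = 0,
    error_rate: float = 0.005,
    mean_reads: float = 120.0,
    n_background_genes: int = 6,
    plant_motifs: bool = True,
) -> SimulatedStudy:
    """Generate the full default study with truth annotations.

    Clean chimeras plus the ``est`` and ``starts`` decoys are expressed;
    the ``starts`` decoy's junction reads are pinned to two start
    positions in two samples so it fails read validation and nothing
    else.
    """
    genome = make_genome(seed=seed)
    genome, bg_genes, bg_bed = plant_genes(genome, n_background_genes, seed=seed + 1)
    genome, chim = plant_chimeras(genome, seed=seed + 2, avoid=bg_genes)
    if plant_motifs:
        genome = _plant_upstream_motifs(genome, chim, seed=seed + 3)

    samples = default_samples()
    expressed = chim.clean_ids + ["d_est", "d_starts"]
    abundances = draw_abundances(expressed, samples, seed=seed + 4, mean_reads=mean_reads)
    jq = chim.junctions["d_starts"]
    forced = {
        "d_starts": [
            ("liver01", jq - 40), ("liver01", jq - 30),
            ("liver02", jq - 40), ("liver02", jq - 30),
        ]
    }
    reads, read_truth = simulate_reads(
        chim.chimera_seqs,
        samples,
        abundances,
        error_rate=error_rate,
        seed=seed + 5,
        junctions=chim.junctions,
        forced_junction_plan=forced,
        avoid_window_ids={"d_starts"},
    )
    ests, est_truth = simulate_ests(
        chim.chimera_seqs, chim.junctions, seed=seed + 6, spanning_overrides={"d_est": 2}
    )
    return SimulatedStudy(
        genome=genome,
        background_genes=bg_genes,
        chimeras=chim,
        samples=samples,
        abundances=abundances,
        reads=reads,
        read_truth=read_truth,
        ests=ests,
        est_truth=est_truth,
        bed_records=bg_bed + chim.bed_records,
    )
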