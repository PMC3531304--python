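"""Trans-splice verification of chimera candidates.

For each candidate the genomic regions of the 5' and 3' partners (each
with flanking context, each in transcribed orientation) are joined into an
artificially fused reference.  The chimeric mRNA is then spliced-aligned
to that reference; a verified fusion point must

* align precisely — one exon block ends exactly at the fusion transcript
  coordinate and the next begins there, with the two blocks on opposite
  sides of the artificial join (no query gap or overlap);
* show the canonical GT/AG (GU-AG on the RNA) donor/acceptor dinucleotides
  in the genomic gap at the junction, read on the transcribed strand;
* preserve reading-frame integrity, operationalised as: the longest open
  reading frame of the chimera spans the fusion point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seqs import longest_orf, revcomp
from .alignment import Block, spliced_alignment
from .discovery import ChimeraCandidate, Locus
from .formats_io import GenomeStore

__all__ = [
    "FusedReference",
    "SpliceCheck",
    "SplicedResult",
    "build_fused_reference",
    "spliced_align",
    "check_junction",
    "splice_signals",
    "cis_splice_signals",
    "check_reading_frame",
    "verify_candidates",
    "VerifiedCandidate",
]


@dataclass
class _Segment:
    """Strictly monotone, invertible map between one fused-reference
    interval and its genomic source interval."""

    chrom: str
    strand: str
    g_start: int
    g_end: int
    f_start: int
    f_end: int

    def fused_to_genomic(self, f: int) -> int:
        if not (self.f_start <= f < self.f_end):
            raise ValueError("position outside segment")
        off = f - self.f_start
        if self.strand == "+":
            return self.g_start + off
        return self.g_end - 1 - off

    def genomic_to_fused(self, g: int) -> int:
        if not (self.g_start <= g < self.g_end):
            raise ValueError("position outside segment")
        if self.strand == "+":
            return self.f_start + (g - self.g_start)
        return self.f_start + (self.g_end - 1 - g)


@dataclass
class FusedReference:
    seq: str
    boundary: int  # offset of the artificial join = length of the 5' segment
    segments: tuple[_Segment, _Segment]

    def fused_to_genomic(self, f: int) -> tuple[str, int]:
        seg = self.segments[0] if f < self.boundary else self.segments[1]
        return seg.chrom, seg.fused_to_genomic(f)


@dataclass
class SplicedResult:
    status: str  # "ok" or "failed"
    score: int
    blocks: list[Block]
    q_aligned_fraction: float


@dataclass
class SpliceCheck:
    aligned_precisely: bool
    donor: str
    acceptor: str
    canonical: bool
    frame_ok: bool
    status: str = "ok"
    flags: list[str] = field(default_factory=list)


def _extract_segment(genome: GenomeStore, locus: Locus, flank: int, f_start: int) -> tuple[str, _Segment]:
    if locus.chrom not in genome:
        raise ValueError(f"locus chromosome {locus.chrom!r} not in genome")
    chrom_len = len(genome[locus.chrom])
    if not (0 <= locus.start < locus.end <= chrom_len):
        raise ValueError(f"locus outside genome: {locus.chrom}:{locus.start}-{locus.end}")
    g_start = max(0, locus.start - flank)
    g_end = min(chrom_len, locus.end + flank)
    seq = genome[locus.chrom][g_start:g_end]
    if locus.strand == "-":
        seq = revcomp(seq)
    seg = _Segment(locus.chrom, locus.strand, g_start, g_end, f_start, f_start + len(seq))
    return seq, seg


def build_fused_reference(
    genome: GenomeStore, candidate: ChimeraCandidate, flank: int = 500
) -> FusedReference:
    """Join the partner regions (each plus ``flank`` nt of context, clipped
    at chromosome edges) into one 5'->3' reference in transcript
    orientation; minus-strand partners are reverse-complemented."""
    seq5, seg5 = _extract_segment(genome, candidate.partner5, flank, 0)
    seq3, seg3 = _extract_segment(genome, candidate.partner3, flank, len(seq5))
    return FusedReference(seq=seq5 + seq3, boundary=len(seq5), segments=(seg5, seg3))


def spliced_align(
    mrna_seq: str,
    fused_ref: FusedReference | str,
    min_intron: int = 30,
    seed_len: int = 12,
    max_block_mismatch_rate: float = 0.04,
) -> SplicedResult:
    """Align a chimeric mRNA to its fused reference.

    The alignment fails (candidate unverifiable, no exception) when less
    than half the query aligns or any exon block exceeds the mismatch-rate
    tolerance, mirroring the >= 96% identity regime of discovery.
    """
    if len(mrna_seq) < 2 * seed_len:
        raise ValueError(f"mRNA shorter than 2 x seed_len = {2 * seed_len}")
    target = fused_ref.seq if isinstance(fused_ref, FusedReference) else fused_ref
    score, blocks = spliced_alignment(mrna_seq, target, min_intron=min_intron)
    aligned = sum(b.length for b in blocks)
    frac = aligned / len(mrna_seq)
    status = "ok"
    if frac < 0.5:
        status = "failed"
    elif any(b.mismatch_rate > max_block_mismatch_rate for b in blocks):
        status = "failed"
    return SplicedResult(status=status, score=score, blocks=blocks, q_aligned_fraction=frac)


def _junction_gap(blocks: list[Block], boundary: int) -> tuple[Block, Block] | None:
    """The consecutive block pair whose target gap crosses the artificial
    join, if any."""
    for b1, b2 in zip(blocks, blocks[1:]):
        if b1.t_end <= boundary <= b2.t_start:
            return b1, b2
    return None


def check_junction(
    blocks: list[Block], candidate: ChimeraCandidate, fused_ref: FusedReference
) -> bool:
    """True iff the fusion point aligned precisely: one block ends exactly
    at ``junction_q`` on the query and the next begins there, the two
    blocks sitting on opposite sides of the artificial join."""
    pair = _junction_gap(blocks, fused_ref.boundary)
    if pair is None:
        return False
    b1, b2 = pair
    return b1.q_end == candidate.junction_q == b2.q_start


def splice_signals(
    fused_ref: FusedReference, blocks: list[Block]
) -> tuple[str, str, bool, str | None]:
    """Donor/acceptor dinucleotides of the junction intron.

    Donor: the 2 nt immediately 3' of the 5' block end on the fused
    reference; acceptor: the 2 nt immediately 5' of the 3' block start.
    Both are already in transcribed orientation because the fused
    reference is.  Returns ``(donor, acceptor, canonical, flag)``.
    """
    pair = _junction_gap(blocks, fused_ref.boundary)
    if pair is None:
        return "NN", "NN", False, "no-junction-intron"
    b1, b2 = pair
    seq = fused_ref.seq
    donor = seq[b1.t_end : b1.t_end + 2]
    acceptor = seq[b2.t_start - 2 : b2.t_start]
    if len(donor) < 2 or b2.t_start - 2 < b1.t_end or len(acceptor) < 2:
        return "NN", "NN", False, "no-context"
    canonical = donor == "GT" and acceptor == "AG"
    return donor, acceptor, canonical, None


def cis_splice_signals(
    fused_ref: FusedReference, blocks: list[Block]
) -> list[tuple[str, str]]:
    """Donor/acceptor dinucleotides of the non-junction (cis) introns,
    reported informationally."""
    boundary = fused_ref.boundary
    out = []
    for b1, b2 in zip(blocks, blocks[1:]):
        if b1.t_end <= boundary <= b2.t_start:
            continue
        out.append((fused_ref.seq[b1.t_end : b1.t_end + 2],
                    fused_ref.seq[b2.t_start - 2 : b2.t_start]))
    return out


def check_reading_frame(mrna_seq: str, junction_q: int) -> bool:
    """Reading-frame integrity: the longest forward-frame ORF (ATG..stop,
    standard code) spans the fusion point."""
    orf = longest_orf(mrna_seq)
    if orf is None:
        return False
    s, e = orf
    return s < junction_q < e


@dataclass
class VerifiedCandidate:
    candidate: ChimeraCandidate
    check: SpliceCheck
    passed: bool
    reason: str | None  # first failing criterion, or None


def verify_candidates(
    candidates: list[ChimeraCandidate],
    genome: GenomeStore,
    mrna_seqs: GenomeStore | dict[str, str],
    flank: int = 500,
    min_intron: int = 30,
    seed_len: int = 12,
) -> list[VerifiedCandidate]:
    """Run the full verification chain on every candidate."""
    results = []
    for cand in candidates:
        mrna = mrna_seqs[cand.mrna_id]
        fused = build_fused_reference(genome, cand, flank=flank)
        aln = spliced_align(mrna, fused, min_intron=min_intron, seed_len=seed_len)
        if aln.status != "ok":
            check = SpliceCheck(False, "NN", "NN", False, False, status="failed",
                                flags=["alignment-failed"])
            results.append(VerifiedCandidate(cand, check, False, "alignment"))
            continue
        precise = check_junction(aln.blocks, cand, fused)
        donor, acceptor, canonical, flag = splice_signals(fused, aln.blocks)
        frame_ok = check_reading_frame(mrna, cand.junction_q)
        check = SpliceCheck(precise, donor, acceptor, canonical, frame_ok,
                            flags=[flag] if flag else [])
        if not precise:
            reason = "junction"
        elif not canonical:
            reason = "splice"
        elif not frame_ok:
            reason = "frame"
        else:
            reason = None
        results.append(VerifiedCandidate(cand, check, reason is None, reason))
    return results
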