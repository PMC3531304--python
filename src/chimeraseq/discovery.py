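"""Inference of putative chimeric mRNAs from split transcript alignments.

A transcript aligned to exactly two non-contiguous genomic loci, where the
two aligned query parts abut within a small tolerance, is a chimera
candidate.  Filters follow the stringent regime used for curated
mRNA-to-genome alignments: >= 96% base identity, >= 100 nt aligned length
per part, and an overlap or gap of at most 10 nt between the two query
parts at the fusion junction.

Fusion geometry is classified into inter-chromosomal, intra-chromosomal
inter-strand and intra-strand events; intra-strand events are further
ordered by the relative genomic layout of the two partners in
transcription direction (the 5' partner downstream of the 3' partner, one
partner nested in the other, or a colinear but implausibly distant
read-through arrangement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .formats_io import AlignmentRecord

__all__ = [
    "Locus",
    "DiscoveryParams",
    "ChimeraCandidate",
    "filter_alignments",
    "pair_partners",
    "classify_fusion",
    "classify_order",
    "discover_chimeras",
]

FUSION_CLASSES = ("inter_chromosomal", "intra_inter_strand", "intra_intra_strand")
ORDER_TYPES = (
    "partner5_downstream",
    "nested_3p_in_5p",
    "nested_5p_in_3p",
    "colinear_readthrough",
    "ambiguous",
    "not_applicable",
)


@dataclass(frozen=True)
class Locus:
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty locus {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class DiscoveryParams:
    """Alignment-level and junction-level discovery filters."""

    min_identity: float = 0.96
    min_align_len: int = 100
    max_junction_gap: int = 10
    #: colinear same-strand partners farther apart than this cannot be one
    #: cis intron and are kept as read-through-like candidates
    max_intron: int = 1_000_000
    #: if set, drop alignments whose identity is more than this far below
    #: the per-transcript best (Blat-style near-best filter)
    near_best: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_align_len < 1 or self.max_junction_gap < 0:
            raise ValueError("bad discovery parameters")


@dataclass
class ChimeraCandidate:
    """A 5'/3' partner pair with its fusion-junction bookkeeping.

    ``junction_q`` is the transcript coordinate of the fusion point (end of
    the 5' part, 0-based half-open); ``gap_overlap`` is signed nt between
    the query spans (positive = gap, negative = overlap).
    """

    mrna_id: str
    partner5: Locus
    partner3: Locus
    junction_q: int
    gap_overlap: int
    fusion_class: str = ""
    order_type: str = "not_applicable"
    rec5: AlignmentRecord | None = field(default=None, repr=False)
    rec3: AlignmentRecord | None = field(default=None, repr=False)


def filter_alignments(
    records: Iterable[AlignmentRecord], params: DiscoveryParams
) -> list[AlignmentRecord]:
    """Keep records with identity >= min_identity and aligned query length
    >= min_align_len (both boundaries inclusive)."""
    kept = []
    for r in records:
        if r.aligned_query_length is None:
            continue
        if r.identity >= params.min_identity and r.aligned_query_length >= params.min_align_len:
            kept.append(r)
    return kept


def _removal_reasons(
    records: Iterable[AlignmentRecord], params: DiscoveryParams
) -> list[str]:
    reasons = []
    for r in records:
        if r.aligned_query_length is None:
            reasons.append("bed12_no_query_coords")
        elif r.identity < params.min_identity:
            reasons.append("identity")
        elif r.aligned_query_length < params.min_align_len:
            reasons.append("length")
    return reasons


def _mirror(locus: Locus) -> tuple[int, int]:
    """Locus interval in transcription-direction coordinates.

    On the plus strand this is the genomic interval itself; on the minus
    strand coordinates are negated so that "downstream" always means
    larger values.
    """
    if locus.strand == "+":
        return locus.start, locus.end
    return -locus.end, -locus.start


def _non_contiguous(l5: Locus, l3: Locus, params: DiscoveryParams) -> bool:
    """Can these two loci NOT be explained by one cis (colinear) transcript?"""
    if l5.chrom != l3.chrom or l5.strand != l3.strand:
        return True
    s5, e5 = _mirror(l5)
    s3, e3 = _mirror(l3)
    if e5 <= s3:  # colinear: 5' upstream of 3' in transcription direction
        return s3 - e5 > params.max_intron
    return True  # out of order, nested, or overlapping


def pair_partners(
    records: list[AlignmentRecord], params: DiscoveryParams
) -> tuple[ChimeraCandidate | None, str | None]:
    """Pair the two aligned parts of one transcript into a candidate.

    ``records`` must all share a query name and be pre-filtered.  Returns
    ``(candidate, None)`` or ``(None, reason)`` where the reason names the
    rule that suppressed the transcript.
    """
    if not records:
        return None, "no_alignments"
    if len({r.qName for r in records}) != 1:
        raise ValueError("pair_partners expects records for a single query")
    if len(records) == 1:
        return None, "single_locus"
    if len(records) > 2:
        return None, "ambiguous_multi_locus"

    a, b = sorted(records, key=lambda r: r.qStart)
    if a.qStart == b.qStart:
        return None, "ambiguous_tie"
    l5 = Locus(a.tName, a.strand, a.tStart, a.tEnd)
    l3 = Locus(b.tName, b.strand, b.tStart, b.tEnd)
    if not _non_contiguous(l5, l3, params):
        return None, "contiguous"
    g = b.qStart - a.qEnd
    if abs(g) > params.max_junction_gap:
        return None, "gap"
    cand = ChimeraCandidate(
        mrna_id=a.qName,
        partner5=l5,
        partner3=l3,
        junction_q=a.qEnd,
        gap_overlap=g,
        rec5=a,
        rec3=b,
    )
    cand.fusion_class = classify_fusion(cand)
    cand.order_type = (
        classify_order(cand) if cand.fusion_class == "intra_intra_strand" else "not_applicable"
    )
    return cand, None


def classify_fusion(candidate: ChimeraCandidate) -> str:
    l5, l3 = candidate.partner5, candidate.partner3
    if l5.chrom != l3.chrom:
        return "inter_chromosomal"
    if l5.strand != l3.strand:
        return "intra_inter_strand"
    return "intra_intra_strand"


def classify_order(candidate: ChimeraCandidate) -> str:
    """Order the partner intervals of a same-strand event in transcription
    direction.  Partially overlapping, non-nested intervals are reported as
    ``ambiguous`` and left out of order tabulations."""
    l5, l3 = candidate.partner5, candidate.partner3
    s5, e5 = _mirror(l5)
    s3, e3 = _mirror(l3)
    if s5 >= e3:
        return "partner5_downstream"
    if e5 <= s3:
        return "colinear_readthrough"
    nested_3in5 = s5 <= s3 and e3 <= e5 and (s3, e3) != (s5, e5)
    nested_5in3 = s3 <= s5 and e5 <= e3 and (s3, e3) != (s5, e5)
    if nested_3in5:
        return "nested_3p_in_5p"
    if nested_5in3:
        return "nested_5p_in_3p"
    return "ambiguous"


def discover_chimeras(
    records: Iterable[AlignmentRecord], params: DiscoveryParams | None = None
) -> tuple[list[ChimeraCandidate], list[dict]]:
    """Run the full discovery pass over a mixed set of alignments.

    Records are grouped by transcript, filtered, optionally trimmed by the
    near-best rule, and paired.  Returns candidates plus a reject log with
    one row per suppressed transcript naming the decisive filter.
    """
    params = params or DiscoveryParams()
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.qName, []).append(r)

    candidates: list[ChimeraCandidate] = []
    rejects: list[dict] = []
    for qname in sorted(by_query):
        group = by_query[qname]
        if params.near_best is not None:
            with_q = [r for r in group if r.aligned_query_length is not None]
            if with_q:
                best = max(r.identity for r in with_q)
                group = [
                    r for r in group
                    if r.aligned_query_length is not None
                    and r.identity >= best - params.near_best
                ]
        kept = filter_alignments(group, params)
        if len(kept) < 2:
            removed = _removal_reasons(
                [r for r in group if r not in kept], params
            )
            reason = removed[0] if removed else "single_locus"
            rejects.append({"mrna_id": qname, "stage": "discover", "reason": reason})
            continue
        cand, reason = pair_partners(kept, params)
        if cand is None:
            rejects.append({"mrna_id": qname, "stage": "discover", "reason": reason})
        else:
            candidates.append(cand)
    return candidates, rejects
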