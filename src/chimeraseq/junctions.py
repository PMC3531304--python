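"""Quantification of chimera expression from single-end RNA-seq.

The strategy mirrors ungapped short-read mapping of the Bowtie-v era:

1. reads are quality-filtered and right-trimmed to a uniform length L;
2. reads are mapped to the genome ungapped with at most ``max_mismatches``
   Hamming mismatches; only reads mapping to NO contiguous genomic locus
   can derive from a fusion junction, so the *unmapped* partition feeds
   junction calling (multi-mapped reads are discarded);
3. for each chimera a junction reference of length 2*(L-k) nt is built —
   the last L-k nt of the 5' part followed by the first L-k nt of the 3'
   part — so that any read aligned to it at a valid start position
   overhangs the fusion point by at least k nt (default 5) on both sides.
   With L=76 and k=5 the reference is 142 nt (71 nt per side) and valid
   1-based read starts run from 1 to 67;
4. an event is *validated* when its junction reads come from at least 3
   distinct start positions or at least 3 distinct samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqs import encode, revcomp
from .formats_io import GenomeStore, ReadRecord

__all__ = [
    "JunctionParams",
    "JunctionRef",
    "JunctionHit",
    "ValidationResult",
    "MapResult",
    "GenomeIndex",
    "qc_trim",
    "map_genome",
    "build_junction_refs",
    "call_junction_reads",
    "validate_events",
    "coverage_profile",
]


@dataclass
class JunctionParams:
    read_length: int = 76
    min_overhang: int = 5
    max_mismatches: int = 2
    min_starts: int = 3
    min_samples: int = 3

    def __post_init__(self) -> None:
        if self.read_length <= 2 * self.min_overhang:
            raise ValueError("read length must exceed twice the overhang")

    @property
    def ref_length(self) -> int:
        """Junction-reference length, 2*(L-k)."""
        return 2 * (self.read_length - self.min_overhang)

    @property
    def fusion_offset(self) -> int:
        """0-based position of the first 3'-side base on the reference."""
        return self.read_length - self.min_overhang

    @property
    def last_start_1based(self) -> int:
        """Largest valid 1-based junction-read start, L - 2k + 1."""
        return self.read_length - 2 * self.min_overhang + 1


@dataclass
class JunctionRef:
    event_id: str
    seq: str
    fusion_offset: int
    clipped: bool = False  # a side was shorter than L-k; excluded from calling


@dataclass
class JunctionHit:
    read_id: str
    sample_id: str
    event_id: str
    start_1based: int
    mismatches: int


@dataclass
class ValidationResult:
    event_id: str
    n_reads: int
    n_start_positions: int
    n_samples: int
    validated: bool


@dataclass
class MapResult:
    read_id: str
    status: str  # unique | multi | unmapped
    hits: list[tuple[str, int, str, int]] = field(default_factory=list)  # chrom,pos,strand,mm


# ---------------------------------------------------------------------------
# QC


def qc_trim(
    reads: list[ReadRecord],
    target_len: int,
    min_q: int = 20,
    qc_mode: str = "mean",
) -> list[ReadRecord]:
    """Right-trim reads to ``target_len`` and drop low-quality or short reads.

    A read fails QC when its mean (``qc_mode="mean"``, default) or minimum
    (``qc_mode="min"``) post-trim Phred score is below ``min_q``.  Reads
    shorter than ``target_len`` are removed.
    """
    if qc_mode not in ("mean", "min"):
        raise ValueError("qc_mode must be 'mean' or 'min'")
    out = []
    for r in reads:
        if len(r.seq) < target_len:
            continue
        seq, qual = r.seq[:target_len], r.qual[:target_len]
        stat = (sum(qual) / len(qual)) if qc_mode == "mean" else min(qual)
        if stat < min_q:
            continue
        out.append(ReadRecord(r.read_id, r.sample_id, seq, qual))
    return out


# ---------------------------------------------------------------------------
# Ungapped genome mapping (pigeonhole-seeded k-mer index)


class GenomeIndex:
    """Sorted-hash k-mer index over a genome for ungapped mapping.

    For mismatch budget m, a read is split into m+1 parts; at least one
    part is exact in any qualifying alignment, so looking up the first
    ``k`` bases of every part finds all candidate positions (requires read
    length >= (m+1)*k; shorter reads fall back to a full scan).
    """

    def __init__(self, genome: GenomeStore, k: int = 16) -> None:
        self.k = k
        self.names = sorted(genome.sequences)
        self.offsets: dict[str, int] = {}
        self.lengths: dict[str, int] = {}
        parts = []
        pos = 0
        for name in self.names:
            self.offsets[name] = pos
            self.lengths[name] = len(genome[name])
            parts.append(genome[name])
            pos += len(genome[name]) + 1  # sentinel N between chromosomes
            parts.append("N")
        self.concat = "".join(parts)
        self.codes = encode(self.concat)
        n = len(self.codes)
        if n >= k:
            h = np.zeros(n - k + 1, dtype=np.uint64)
            bad = np.zeros(n - k + 1, dtype=bool)
            for i in range(k):
                window = self.codes[i : n - k + 1 + i]
                h = h * np.uint64(4) + np.minimum(window, 3).astype(np.uint64)
                bad |= window == 4
            order = np.argsort(h, kind="stable")
            self.sorted_hashes = h[order]
            self.sorted_pos = order.astype(np.int64)
            self.valid = ~bad
        else:
            self.sorted_hashes = np.zeros(0, dtype=np.uint64)
            self.sorted_pos = np.zeros(0, dtype=np.int64)
            self.valid = np.zeros(0, dtype=bool)

    def locate(self, kmer_codes: np.ndarray) -> np.ndarray:
        if (kmer_codes == 4).any():
            return np.zeros(0, dtype=np.int64)
        h = np.uint64(0)
        for c in kmer_codes:
            h = h * np.uint64(4) + np.uint64(c)
        lo = np.searchsorted(self.sorted_hashes, h, side="left")
        hi = np.searchsorted(self.sorted_hashes, h, side="right")
        pos = self.sorted_pos[lo:hi]
        return pos[self.valid[pos]]

    def chrom_at(self, global_pos: int, length: int) -> tuple[str, int] | None:
        """Resolve a concatenated-genome position to (chrom, pos), or None
        when the window crosses a chromosome boundary."""
        for name in reversed(self.names):
            off = self.offsets[name]
            if global_pos >= off:
                if global_pos + length <= off + self.lengths[name]:
                    return name, global_pos - off
                return None
        return None


def _mismatches_at(index: GenomeIndex, pos: int, read_codes: np.ndarray) -> int:
    window = index.codes[pos : pos + len(read_codes)]
    if len(window) != len(read_codes):
        return len(read_codes)
    return int(np.count_nonzero((window != read_codes) | (window == 4)))


def map_genome(
    reads: list[ReadRecord],
    genome: GenomeStore,
    max_mismatches: int = 2,
    index: GenomeIndex | None = None,
    k: int = 16,
) -> dict[str, MapResult]:
    """Partition reads into unique / multi / unmapped on the genome.

    A read is *unique* iff exactly one genomic position on either strand
    aligns ungapped (Hamming) with at most ``max_mismatches``; *multi* for
    more than one, *unmapped* for none.  The classification equals a
    brute-force scan of every position.
    """
    index = index or GenomeIndex(genome, k=k)
    results: dict[str, MapResult] = {}
    for read in reads:
        L = len(read.seq)
        hits: dict[tuple[int, str], int] = {}
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            codes = encode(seq)
            if L >= (max_mismatches + 1) * index.k:
                part = L // (max_mismatches + 1)
                seed_offsets = [p * part for p in range(max_mismatches + 1)]
                cands = set()
                for off in seed_offsets:
                    for p in index.locate(codes[off : off + index.k]):
                        start = int(p) - off
                        if start >= 0:
                            cands.add(start)
                for start in cands:
                    mm = _mismatches_at(index, start, codes)
                    if mm <= max_mismatches:
                        hits[(start, strand)] = mm
            else:  # short-read fallback: exhaustive scan
                n = len(index.codes) - L + 1
                if n > 0:
                    genome_windows = np.lib.stride_tricks.sliding_window_view(index.codes, L)
                    mm_all = ((genome_windows != codes) | (genome_windows == 4)).sum(axis=1)
                    for start in np.nonzero(mm_all <= max_mismatches)[0]:
                        hits[(int(start), strand)] = int(mm_all[start])
        resolved = []
        for (start, strand), mm in sorted(hits.items()):
            loc = index.chrom_at(start, L)
            if loc is not None:
                resolved.append((loc[0], loc[1], strand, mm))
        status = "unmapped" if not resolved else ("unique" if len(resolved) == 1 else "multi")
        results[read.read_id] = MapResult(read.read_id, status, resolved)
    return results


# ---------------------------------------------------------------------------
# Junction references and junction-read calling


def build_junction_refs(
    chimera_seqs: dict[str, str],
    junctions: dict[str, int],
    params: JunctionParams,
) -> list[JunctionRef]:
    """Build the 2*(L-k) nt junction reference for every chimera.

    A side shorter than L-k is clipped and the reference flagged; clipped
    references are excluded from start-window calling.
    """
    side = params.fusion_offset  # L - k
    refs = []
    for event_id in sorted(chimera_seqs):
        seq = chimera_seqs[event_id]
        jq = junctions[event_id]
        left = seq[max(0, jq - side) : jq]
        right = seq[jq : jq + side]
        clipped = len(left) < side or len(right) < side
        refs.append(
            JunctionRef(
                event_id=event_id,
                seq=left + right,
                fusion_offset=len(left),
                clipped=clipped,
            )
        )
    return refs


def call_junction_reads(
    unmapped_reads: list[ReadRecord],
    junction_refs: list[JunctionRef],
    params: JunctionParams,
) -> tuple[list[JunctionHit], list[tuple[str, tuple[str, ...]]]]:
    """Call junction reads among genome-unmapped reads.

    A hit needs an ungapped alignment to a junction reference with at most
    ``max_mismatches`` mismatches starting within the valid window
    (1-based start in [1, L-2k+1]), in either orientation.  A read whose
    best mismatch count is achieved on several references is flagged
    *shared* and excluded from per-event analysis; the second return value
    lists ``(read_id, tied_event_ids)``.
    """
    L = params.read_length
    usable = [r for r in junction_refs if not r.clipped and len(r.seq) == params.ref_length]
    if not usable:
        return [], []
    n_starts = params.last_start_1based
    windows = np.stack(
        [
            np.stack([encode(ref.seq[s : s + L]) for s in range(n_starts)])
            for ref in usable
        ]
    )  # (refs, starts, L)

    hits: list[JunctionHit] = []
    shared: list[tuple[str, tuple[str, ...]]] = []
    for read in unmapped_reads:
        if len(read.seq) != L:
            continue
        best_mm = params.max_mismatches + 1
        best: list[tuple[int, int]] = []  # (ref index, 0-based start)
        for seq in (read.seq, revcomp(read.seq)):
            codes = encode(seq)
            mm = ((windows != codes) | (windows == 4)).sum(axis=2)  # (refs, starts)
            m = int(mm.min())
            if m < best_mm:
                best_mm = m
                best = [tuple(x) for x in np.argwhere(mm == m)]
            elif m == best_mm:
                best.extend(tuple(x) for x in np.argwhere(mm == m))
        if best_mm > params.max_mismatches:
            continue
        ref_ids = sorted({usable[r].event_id for r, _ in best})
        if len(ref_ids) > 1:
            shared.append((read.read_id, tuple(ref_ids)))
            continue
        r, s = min(best)  # leftmost start on ties
        hits.append(
            JunctionHit(
                read_id=read.read_id,
                sample_id=read.sample_id,
                event_id=usable[r].event_id,
                start_1based=s + 1,
                mismatches=best_mm,
            )
        )
    return hits, shared


def validate_events(
    hits: list[JunctionHit],
    params: JunctionParams,
    event_ids: list[str] | None = None,
) -> dict[str, ValidationResult]:
    """Apply the >=3-distinct-starts-or->=3-samples validation rule."""
    by_event: dict[str, list[JunctionHit]] = {}
    for h in hits:
        by_event.setdefault(h.event_id, []).append(h)
    ids = event_ids if event_ids is not None else sorted(by_event)
    out = {}
    for event_id in ids:
        ev = by_event.get(event_id, [])
        starts = {h.start_1based for h in ev}
        samples = {h.sample_id for h in ev}
        out[event_id] = ValidationResult(
            event_id=event_id,
            n_reads=len(ev),
            n_start_positions=len(starts),
            n_samples=len(samples),
            validated=len(starts) >= params.min_starts or len(samples) >= params.min_samples,
        )
    return out


def coverage_profile(
    genome_hit_intervals: list[tuple[int, int]],
    junction_hits: list[JunctionHit],
    transcript_len: int,
    junction_q: int,
    params: JunctionParams,
) -> np.ndarray:
    """Per-base read coverage along a chimera transcript.

    Pools reads uniquely mapped to the genome (already projected to
    transcript coordinates by the caller, as half-open intervals) with the
    chimera's junction reads (converted here from junction-reference
    starts).  ``counts[i]`` is the number of pooled reads covering
    position ``i``.
    """
    counts = np.zeros(transcript_len, dtype=np.int64)
    ref_left = params.fusion_offset
    intervals = list(genome_hit_intervals)
    for h in junction_hits:
        start = junction_q - ref_left + (h.start_1based - 1)
        intervals.append((start, start + params.read_length))
    for s, e in intervals:
        s, e = max(0, s), min(transcript_len, e)
        if s < e:
            counts[s:e] += 1
    return counts
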