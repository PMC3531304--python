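"""EST evidence for fusion junctions.

A chimera candidate gains independent experimental support when expressed
sequence tags align across its fusion point.  An EST counts as *spanning*
when a single local alignment covers at least ``min_flank`` nt (default
20) on both sides of the fusion point at >= 96% identity; a candidate is
*supported* when at least ``min_ests`` (default 3) distinct ESTs span it.
ESTs are unstranded, so the reverse complement is aligned as well.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seqs import revcomp
from .alignment import smith_waterman

__all__ = ["EstHit", "EstSupport", "local_align", "spanning_support", "est_support"]

SEED_K = 11  # BLAST-default word size for nucleotide searches


@dataclass
class EstHit:
    est_id: str
    chimera_id: str
    q_start: int  # span on the chimera, 0-based half-open
    q_end: int
    identity: float
    orientation: str = "forward"


@dataclass
class EstSupport:
    chimera_id: str
    n_spanning: int
    supported: bool
    spanning_est_ids: tuple[str, ...] = ()


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def local_align(
    query: str, target: str, min_identity: float = 0.96, k: int = SEED_K
) -> tuple[tuple[int, int], tuple[int, int], float] | None:
    """Seeded local alignment of ``query`` against ``target``.

    A shared exact ``k``-mer gates the (gapped) local alignment; the hit is
    discarded when its identity falls below ``min_identity`` or it is
    shorter than ``2*k``.  Returns ``(query_span, target_span, identity)``
    or ``None``.
    """
    if not query or not target:
        raise ValueError("sequences must be nonempty")
    if not _shares_kmer(target, query, k):
        return None
    aln = smith_waterman(query, target)
    if aln is None:
        return None
    if aln.columns < 2 * k or aln.identity < min_identity:
        return None
    return (aln.q_start, aln.q_end), (aln.t_start, aln.t_end), aln.identity


def spanning_support(
    hits: list[EstHit],
    fusion_point: int,
    min_flank: int = 20,
    min_ests: int = 3,
) -> EstSupport:
    """Count distinct ESTs whose hit span covers
    ``[fusion_point - min_flank, fusion_point + min_flank)``."""
    chimera_ids = {h.chimera_id for h in hits}
    if len(chimera_ids) > 1:
        raise ValueError("hits must all target one chimera")
    spanning = sorted(
        {
            h.est_id
            for h in hits
            if h.q_start <= fusion_point - min_flank and h.q_end >= fusion_point + min_flank
        }
    )
    return EstSupport(
        chimera_id=next(iter(chimera_ids)) if chimera_ids else "",
        n_spanning=len(spanning),
        supported=len(spanning) >= min_ests,
        spanning_est_ids=tuple(spanning),
    )


def est_support(
    chimera_seqs: dict[str, str],
    junctions: dict[str, int],
    ests: dict[str, str],
    min_identity: float = 0.96,
    min_flank: int = 20,
    min_ests: int = 3,
) -> tuple[dict[str, EstSupport], list[EstHit]]:
    """Score every chimera by EST evidence spanning its fusion point.

    ``junctions`` maps chimera id to the fusion-point transcript
    coordinate.  Each EST is aligned in both orientations against each
    chimera; the better orientation wins.
    """
    all_hits: list[EstHit] = []
    support: dict[str, EstSupport] = {}
    for chimera_id in sorted(chimera_seqs):
        cseq = chimera_seqs[chimera_id]
        hits = []
        for est_id in sorted(ests):
            best = None
            for orientation, seq in (("forward", ests[est_id]), ("reverse", revcomp(ests[est_id]))):
                res = local_align(seq, cseq, min_identity=min_identity)
                if res is None:
                    continue
                (_, _), (t0, t1), ident = res
                hit = EstHit(est_id, chimera_id, t0, t1, ident, orientation)
                if best is None or (hit.q_end - hit.q_start) * hit.identity > (
                    best.q_end - best.q_start
                ) * best.identity:
                    best = hit
            if best is not None:
                hits.append(best)
        all_hits.extend(hits)
        support[chimera_id] = spanning_support(
            hits, junctions[chimera_id], min_flank=min_flank, min_ests=min_ests
        )
    return support, all_hits
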