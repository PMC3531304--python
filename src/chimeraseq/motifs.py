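"""Shared-motif analysis of parental genomic regions.

For each chimera the genomic neighbourhoods of its 5' and 3' partner loci
are split into four categories — upstream window, exons, introns,
downstream window, all read in transcription direction — and each of the
(up to) 16 category pairings is searched for a single shared DNA motif of
width 10-30 nt (zero or one site per sequence, one motif per pair).  The
search enumerates shared exact 10-mers as seeds and extends the best seed
pair under +1/-1 scoring; significance is an empirical p-value against
dinucleotide-shuffled replicates of one member, which preserves
local composition.

Shared motifs are then compared against a PFM library (JASPAR-style) by
mean per-column Pearson correlation over all offsets (overlap >= 4
columns) and both orientations, with an empirical column-shuffle null and
Benjamini-Hochberg FDR across the library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seqs import dinucleotide_shuffle, revcomp
from .discovery import ChimeraCandidate
from .formats_io import GenomeStore, Pfm

__all__ = [
    "RegionPair",
    "SharedMotif",
    "MotifMatch",
    "extract_region_pairs",
    "find_shared_motif",
    "tabulate_categories",
    "match_pfm",
]

CATEGORIES = ("upstream", "exon", "intron", "downstream")


@dataclass
class RegionPair:
    chimera_id: str
    category5: str
    category3: str
    seq5: str
    seq3: str
    clipped: bool = False


@dataclass
class SharedMotif:
    chimera_id: str
    width: int
    site5: int  # 0-based offsets of the site in each sequence
    site3: int
    matrix: np.ndarray  # 4 x W counts accumulated from the two sites
    score: int
    empirical_p: float
    category5: str = ""
    category3: str = ""


@dataclass
class MotifMatch:
    shared_motif_id: str
    pfm_id: str
    offset: int
    orientation: str  # forward | reverse_complement
    similarity: float
    p: float
    q: float


# ---------------------------------------------------------------------------
# Region extraction


def _fetch(genome: GenomeStore, chrom: str, start: int, end: int, strand: str) -> tuple[str, bool]:
    """Genomic slice in transcription orientation; clips at edges."""
    n = len(genome[chrom])
    s, e = max(0, start), min(n, end)
    clipped = (s, e) != (start, end)
    if s >= e:
        return "", clipped
    seq = genome[chrom][s:e]
    return (revcomp(seq) if strand == "-" else seq), clipped


def _partner_regions(
    genome: GenomeStore, locus, blocks: list[tuple[int, int]], up_window: int, down_window: int
) -> dict[str, tuple[str, bool]]:
    chrom, strand = locus.chrom, locus.strand
    if strand == "+":
        upstream = _fetch(genome, chrom, locus.start - up_window, locus.start, strand)
        downstream = _fetch(genome, chrom, locus.end, locus.end + down_window, strand)
    else:  # minus strand: upstream lies at higher coordinates
        upstream = _fetch(genome, chrom, locus.end, locus.end + up_window, strand)
        downstream = _fetch(genome, chrom, locus.start - down_window, locus.start, strand)
    exon_parts = [_fetch(genome, chrom, s, e, strand)[0] for s, e in blocks]
    gaps = [(e1, s2) for (_, e1), (s2, _) in zip(blocks, blocks[1:]) if s2 > e1]
    intron_parts = [_fetch(genome, chrom, s, e, strand)[0] for s, e in gaps]
    if strand == "-":
        exon_parts.reverse()
        intron_parts.reverse()
    return {
        "upstream": upstream,
        "downstream": downstream,
        "exon": ("".join(exon_parts), False),
        "intron": ("".join(intron_parts), False),
    }


def extract_region_pairs(
    candidate: ChimeraCandidate,
    genome: GenomeStore,
    up_window: int = 2000,
    down_window: int = 2000,
) -> list[RegionPair]:
    """All category pairings (with both sequences nonempty) of the two
    partner neighbourhoods.  Exon blocks come from the candidate's own
    alignment records; single-exon partners have no intron sequence and
    those pairings are skipped."""
    if candidate.rec5 is None or candidate.rec3 is None:
        raise ValueError("candidate lacks alignment records")
    r5 = _partner_regions(
        genome, candidate.partner5, candidate.rec5.target_blocks, up_window, down_window
    )
    r3 = _partner_regions(
        genome, candidate.partner3, candidate.rec3.target_blocks, up_window, down_window
    )
    pairs = []
    for c5 in CATEGORIES:
        seq5, clip5 = r5[c5]
        if not seq5:
            continue
        for c3 in CATEGORIES:
            seq3, clip3 = r3[c3]
            if not seq3:
                continue
            pairs.append(RegionPair(candidate.mrna_id, c5, c3, seq5, seq3, clip5 or clip3))
    return pairs


# ---------------------------------------------------------------------------
# Shared-motif search

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _site_matrix(a: str, b: str) -> np.ndarray:
    counts = np.zeros((4, len(a)), dtype=float)
    for col, (x, y) in enumerate(zip(a, b)):
        for base in (x, y):
            if base in _BASE_INDEX:
                counts[_BASE_INDEX[base], col] += 1
    return counts


def _best_shared_site(
    seq5: str, seq3: str, w_min: int, w_max: int, max_seeds: int = 20000
) -> tuple[int, int, int, int] | None:
    """Best-scoring pair of sites sharing an exact ``w_min``-mer seed.

    Each seed pair is extended greedily in both directions under +1/-1
    match/mismatch scoring, then trimmed back to ``w_max`` by dropping the
    lower-scoring outermost extension steps (right side first on ties).
    Returns ``(score, site5, site3, width)`` or ``None``.
    """
    k = w_min
    if len(seq5) < k or len(seq3) < k:
        return None
    index: dict[str, list[int]] = {}
    for i in range(len(seq5) - k + 1):
        index.setdefault(seq5[i : i + k], []).append(i)
    best = None
    n_seeds = 0
    for j in range(len(seq3) - k + 1):
        for i in index.get(seq3[j : j + k], ()):
            n_seeds += 1
            if n_seeds > max_seeds:
                break
            # extend left
            left_contrib = []
            cum = run_best = 0
            best_l = 0
            step = 1
            while i - step >= 0 and j - step >= 0:
                cum += 1 if seq5[i - step] == seq3[j - step] else -1
                left_contrib.append(1 if seq5[i - step] == seq3[j - step] else -1)
                if cum > run_best:
                    run_best, best_l = cum, step
                step += 1
            left_contrib = left_contrib[:best_l]
            # extend right
            right_contrib = []
            cum = run_best = 0
            best_r = 0
            step = 0
            while i + k + step < len(seq5) and j + k + step < len(seq3):
                hit = seq5[i + k + step] == seq3[j + k + step]
                cum += 1 if hit else -1
                right_contrib.append(1 if hit else -1)
                if cum > run_best:
                    run_best, best_r = cum, step + 1
                step += 1
            right_contrib = right_contrib[:best_r]
            l, r = best_l, best_r
            score = k + sum(left_contrib) + sum(right_contrib)
            while k + l + r > w_max:
                if r > 0 and (l == 0 or right_contrib[r - 1] <= left_contrib[l - 1]):
                    score -= right_contrib[r - 1]
                    r -= 1
                else:
                    score -= left_contrib[l - 1]
                    l -= 1
            cand = (score, i - l, j - l, k + l + r)
            if best is None or cand[0] > best[0]:
                best = cand
        if n_seeds > max_seeds:
            break
    return best


def find_shared_motif(
    seq5: str,
    seq3: str,
    w_min: int = 10,
    w_max: int = 30,
    n_shuffles: int = 200,
    seed: int = 0,
    p_max: float = 0.05,
    chimera_id: str = "",
) -> SharedMotif | None:
    """Single best shared motif between two sequences, or ``None``.

    The empirical p-value is the fraction of ``n_shuffles`` dinucleotide-
    shuffled replicates of ``seq3`` whose best shared-site score reaches
    the observed score; pairs with no shared seed or p > ``p_max`` yield
    ``None``.
    """
    if len(seq5) < w_min or len(seq3) < w_min:
        return None
    obs = _best_shared_site(seq5, seq3, w_min, w_max)
    if obs is None:
        return None
    score, site5, site3, width = obs
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        sh = dinucleotide_shuffle(seq3, rng)
        null = _best_shared_site(seq5, sh, w_min, w_max)
        if null is not None and null[0] >= score:
            exceed += 1
    p = exceed / n_shuffles
    if p > p_max:
        return None
    return SharedMotif(
        chimera_id=chimera_id,
        width=width,
        site5=site5,
        site3=site3,
        matrix=_site_matrix(seq5[site5 : site5 + width], seq3[site3 : site3 + width]),
        score=score,
        empirical_p=p,
    )


# ---------------------------------------------------------------------------
# Category tabulation (Table-1-style 4x4 matrix)


def tabulate_categories(
    shared_motifs: list[SharedMotif],
    matched_ids: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """4x4 count matrices over (5' category, 3' category).

    Each chimera contributes its single best-scoring pair (ties broken by
    category order).  The second matrix counts only chimeras whose shared
    motif significantly matched a library PFM (ids in ``matched_ids``).
    """
    matched_ids = matched_ids or set()
    best: dict[str, SharedMotif] = {}
    for m in shared_motifs:
        cur = best.get(m.chimera_id)
        rank = (m.score, -CATEGORIES.index(m.category5), -CATEGORIES.index(m.category3))
        if cur is None:
            best[m.chimera_id] = m
        else:
            cur_rank = (cur.score, -CATEGORIES.index(cur.category5), -CATEGORIES.index(cur.category3))
            if rank > cur_rank:
                best[m.chimera_id] = m
    total = np.zeros((4, 4), dtype=int)
    matched = np.zeros((4, 4), dtype=int)
    for m in best.values():
        i, j = CATEGORIES.index(m.category5), CATEGORIES.index(m.category3)
        total[i, j] += 1
        if m.chimera_id in matched_ids:
            matched[i, j] += 1
    return total, matched


# ---------------------------------------------------------------------------
# PFM comparison (TOMTOM-style)


def _column_z(freq: np.ndarray) -> np.ndarray:
    """Column-standardised frequencies; degenerate (uniform) columns zeroed
    so their correlation contributes 0."""
    centered = freq - freq.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, centered / norms, 0.0)
    return z


def _pfm_revcomp(freq: np.ndarray) -> np.ndarray:
    return freq[::-1, ::-1]


def _best_similarity(zm: np.ndarray, zp: np.ndarray, min_overlap: int) -> tuple[float, int, str] | None:
    """Best mean per-column Pearson correlation over offsets/orientations.

    Offset d aligns motif column i with pfm column i + d.
    """
    best = None
    for orientation, z in (("forward", zp), ("reverse_complement", _pfm_revcomp(zp))):
        r = zm.T @ z  # (Wm, Wp) column-correlation matrix
        wm, wp = r.shape
        for d in range(-(wm - min_overlap), wp - min_overlap + 1):
            diag = np.diagonal(r, offset=d)
            if diag.size < min_overlap:
                continue
            sim = float(diag.mean())
            if best is None or sim > best[0]:
                best = (sim, d, orientation)
    return best


def match_pfm(
    shared_motif: SharedMotif,
    pfm_library: list[Pfm],
    n_shuffles: int = 200,
    seed: int = 0,
    min_overlap: int = 4,
    p_threshold: float = 0.05,
) -> list[MotifMatch]:
    """Compare a shared motif against every library PFM.

    Per PFM: similarity = best mean per-column Pearson correlation of
    frequency columns over all offsets with >= ``min_overlap`` overlapping
    columns and both orientations; p = add-one empirical p over
    ``n_shuffles`` column-permuted replicates of that PFM (guaranteeing
    p in (0, 1]); q = Benjamini-Hochberg FDR across the library.  Matches
    with p below ``p_threshold`` are returned sorted by p.
    """
    if not pfm_library:
        raise ValueError("PFM library is empty")
    if shared_motif.width < min_overlap:
        raise ValueError("motif narrower than the minimum overlap")
    freq_m = shared_motif.matrix / shared_motif.matrix.sum(axis=0, keepdims=True)
    zm = _column_z(freq_m)
    rng = np.random.default_rng(seed)
    raw: list[tuple[str, float, int, str, float]] = []
    for pfm in pfm_library:
        zp = _column_z(pfm.frequencies)
        obs = _best_similarity(zm, zp, min_overlap)
        if obs is None:
            continue
        sim, offset, orientation = obs
        exceed = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(zp.shape[1])
            null = _best_similarity(zm, zp[:, perm], min_overlap)
            if null is not None and null[0] >= sim:
                exceed += 1
        p = (1 + exceed) / (1 + n_shuffles)
        raw.append((pfm.motif_id, sim, offset, orientation, p))

    # Benjamini-Hochberg across the library
    order = sorted(range(len(raw)), key=lambda i: raw[i][4])
    n = len(raw)
    q = [0.0] * n
    prev = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        val = min(prev, raw[i][4] * n / (rank_pos + 1))
        q[i] = val
        prev = val

    motif_id = f"{shared_motif.chimera_id}:{shared_motif.site5}-{shared_motif.site3}"
    matches = [
        MotifMatch(motif_id, pid, offset, orientation, sim, p, q[i])
        for i, (pid, sim, offset, orientation, p) in enumerate(raw)
        if p < p_threshold
    ]
    matches.sort(key=lambda m: (m.p, m.pfm_id))
    return matches
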