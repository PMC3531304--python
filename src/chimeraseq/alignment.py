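"""Dynamic-programming alignment engines.

Two engines back the pipeline's sequence comparisons:

* :func:`smith_waterman` — classic local alignment with linear gap
  penalties, used by the EST support module.
* :func:`spliced_alignment` — local alignment in which the only gaps
  allowed are target-side jumps of at least ``min_intron`` nt at a flat
  penalty (introns).  Queries are mature transcripts, so the model is
  substitution-only within exon blocks; this is the simplified spliced
  aligner used to verify fusion junctions against artificially fused
  genomic references.

Both engines fill their matrices with vectorised numpy recurrences and
trace back with a fixed preference order (diagonal first, then gap/intron,
then stop; intron donors resolved to the leftmost optimal source column).
The preference order is part of the contract: it makes results
deterministic and lets an independent scalar implementation of the same
recurrence reproduce them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seqs import encode

__all__ = ["LocalAlignment", "Block", "smith_waterman", "spliced_alignment"]

_NEG = np.int64(np.iinfo(np.int32).min // 4)


@dataclass
class LocalAlignment:
    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns


@dataclass
class Block:
    """One gap-free aligned block (equal query and target extent)."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def mismatch_rate(self) -> float:
        return self.mismatches / self.length


def _score_matrix(q: np.ndarray, t: np.ndarray, match: int, mismatch: int) -> np.ndarray:
    """Per-(i,j) substitution scores; N (code 4) never matches."""
    eq = (q[:, None] == t[None, :]) & (q[:, None] != 4) & (t[None, :] != 4)
    return np.where(eq, match, mismatch).astype(np.int32)


def smith_waterman(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> LocalAlignment | None:
    """Best local alignment of ``query`` against ``target``.

    Returns ``None`` for empty inputs or when no positive-scoring local
    alignment exists.  Identity counts matches over all alignment columns
    (gap columns included).  Ties are resolved to the alignment ending at
    the smallest query then target coordinate, preferring diagonal over
    query-consuming over target-consuming steps in the traceback.
    """
    if not query or not target:
        return None
    q, t = encode(query), encode(target)
    n, m = len(q), len(t)
    g = -gap
    S = _score_matrix(q, t, match, mismatch)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jw = np.arange(1, m + 1, dtype=np.int64) * g
    for i in range(1, n + 1):
        prev = H[i - 1]
        diag = prev[:-1] + S[i - 1]
        up = prev[1:] + gap
        cand = np.maximum(0, np.maximum(diag, up))
        # left-gap chains: H[i][j] = max_{j'<=j} cand[j'] - g*(j-j')
        H[i, 1:] = (np.maximum.accumulate(cand + jw) - jw).astype(np.int32)

    score = int(H.max())
    if score <= 0:
        return None
    flat = int(np.argmax(H))  # row-major: smallest i, then smallest j
    i, j = divmod(flat, m + 1)

    q_end, t_end = i, j
    matches = columns = 0
    while H[i, j] > 0:
        v = H[i, j]
        if i > 0 and j > 0 and v == H[i - 1, j - 1] + S[i - 1, j - 1]:
            matches += int(S[i - 1, j - 1] == match)
            columns += 1
            i, j = i - 1, j - 1
        elif i > 0 and v == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        elif j > 0 and v == H[i, j - 1] + gap:
            columns += 1
            j -= 1
        else:  # pragma: no cover - recurrence guarantees a predecessor
            raise AssertionError("traceback failed")
    return LocalAlignment(score, i, q_end, j, t_end, matches, columns)


def spliced_alignment(
    query: str,
    target: str,
    min_intron: int = 30,
    match: int = 1,
    mismatch: int = -1,
    intron_penalty: int = 4,
) -> tuple[int, list[Block]]:
    """Local substitution-only alignment with intron jumps on the target.

    Recurrence (cell value = best score of a local path ending there)::

        vd[i][j] = max(0, V[i-1][j-1] + s(q[i-1], t[j-1]))
        V[i][j]  = max(vd[i][j],
                       max_{j' <= j - min_intron} vd[i][j'] - intron_penalty)

    so consecutive blocks are separated by a target gap of at least
    ``min_intron`` nt and chained introns are never profitable.  Returns
    ``(score, blocks)``, blocks query- and target-colinear in ascending
    order; ``(0, [])`` when nothing aligns.
    """
    if not query or not target:
        return 0, []
    q, t = encode(query), encode(target)
    n, m = len(q), len(t)
    S = _score_matrix(q, t, match, mismatch)
    V = np.zeros((n + 1, m + 1), dtype=np.int32)
    JP = np.zeros((n + 1, m + 1), dtype=np.int32)  # intron source column per cell
    idx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        diag = V[i - 1, :-1].astype(np.int64) + S[i - 1]
        vd = np.maximum(0, diag)
        if m > min_intron:
            runmax = np.maximum.accumulate(vd)
            # leftmost running argmax of vd (1-based columns)
            better = vd > np.concatenate(([_NEG], runmax[:-1]))
            runarg = np.maximum.accumulate(np.where(better, idx, 0))
            intron = np.full(m, _NEG, dtype=np.int64)
            intron[min_intron:] = runmax[:-min_intron] - intron_penalty
            take = intron > vd  # prefer the diagonal value on ties
            src = np.zeros(m, dtype=np.int64)
            src[min_intron:] = runarg[:-min_intron]
            V[i, 1:] = np.where(take, intron, vd).astype(np.int32)
            JP[i, 1:] = np.where(take, src, 0).astype(np.int32)
        else:
            V[i, 1:] = vd.astype(np.int32)

    score = int(V.max())
    if score <= 0:
        return 0, []
    flat = int(np.argmax(V))  # global maximum is never intron-derived
    i, j = divmod(flat, m + 1)
    v = int(V[i, j])

    blocks: list[Block] = []
    bq_end, bt_end = i, j  # exclusive end of the block being walked
    mism = 0
    while v > 0:
        if i > 0 and j > 0 and v == int(V[i - 1, j - 1]) + int(S[i - 1, j - 1]):
            mism += int(S[i - 1, j - 1] != match)
            v -= int(S[i - 1, j - 1])
            i, j = i - 1, j - 1
        else:
            # intron jump within row i: close the block, hop to the source
            blocks.append(Block(i, bq_end, j, bt_end, mism))
            j = int(JP[i, j])
            v += intron_penalty  # path value at the source cell is vd, not V
            bq_end, bt_end = i, j
            mism = 0
    if bq_end > i:
        blocks.append(Block(i, bq_end, j, bt_end, mism))
    blocks.reverse()
    return score, blocks
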