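"""Low-level nucleotide-sequence helpers shared across the pipeline.

All sequences are plain upper-case strings over {A,C,G,T,N}; numeric code
uses A=0, C=1, G=2, T=3, N=4 so that an ``N`` never matches anything.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte value -> numeric base code (A,C,G,T,N -> 0..4); everything else -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array with A,C,G,T,N -> 0..4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """i.i.d. random DNA with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y or x == "N" for x, y in zip(a, b))


def orf_spans(seq: str) -> list[tuple[int, int]]:
    """All forward-frame open reading frames as half-open [start, end) spans.

    An ORF runs from an ATG to the end of the first in-frame stop codon; an
    ATG with no downstream in-frame stop yields an ORF running to the last
    complete codon of the sequence.  Only the sense (transcript) strand is
    scanned: mRNA orientation is known.
    """
    spans: list[tuple[int, int]] = []
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOP_CODONS:
                spans.append((start, pos + 3))
                start = None
        if start is not None:
            last = n - ((n - frame) % 3)
            spans.append((start, last))
    return spans


def longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest forward-frame ORF; ties broken by leftmost start."""
    spans = orf_spans(seq)
    if not spans:
        return None
    return max(spans, key=lambda s: (s[1] - s[0], -s[0]))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide composition.

    Altschul–Erikson doublet shuffle: the sequence is viewed as an Eulerian
    walk on the 4-letter De Bruijn multigraph; a random spanning
    tree toward the final letter fixes each vertex's last exit edge, the
    remaining edges are permuted, and the walk is replayed.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges)

    # choose a random last-exit edge per vertex until they form a tree into `last`
    while True:
        last_exit = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        ok = True
        for v in last_exit:
            hops, cur = 0, v
            while cur != last:
                if cur not in last_exit or hops > 4:
                    ok = False
                    break
                cur = last_exit[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_exit[v])
        shuffled[v] = rest

    out = [first]
    counters = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
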