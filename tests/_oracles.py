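"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain scalar Python against the same
mathematical definitions the package implements with vectorised
recurrences — no code is shared with the implementation beyond the
published tie-break contract (diagonal first, then gap/intron with the
leftmost optimal source, then stop; best cell = smallest query index,
then smallest target index).
"""

from __future__ import annotations

from itertools import combinations


def _score(a: str, b: str, match: int, mismatch: int) -> int:
    if a == "N" or b == "N" or a != b:
        return mismatch
    return match


def smith_waterman_oracle(query, target, match=1, mismatch=-1, gap=-2):
    """Scalar Smith-Waterman; returns (score, q_span, t_span, matches, columns)."""
    n, m = len(query), len(target)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(query[i - 1], target[j - 1], match, mismatch)
            v = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = v
            if v > best:
                best, bi, bj = v, i, j
    if best <= 0:
        return None
    i, j = bi, bj
    matches = columns = 0
    while H[i][j] > 0:
        v = H[i][j]
        s = _score(query[i - 1], target[j - 1], match, mismatch) if i and j else None
        if i and j and v == H[i - 1][j - 1] + s:
            matches += int(s == match)
            columns += 1
            i, j = i - 1, j - 1
        elif i and v == H[i - 1][j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, (i, bi), (j, bj), matches, columns


def spliced_oracle(query, target, min_intron=30, match=1, mismatch=-1, intron_penalty=4):
    """Scalar spliced local alignment; returns (score, blocks) with blocks
    as (q_start, q_end, t_start, t_end) tuples."""
    n, m = len(query), len(target)
    NEG = -(10**9)
    V = [[0] * (m + 1) for _ in range(n + 1)]
    VD = [[0] * (m + 1) for _ in range(n + 1)]
    JP = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        run_best, run_arg = NEG, 0
        for j in range(1, m + 1):
            s = _score(query[i - 1], target[j - 1], match, mismatch)
            vd = max(0, V[i - 1][j - 1] + s)
            VD[i][j] = vd
            if j - min_intron >= 1:
                cand = VD[i][j - min_intron]
                if cand > run_best:  # leftmost running argmax
                    run_best, run_arg = cand, j - min_intron
            intron = run_best - intron_penalty if run_best > NEG else NEG
            if intron > vd:
                V[i][j] = intron
                JP[i][j] = run_arg
            else:
                V[i][j] = vd
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if V[i][j] > best:
                best, bi, bj = V[i][j], i, j
    if best <= 0:
        return 0, []
    i, j, v = bi, bj, best
    blocks = []
    bq_end, bt_end = i, j
    while v > 0:
        s = _score(query[i - 1], target[j - 1], match, mismatch) if i and j else None
        if i and j and v == V[i - 1][j - 1] + s:
            v -= s
            i, j = i - 1, j - 1
        else:
            blocks.append((i, bq_end, j, bt_end))
            j = JP[i][j]
            v += intron_penalty
            bq_end, bt_end = i, j
    if bq_end > i:
        blocks.append((i, bq_end, j, bt_end))
    blocks.reverse()
    return best, blocks


def hamming_map_oracle(read_seq: str, genome: dict[str, str], max_mm: int):
    """Every ungapped alignment position (either strand) within the
    mismatch budget, by exhaustive scan."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = read_seq.translate(comp)[::-1]
    L = len(read_seq)
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            for strand, s in (("+", read_seq), ("-", rc)):
                mm = sum(1 for a, b in zip(window, s) if a != b or a == "N")
                if mm <= max_mm:
                    hits.append((chrom, start, strand, mm))
    return sorted(hits)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ranksum_oracle(group_a, group_b):
    """Exact two-sided rank-sum p by enumerating every label assignment."""
    pooled = list(group_a) + list(group_b)
    ranks = _midranks(pooled)
    n_a = len(group_a)
    w_obs = sum(ranks[:n_a])
    le = ge = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        w = sum(ranks[i] for i in idx)
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2 * min(le / total, ge / total))


def orf_oracle(seq: str):
    """All (start, end) ATG..stop spans in the three forward frames by
    brute-force codon walking; ATGs without a downstream in-frame stop run
    to the last complete codon."""
    stops = {"TAA", "TAG", "TGA"}
    spans = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        for p in range(start + 3, len(seq) - 2, 3):
            if seq[p : p + 3] in stops:
                end = p + 3
                break
        if end is None:
            end = start + 3 * ((len(seq) - start) // 3)
        spans.append((start, end))
    return spans


def ks_d_oracle(data, cdf):
    """sup |F_n - F| by direct enumeration at the sorted sample points."""
    xs = sorted(data)
    n = len(xs)
    d = 0.0
    for i, x in enumerate(xs):
        f = cdf(x)
        d = max(d, abs((i + 1) / n - f), abs(i / n - f))
    return d
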