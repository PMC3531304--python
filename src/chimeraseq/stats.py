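"""Expression-variability statistics for validated chimeric events.

Dispersion across samples is graded by the coefficient of variation
(CV = 100 * sample standard deviation / sample mean of junction-read
counts), the CV distribution is checked against normality with a
one-sample Kolmogorov-Smirnov test, and between-group differences
(e.g. male vs female) are assessed with an exact two-sided rank-sum test:
the null distribution of the rank sum is enumerated over all label
assignments whenever that is feasible, with a tie-corrected normal
approximation beyond.  Counts are compared raw (no library-size
normalisation) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .discovery import ChimeraCandidate

__all__ = [
    "CvStat",
    "RankSumResult",
    "filter_unique_events",
    "cv",
    "ks_normality",
    "ranksum_exact",
    "group_comparison",
]

EXACT_ENUMERATION_LIMIT = 10**6  # max C(nA+nB, nA) for full enumeration


@dataclass
class CvStat:
    event_id: str
    mean: float
    sd: float
    cv_percent: float | None  # None (flagged undefined) when mean == 0


@dataclass
class RankSumResult:
    statistic: float  # rank sum W of group A (midranks under ties)
    pvalue: float
    method: str  # "exact" or "normal"


def filter_unique_events(
    validated_events: list[str],
    candidates: list[ChimeraCandidate],
    matrix: pd.DataFrame,
) -> list[str]:
    """Unique-event cut: present (count > 0) in every sample, and neither
    partner locus interval overlaps a partner interval of any other
    candidate.

    ``matrix`` is events x samples junction-read counts.  Overlap is
    genomic (chromosome + coordinate range), strand-insensitive.
    """
    by_id = {c.mrna_id: c for c in candidates}
    loci = {
        c.mrna_id: [
            (c.partner5.chrom, c.partner5.start, c.partner5.end),
            (c.partner3.chrom, c.partner3.start, c.partner3.end),
        ]
        for c in candidates
    }
    kept = []
    for event_id in validated_events:
        if event_id not in by_id or event_id not in matrix.index:
            continue
        row = matrix.loc[event_id]
        if (row <= 0).any():
            continue
        mine = loci[event_id]
        clash = False
        for other_id, theirs in loci.items():
            if other_id == event_id:
                continue
            for chrom_a, s_a, e_a in mine:
                for chrom_b, s_b, e_b in theirs:
                    if chrom_a == chrom_b and s_a < e_b and s_b < e_a:
                        clash = True
        if not clash:
            kept.append(event_id)
    return kept


def cv(values, event_id: str = "") -> CvStat:
    """Coefficient of variation in percent with the n-1 (sample) sd."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("cv requires at least two values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    pct = None if mean == 0 else 100.0 * sd / mean
    return CvStat(event_id=event_id, mean=mean, sd=sd, cv_percent=pct)


def ks_normality(cv_list) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with mean and (n-1) sd estimated from the data.

    No small-sample (Lilliefors) correction is applied by default; the
    asymptotic KS p-value is returned.
    """
    arr = np.asarray(list(cv_list), dtype=float)
    if arr.size < 5:
        raise ValueError("ks_normality requires n >= 5")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    res = sps.kstest(arr, "norm", args=(arr.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def ranksum_exact(group_a, group_b) -> RankSumResult:
    """Two-sided rank-sum test with an exact permutation null.

    W is the rank sum of group A (midranks for ties); the two-sided
    p-value is ``2 * min(P(W <= w), P(W >= w))`` capped at 1, with the
    null taking all ``C(nA+nB, nA)`` label assignments as equally likely.
    Enumeration is exact up to ``EXACT_ENUMERATION_LIMIT`` assignments;
    beyond that a tie-corrected normal approximation is used.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n = a.size, a.size + b.size
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())

    if math.comb(n, n_a) <= EXACT_ENUMERATION_LIMIT:
        r2 = np.rint(2 * ranks).astype(np.int64)  # half-ranks -> exact ints
        w2 = int(round(2 * w_obs))
        combos = np.fromiter(
            (sum(c) for c in combinations(r2, n_a)), dtype=np.int64,
            count=math.comb(n, n_a),
        )
        p_le = np.count_nonzero(combos <= w2) / combos.size
        p_ge = np.count_nonzero(combos >= w2) / combos.size
        p = min(1.0, 2 * min(p_le, p_ge))
        return RankSumResult(w_obs, p, "exact")

    mean = n_a * (n + 1) / 2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n_a * (n - n_a) / 12 * ((n + 1) - tie_term)
    if var == 0:
        return RankSumResult(w_obs, 1.0, "normal")
    z = (w_obs - mean) / math.sqrt(var)
    p = min(1.0, 2 * min(sps.norm.cdf(z), sps.norm.sf(z)))
    return RankSumResult(w_obs, float(p), "normal")


def group_comparison(
    matrix: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-event CV and two-group rank-sum p over a counts matrix.

    ``groups`` maps sample id to one of exactly two group labels.  Returns
    a frame with per-event mean, sd, cv_percent and ranksum_p, sorted by
    ranksum_p (the top-of-table view used to scan for sex- or
    breed-differential events).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("group_comparison needs exactly two groups")
    cols_a = [s for s in matrix.columns if groups.get(s) == labels[0]]
    cols_b = [s for s in matrix.columns if groups.get(s) == labels[1]]
    rows = []
    for event_id, row in matrix.iterrows():
        stat = cv(row.values, event_id=event_id)
        rs = ranksum_exact(row[cols_a].values, row[cols_b].values)
        rows.append(
            {
                "event_id": event_id,
                "mean": stat.mean,
                "sd": stat.sd,
                "cv_percent": stat.cv_percent,
                "ranksum_p": rs.pvalue,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["ranksum_p", "event_id"], kind="mergesort")
        .reset_index(drop=True)
    )
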