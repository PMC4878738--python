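"""Independent brute-force oracles for interval operations.

Deliberately naive — all-pairs scans and per-base bitmaps — and kept free of
any chrombound internals beyond the plain dataclasses, so that agreement with
the package's vectorized/tree-based implementations is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_overlap(a: tuple, b: tuple, min_bp: int = 1) -> bool:
    """a, b = (chrom, start, end)."""
    if a[0] != b[0]:
        return False
    return min(a[2], b[2]) - max(a[1], b[1]) >= min_bp


def brute_overlap_mask(a_list, b_list, min_bp: int = 1):
    return [any(brute_overlap(a, b, min_bp) for b in b_list) for a in a_list]


def brute_merge(intervals, max_gap: int):
    """Repeated pairwise joining until fixed point; order-independent."""
    regions = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                if a[0] != b[0]:
                    continue
                gap = max(b[1] - a[2], a[1] - b[2])
                if gap <= max_gap:
                    regions[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    regions.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(r) for r in regions)


def brute_distance(a: tuple, b: tuple):
    """Coordinate-gap distance; b may be (chrom, start, end) or (chrom, pos)."""
    if a[0] != b[0]:
        return None
    if len(b) == 2:
        return max(0, a[1] - b[1], b[1] - a[2])
    return max(0, b[1] - a[2], a[1] - b[2])


def brute_within_distance(queries, anchors, d: int):
    q_hits = [
        any(
            (dist := brute_distance(q, a)) is not None and dist <= d for a in anchors
        )
        for q in queries
    ]
    a_hits = [
        any(
            (dist := brute_distance(q, a)) is not None and dist <= d for q in queries
        )
        for a in anchors
    ]
    return q_hits, a_hits


def bitmap_bin_labels(genes, chrom: str, size: int, gaps, promoter_d=1000, distal_d=50000):
    """Per-base bin labels for one toy chromosome.

    genes: list of (strand, tss, tes) on this chromosome.
    gaps: list of (start, end).
    Returns an array of bin-name strings, one per base.
    """
    RANK = {
        "promoter": 0,
        "downstream": 1,
        "genic": 2,
        "five_prime_distal": 3,
        "three_prime_distal": 4,
        "intergenic": 5,
        "unassigned_gap": 6,
    }
    NAMES = {v: k for k, v in RANK.items()}
    rank = np.full(size, RANK["intergenic"], dtype=np.int8)

    def paint(lo, hi, r):
        lo, hi = max(0, lo), min(size, hi)
        if lo < hi:
            rank[lo:hi] = np.minimum(rank[lo:hi], r)

    for strand, tss, tes in genes:
        lo, hi = min(tss, tes), max(tss, tes)
        paint(tss - promoter_d, tss + promoter_d, RANK["promoter"])
        paint(tes - promoter_d, tes + promoter_d, RANK["downstream"])
        paint(lo, hi, RANK["genic"])
        if strand == "+":
            paint(tss - distal_d, tss - promoter_d, RANK["five_prime_distal"])
            paint(tes + promoter_d, tes + distal_d, RANK["three_prime_distal"])
        else:
            paint(tss + promoter_d, tss + distal_d, RANK["five_prime_distal"])
            paint(tes - distal_d, tes - promoter_d, RANK["three_prime_distal"])
    for lo, hi in gaps:
        rank[max(0, lo):min(size, hi)] = RANK["unassigned_gap"]
    return np.array([NAMES[r] for r in rank])


def brute_call_domains(windows, min_fold: float, merge_gap: int, min_length: int):
    """windows: list of (chrom, start, end, fold). Composed from brute_merge."""
    enriched = [(c, s, e) for c, s, e, f in windows if f > min_fold]
    merged = brute_merge(enriched, merge_gap)
    return [m for m in merged if m[2] - m[1] > min_length]


def rank_sum_exhaustive_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks = _midranks(pooled)
    obs = sum(ranks[i] for i in range(n))
    stats = []
    for combo in combinations(range(n + m), n):
        stats.append(sum(ranks[i] for i in combo))
    stats = np.asarray(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
    return float(p)


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
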