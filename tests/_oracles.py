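"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — enumeration, fixpoint merging,
linear scans — and shares no code path with the package implementation.
"""

from itertools import combinations, groupby

import numpy as np


def brute_loci_max(positions, min_sbs, threshold):
    """Maximal runs with every adjacent gap <= threshold, via groupby on the
    gap flags.  Returns closed index intervals [i, j]."""
    positions = list(positions)
    n = len(positions)
    if n < 2:
        return []
    flags = [positions[k + 1] - positions[k] <= threshold for k in range(n - 1)]
    out = []
    idx = 0
    for ok, grp in groupby(flags):
        length = len(list(grp))
        if ok and length + 1 >= min_sbs:
            out.append((idx, idx + length))
        idx += length
    return out


def brute_loci_mean(positions, min_sbs, threshold):
    """Union of all qualifying mean-IMD windows, merged to a fixpoint."""
    positions = list(positions)
    n = len(positions)
    windows = []
    for i in range(n):
        for j in range(i + min_sbs - 1, n):
            if positions[j] - positions[i] <= threshold * (j - i):
                windows.append([i, j])
    # fixpoint pairwise merge of overlapping closed intervals
    changed = True
    while changed:
        changed = False
        out = []
        for w in windows:
            for o in out:
                if w[0] <= o[1] and o[0] <= w[1]:
                    o[0] = min(o[0], w[0])
                    o[1] = max(o[1], w[1])
                    changed = True
                    break
            else:
                out.append(list(w))
        windows = out
    return sorted((a, b) for a, b in windows)


def naive_merge(intervals):
    """O(n^2) fixpoint merge of half-open intervals (adjacency merges too)."""
    ivs = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        for iv in ivs:
            for o in out:
                if iv[0] <= o[1] and o[0] <= iv[1]:  # overlap or touch
                    o[0] = min(o[0], iv[0])
                    o[1] = max(o[1], iv[1])
                    changed = True
                    break
            else:
                out.append(list(iv))
        ivs = out
    return sorted((a, b) for a, b in ivs)


def linear_scan_membership(position, intervals):
    """1-based position vs half-open interval list."""
    coord = position - 1
    return any(s <= coord < e for s, e in intervals)


def linear_scan_bin(position, chrom_lengths, chrom, width):
    """Global bin index by walking every bin edge."""
    idx = 0
    for c, length in chrom_lengths:
        start = 0
        while start < length:
            end = min(start + width, length)
            if c == chrom and start <= position - 1 < end:
                return idx
            idx += 1
            start = end
    raise AssertionError("position not covered")


def exact_wilcoxon_pvalue(x, y):
    """Two-sided exact rank-sum p-value by full enumeration of assignments."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(x), len(y)
    observed = sum(ranks[v] for v in x)
    mean = n * (n + m + 1) / 2
    stats = [
        sum(idx) for idx in combinations(range(1, n + m + 1), n)
    ]
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


def bh_stepup(pvalues):
    """Textbook BH step-up: p_(i) * m / i, cumulative min from the top."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted
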