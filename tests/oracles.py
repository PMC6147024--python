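"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles (substring
scanning, per-read tallies, enumeration) without touching the package's
implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_digest(seq: str) -> list[tuple[int, int]]:
    """Fragments by naive substring scanning: cut 1 bp after every CCGG."""
    cuts = []
    for i in range(len(seq) - 3):
        if seq[i : i + 4] == "CCGG":
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(seq)]
    return [(s, e) for s, e in zip(bounds[:-1], bounds[1:]) if s < e]


def brute_force_fragment_proportion(
    records: list[tuple[int, int, int]], frag: tuple[int, int]
) -> tuple[float | None, int]:
    """Per-read tally of (pos, n_meth, n_unmeth) records within a fragment.

    Counts every methylated and unmethylated read one by one.
    """
    meth_reads = 0
    total_reads = 0
    for pos, n_meth, n_unmeth in records:
        if frag[0] <= pos < frag[1]:
            for _ in range(n_meth):
                meth_reads += 1
                total_reads += 1
            for _ in range(n_unmeth):
                total_reads += 1
    if total_reads == 0:
        return None, 0
    return meth_reads / total_reads, total_reads


def brute_force_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values by direct procedure."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(1.0, pvalues[i] * m / rank_from_end)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


def brute_force_anova(a: list[float], b: list[float]) -> tuple[float, float]:
    """One-way ANOVA for two groups from the defining sums of squares."""
    import scipy.stats

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    grand = (sum(a) + sum(b)) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
    dfb, dfw = 1, na + nb - 2
    F = (ssb / dfb) / (ssw / dfw)
    p = scipy.stats.f.sf(F, dfb, dfw)
    return F, float(p)


def average_ranks(values: list[float]) -> list[float]:
    """Average ranks with ties, derived by sorting alone."""
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


def brute_force_spearman(x: list[float], y: list[float]) -> float:
    """Rank (average ties), then Pearson from the defining formula."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_force_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating draws for small universes (N <= 12 feasible)."""
    universe = list(range(N))
    annotated = set(range(K))
    count = 0
    total = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(annotated.intersection(combo)) >= k:
            count += 1
    return count / total


def brute_force_overlap(
    iv1: tuple[int, int], iv2: tuple[int, int]
) -> int:
    """Per-base interval intersection size."""
    return len(set(range(*iv1)) & set(range(*iv2)))
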