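"""Independent brute-force oracles used by the test suite.

Each oracle deliberately uses the naive O(n*m) / scan formulation so it
shares no code path with the package implementation it checks.
"""
from __future__ import annotations

import numpy as np

from methseek.core import MethylationSite


def depth_by_membership(alignments, window) -> list[int]:
    """Per-base depth by literal membership testing, O(n * L)."""
    out = []
    for pos in range(window.start, window.end):
        out.append(
            sum(
                1
                for iv in alignments
                if iv.contig == window.contig and iv.start <= pos < iv.end
            )
        )
    return out


def maximal_runs(depth, threshold, min_width=1) -> list[tuple[int, int]]:
    """Maximal runs of depth >= threshold by explicit left-to-right scan;
    returns window-relative [start, end) pairs."""
    runs = []
    i, n = 0, len(depth)
    while i < n:
        if depth[i] >= threshold:
            j = i
            while j < n and depth[j] >= threshold:
                j += 1
            if j - i >= min_width:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def merge_closure(sites, dist) -> list[tuple[str, int, int]]:
    """Fixed-point merging by repeated full pairwise scans: build the
    direct-merge adjacency matrix, take connected components by BFS, merge
    each to its envelope, and repeat until nothing changes."""
    spans = [(s.contig, s.start, s.end) for s in sites]
    while True:
        n = len(spans)
        adj = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                ci, si, ei = spans[i]
                cj, sj, ej = spans[j]
                adj[i][j] = ci == cj and abs(si - sj) <= dist and abs(ei - ej) <= dist
        seen, merged = [False] * n, []
        for i in range(n):
            if seen[i]:
                continue
            queue, comp = [i], []
            seen[i] = True
            while queue:
                k = queue.pop()
                comp.append(k)
                for j in range(n):
                    if adj[k][j] and not seen[j]:
                        seen[j] = True
                        queue.append(j)
            merged.append(
                (
                    spans[comp[0]][0],
                    min(spans[k][1] for k in comp),
                    max(spans[k][2] for k in comp),
                )
            )
        if len(merged) == len(spans):
            return sorted(merged)
        spans = merged


def overlap_counts(alignments_by_sample, sites, samples) -> np.ndarray:
    """counts[i][j] by testing every (site, alignment) pair."""
    counts = np.zeros((len(sites), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        for iv in alignments_by_sample.get(sample, ()):
            for i, site in enumerate(sites):
                if iv.contig == site.contig and iv.start < site.end and iv.end > site.start:
                    counts[i, j] += 1
    return counts


def bh_step_up(pvals) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def median_of_ratios(counts) -> np.ndarray:
    """Size factors by the textbook recipe, in pure Python: per sample, the
    median log-ratio of count to the per-site geometric mean (over sites
    where every sample is positive), exponentiated."""
    import math
    import statistics

    x = np.asarray(counts, dtype=float)
    keep = [i for i in range(x.shape[0]) if (x[i] > 0).all()]
    factors = []
    for j in range(x.shape[1]):
        ratios = []
        for i in keep:
            geo = math.exp(sum(math.log(v) for v in x[i]) / x.shape[1])
            ratios.append(math.log(x[i, j] / geo))
        factors.append(math.exp(statistics.median(ratios)))
    return np.array(factors)


def random_sites(rng, n, contig="chr1", span=10_000, max_len=400) -> list[MethylationSite]:
    sites = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        sites.append(MethylationSite(contig, start, start + length))
    return sites
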