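"""Master-list compilation, near-duplicate site merging, and read counting.

Per-sample peak lists from both conditions are pooled into a master list;
sites whose start AND stop coordinates each lie within ``merge_dist`` bases
(default 100) of one another are merged into a single site spanning the
outermost coordinates.  Merging is applied through connected components of
that predicate, repeated until a fixed point, so the result is independent
of input order and idempotent.  Counting then assigns each sample's
fragments to every consolidated site they overlap by at least one base.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import AlignmentInterval, ContigTable, MethylationSite


@dataclass(frozen=True)
class MergeParams:
    merge_dist: int = 100

    def __post_init__(self) -> None:
        if self.merge_dist < 0:
            raise ValueError("merge_dist must be >= 0")


@dataclass
class CountMatrix:
    """Sites x samples integer fragment counts with condition labels."""

    sites: list[MethylationSite]
    samples: list[str]
    counts: np.ndarray
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int).reshape(len(self.sites), len(self.samples))
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")
        missing = [s for s in self.samples if s not in self.condition]
        if self.condition and missing:
            raise ValueError(f"samples without a condition label: {missing}")

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.site_ids == other.site_ids
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
            and self.condition == other.condition
        )


def _sort_key(contigs: ContigTable | None):
    if contigs is None:
        return lambda s: (s.contig, s.start, s.end)
    return lambda s: (contigs.order(s.contig), s.start, s.end)


def compile_master_list(
    per_sample_peaks: Sequence[Sequence[MethylationSite]],
    contigs: ContigTable | None = None,
) -> list[MethylationSite]:
    """Union of all samples' peaks; exact-duplicate intervals collapse with
    merged provenance.  Sorted by (contig order, start, end)."""
    pooled: dict[tuple[str, int, int], set] = {}
    for peaks in per_sample_peaks:
        for site in peaks:
            if contigs is not None and site.contig not in contigs:
                raise ValueError(f"site on unknown contig: {site.contig!r}")
            pooled.setdefault(site.interval(), set()).update(site.source)
    out = [
        MethylationSite(contig, start, end, frozenset(prov))
        for (contig, start, end), prov in pooled.items()
    ]
    out.sort(key=_sort_key(contigs))
    return out


def _mergeable(a: MethylationSite, b: MethylationSite, dist: int) -> bool:
    return abs(a.start - b.start) <= dist and abs(a.end - b.end) <= dist


def _merge_round(sites: list[MethylationSite], dist: int) -> tuple[list[MethylationSite], bool]:
    """One round: connected components of the direct-merge predicate on the
    current sites (same contig only), each collapsed to its envelope span."""
    order = sorted(range(len(sites)), key=lambda i: (sites[i].contig, sites[i].start, sites[i].end))
    parent = list(range(len(sites)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sites sorted by start: only pairs with start gap <= dist can merge
    for a_pos, i in enumerate(order):
        si = sites[i]
        for j in order[a_pos + 1:]:
            sj = sites[j]
            if sj.contig != si.contig or sj.start - si.start > dist:
                break
            if abs(si.end - sj.end) <= dist:
                union(i, j)

    groups: dict[int, list[MethylationSite]] = {}
    for i in range(len(sites)):
        groups.setdefault(find(i), []).append(sites[i])
    merged = [
        MethylationSite(
            members[0].contig,
            min(m.start for m in members),
            max(m.end for m in members),
            frozenset().union(*(m.source for m in members)),
        )
        for members in groups.values()
    ]
    return merged, len(merged) < len(sites)


def merge_sites(
    sites: Sequence[MethylationSite],
    params: MergeParams = MergeParams(),
    contigs: ContigTable | None = None,
) -> list[MethylationSite]:
    """Merge near-identical sites (both boundaries within ``merge_dist``).

    Sites linked through a chain merge even when the chain's extremes differ
    by more than ``merge_dist``; with ``merge_dist`` 0 only exactly identical
    intervals collapse.  Idempotent: merging its own output changes nothing.
    """
    current = list(sites)
    changed = True
    while changed:
        current, changed = _merge_round(current, params.merge_dist)
    current.sort(key=_sort_key(contigs))
    return current


def count_reads_per_site(
    alignments_by_sample: Mapping[str, Sequence[AlignmentInterval]],
    sites: Sequence[MethylationSite],
    samples: Sequence[str],
    condition: Mapping[str, str],
) -> CountMatrix:
    """counts[i][j] = sample j's fragments overlapping site i by >= 1 base.

    A fragment overlapping two sites increments both; there is no unique
    assignment.  Condition label sets of size != 2 only warn (the screen
    stage requires exactly two).
    """
    import logging

    labels = {condition[s] for s in samples if s in condition}
    if condition and len(labels) != 2:
        logging.getLogger(__name__).warning(
            "expected exactly 2 condition labels, got %d: %s", len(labels), sorted(labels)
        )
    trees: dict[str, IntervalTree] = {}
    for i, site in enumerate(sites):
        trees.setdefault(site.contig, IntervalTree()).addi(site.start, site.end, i)

    counts = np.zeros((len(sites), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        for iv in alignments_by_sample.get(sample, ()):
            tree = trees.get(iv.contig)
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                counts[hit.data, j] += 1
    return CountMatrix(list(sites), list(samples), counts, dict(condition))
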