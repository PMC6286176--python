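"""The methSeek core: per-base depth and depth-threshold peak calling.

A methylation peak is a maximal run of consecutive bases whose fragment
depth meets the threshold (default 10), scanned within a promoter or
intragenic window: the first base of a peak has depth >= threshold and the
base just past its 3' end has depth < threshold or lies outside the window.
Peaks are reported in genome coordinates, clipped at window boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import AlignmentInterval, GenomicWindow, MethylationSite, Provenance


@dataclass(frozen=True)
class PeakParams:
    depth_threshold: int = 10
    min_width: int = 1

    def __post_init__(self) -> None:
        if self.depth_threshold < 1:
            raise ValueError("depth_threshold must be >= 1")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass
class DepthProfile:
    """Per-base fragment depth over one window."""

    window: GenomicWindow
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape != (len(self.window),):
            raise ValueError("depth vector length must equal window length")


def compute_depth(alignments: Iterable[AlignmentInterval], window: GenomicWindow) -> DepthProfile:
    """Depth[i] = number of fragments overlapping base ``window.start + i``.

    Fragments count over their full aligned span; the parts of a fragment
    outside the window contribute nothing.  Implemented with a difference
    array, which the tests hold to a per-base membership oracle.
    """
    diff = np.zeros(len(window) + 1, dtype=np.int64)
    for iv in alignments:
        if iv.contig != window.contig:
            continue
        lo = max(iv.start, window.start) - window.start
        hi = min(iv.end, window.end) - window.start
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    return DepthProfile(window, np.cumsum(diff[:-1]))


def call_peaks(profile: DepthProfile, params: PeakParams = PeakParams()) -> list[MethylationSite]:
    """Maximal runs of depth >= threshold, as genome-coordinate sites.

    Runs shorter than ``min_width`` are discarded; output is sorted by start
    and never extends beyond the window.
    """
    w = profile.window
    above = np.concatenate(([False], profile.depth >= params.depth_threshold, [False]))
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    prov: frozenset[Provenance] = frozenset({("", w.transcript_id, w.region_kind)})
    return [
        MethylationSite(w.contig, w.start + int(s), w.start + int(e), prov)
        for s, e in zip(starts, ends)
        if e - s >= params.min_width
    ]


def _index_alignments(
    alignments: Sequence[AlignmentInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Per contig: fragment (starts, ends) sorted by start, plus the longest
    fragment length, for windowed depth queries."""
    buckets: dict[str, list[tuple[int, int]]] = {}
    for iv in alignments:
        buckets.setdefault(iv.contig, []).append((iv.start, iv.end))
    index = {}
    for contig, spans in buckets.items():
        spans.sort()
        arr = np.asarray(spans, dtype=np.int64)
        index[contig] = (arr[:, 0], arr[:, 1], int((arr[:, 1] - arr[:, 0]).max()))
    return index


def _windowed_depth(
    index: dict[str, tuple[np.ndarray, np.ndarray, int]], window: GenomicWindow
) -> DepthProfile:
    """Same per-base depth as ``compute_depth``, restricted up front to the
    fragments that can overlap the window (their starts lie within one
    maximal fragment length of it)."""
    entry = index.get(window.contig)
    if entry is None:
        return DepthProfile(window, np.zeros(len(window), dtype=np.int64))
    starts, ends, maxlen = entry
    lo = np.searchsorted(starts, window.start - maxlen, side="left")
    hi = np.searchsorted(starts, window.end, side="left")
    s = np.clip(starts[lo:hi], window.start, window.end) - window.start
    e = np.clip(ends[lo:hi], window.start, window.end) - window.start
    keep = e > s
    diff = np.zeros(len(window) + 1, dtype=np.int64)
    np.add.at(diff, s[keep], 1)
    np.add.at(diff, e[keep], -1)
    return DepthProfile(window, np.cumsum(diff[:-1]))


def call_sample_peaks(
    alignments: Sequence[AlignmentInterval],
    windows: Sequence[GenomicWindow],
    params: PeakParams = PeakParams(),
    sample_id: str = "",
) -> list[MethylationSite]:
    """Call peaks over every window for one sample.

    Overlapping windows are scanned independently; identical peak intervals
    produced by different windows are collapsed to one site with the merged
    provenance.
    """
    index = _index_alignments(alignments)
    merged: dict[tuple[str, int, int], set[Provenance]] = {}
    for w in windows:
        profile = _windowed_depth(index, w)
        for site in call_peaks(profile, params):
            key = site.interval()
            prov = merged.setdefault(key, set())
            prov.add((sample_id, w.transcript_id, w.region_kind))
    return [
        MethylationSite(contig, start, end, frozenset(prov))
        for (contig, start, end), prov in sorted(merged.items())
    ]
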