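"""Promoter and intragenic scan windows derived from transcripts.

The promoter window covers ``up`` bases upstream of the TSS and ``down``
bases downstream, where the downstream segment includes the TSS base itself,
so an unclipped window is exactly ``up + down`` bases wide.  Defaults are
5000 bp upstream / 2000 bp downstream.  On the minus strand the TSS is the
rightmost transcribed base and "upstream" extends toward larger genomic
coordinates.  Windows are clipped (not dropped) at contig edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .core import ContigTable, GenomicWindow, TranscriptRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowParams:
    up: int = 5000
    down: int = 2000

    def __post_init__(self) -> None:
        if self.up < 0 or self.down < 1 or self.up + self.down < 1:
            raise ValueError(f"invalid window params up={self.up}, down={self.down}")


def tss_position(t: TranscriptRecord) -> int:
    """0-based genomic position of the first transcribed base."""
    return t.start if t.strand == "+" else t.end - 1


def promoter_window(
    t: TranscriptRecord, params: WindowParams, contigs: ContigTable
) -> GenomicWindow | None:
    """Strand-aware promoter window around the TSS, clipped to the contig.

    Returns ``None`` (with a warning) for the pathological case where
    clipping empties the window entirely.
    """
    s = tss_position(t)
    if t.strand == "+":
        raw_start, raw_end = s - params.up, s + params.down
    else:
        raw_start, raw_end = s - params.down + 1, s + params.up + 1
    start = max(0, raw_start)
    end = min(contigs.length(t.contig), raw_end)
    if start >= end:
        log.warning("transcript %s: promoter window empty after clipping; skipped", t.transcript_id)
        return None
    return GenomicWindow(t.contig, start, end, t.transcript_id, "promoter", t.strand)


def intragenic_window(t: TranscriptRecord, contigs: ContigTable) -> GenomicWindow:
    """The full transcript span, as the intragenic scan region."""
    end = min(contigs.length(t.contig), t.end)
    return GenomicWindow(t.contig, t.start, end, t.transcript_id, "intragenic", t.strand)


def build_windows(
    transcripts: Iterable[TranscriptRecord],
    contigs: ContigTable,
    params: WindowParams = WindowParams(),
    region: str = "promoter",
) -> list[GenomicWindow]:
    """Windows for every transcript; ``region`` is promoter, intragenic or both.

    Windows from different transcripts may overlap; overlaps are resolved
    downstream by consolidation, not here.
    """
    if region not in ("promoter", "intragenic", "both"):
        raise ValueError(f"region must be promoter, intragenic or both, got {region!r}")
    windows: list[GenomicWindow] = []
    for t in transcripts:
        if region in ("promoter", "both"):
            w = promoter_window(t, params, contigs)
            if w is not None:
                windows.append(w)
        if region in ("intragenic", "both"):
            windows.append(intragenic_window(t, contigs))
    return windows
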