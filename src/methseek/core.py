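"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based half-open (BED-native) everywhere in this
package; format readers perform the only conversions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


class ContigTable:
    """Ordered contig-name -> length map defining the coordinate universe.

    Contig order is preserved from the source file and used as the primary
    sort key for genomic output.
    """

    def __init__(self, entries: Iterable[tuple[str, int]] = ()):
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self._lengths:
            raise ValueError(f"duplicate contig name: {name!r}")
        if not isinstance(length, int) or isinstance(length, bool) or length < 1:
            raise ValueError(f"contig {name!r}: length must be a positive integer, got {length!r}")
        self._lengths[name] = length

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContigTable):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def length(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise KeyError(f"unknown contig: {name!r}") from None

    def order(self, name: str) -> int:
        """Rank of *name* in file order; sort key for genomic sorting."""
        try:
            return list(self._lengths).index(name)
        except ValueError:
            raise KeyError(f"unknown contig: {name!r}") from None

    def items(self) -> Iterable[tuple[str, int]]:
        return self._lengths.items()

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:
        return f"ContigTable({list(self._lengths.items())!r})"


@dataclass(frozen=True)
class AlignmentInterval:
    """One aligned, strandless MBD-enriched fragment span."""

    contig: str
    start: int
    end: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def validate(self, contigs: ContigTable) -> None:
        if self.contig not in contigs:
            raise ValueError(f"unknown contig: {self.contig!r}")
        if self.end > contigs.length(self.contig):
            raise ValueError(
                f"interval {self.contig}:{self.start}-{self.end} exceeds contig "
                f"length {contigs.length(self.contig)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript span with strand; the source of TSS positions."""

    transcript_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"transcript {self.transcript_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomicWindow:
    """A promoter or intragenic scan region derived from one transcript."""

    contig: str
    start: int
    end: int
    transcript_id: str
    region_kind: str  # "promoter" | "intragenic"
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty window")
        if self.region_kind not in ("promoter", "intragenic"):
            raise ValueError(f"bad region_kind {self.region_kind!r}")

    def __len__(self) -> int:
        return self.end - self.start


# provenance entry: (sample_id, transcript_id, region_kind)
Provenance = tuple[str, str, str]


@dataclass
class MethylationSite:
    """A called or consolidated methylation peak interval."""

    contig: str
    start: int
    end: int
    source: frozenset[Provenance] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid site [{self.start}, {self.end})")
        self.source = frozenset(self.source)

    @property
    def site_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationSite):
            return NotImplemented
        return self.interval() == other.interval() and self.source == other.source

    def __hash__(self) -> int:
        return hash((self.interval(), self.source))
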