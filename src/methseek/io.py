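"""Readers and writers for every external format the pipeline touches.

Formats: two-column contig sizes, BED3+ alignments, GTF / BED6 transcripts,
BED4 methylation sites, TSV count matrices.  All conversion between the
external coordinate conventions (GTF is 1-based inclusive) and the internal
0-based half-open convention happens here and nowhere else.
"""
from __future__ import annotations

import logging
from os import PathLike
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

from .core import AlignmentInterval, ContigTable, MethylationSite, TranscriptRecord
from .consolidate import CountMatrix

log = logging.getLogger(__name__)

Pathish = str | PathLike


def read_contig_sizes(path: Pathish) -> ContigTable:
    """Parse a whitespace-delimited ``name length`` table, preserving order.

    Raises ``ValueError`` naming the offending line on duplicate contigs or
    non-positive / non-integer lengths.
    """
    table = ContigTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer contig length {raw_len!r}") from None
            try:
                table.add(name, length)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return table


def write_contig_sizes(contigs: ContigTable, path: Pathish) -> None:
    with open(path, "w") as fh:
        for name, length in contigs.items():
            fh.write(f"{name}\t{length}\n")


def read_alignments_bed(
    path: Pathish, contigs: ContigTable, sample_id: str = ""
) -> list[AlignmentInterval]:
    """Read BED3+ aligned fragments; columns past the third are ignored.

    Every interval is validated against *contigs*: unknown contigs and
    out-of-bounds spans are hard errors.
    """
    out: list[AlignmentInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                iv = AlignmentInterval(fields[0], int(fields[1]), int(fields[2]), sample_id)
                iv.validate(contigs)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_alignments_bed(alignments: Iterable[AlignmentInterval], path: Pathish) -> None:
    with open(path, "w") as fh:
        for iv in alignments:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_alignments_bam(path: Pathish, contigs: ContigTable, sample_id: str = "") -> list[AlignmentInterval]:
    """Optional BAM adapter: project each primary, mapped, non-duplicate
    alignment to its reference span.  BED remains the canonical format."""
    import pysam  # deferred: binary-format convenience only

    out: list[AlignmentInterval] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            iv = AlignmentInterval(rec.reference_name, rec.reference_start, rec.reference_end, sample_id)
            iv.validate(contigs)
            out.append(iv)
    return out


def read_transcripts(
    path: Pathish,
    format: str,
    contigs: ContigTable,
    feature_type: str = "transcript",
) -> list[TranscriptRecord]:
    """Read a transcript annotation as GTF or BED6.

    GTF records (1-based inclusive) of *feature_type* are converted to the
    internal 0-based half-open convention; BED6 is taken as-is.  Transcripts
    on contigs absent from *contigs* are dropped with one warning giving the
    count; out-of-bounds coordinates on known contigs are hard errors.
    """
    if format not in ("gtf", "bed6"):
        raise ValueError(f"format must be 'gtf' or 'bed6', got {format!r}")
    records: list[TranscriptRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if format == "gtf":
                feat = feature_from_line(line)
                if feat.featuretype != feature_type:
                    continue
                if feat.strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: transcript without strand")
                if "transcript_id" not in feat.attributes:
                    raise ValueError(f"{path}:{lineno}: missing transcript_id attribute")
                rec = TranscriptRecord(
                    transcript_id=feat.attributes["transcript_id"][0],
                    contig=feat.seqid,
                    start=feat.start - 1,  # GTF 1-based inclusive -> 0-based half-open
                    end=feat.end,
                    strand=feat.strand,
                )
            else:
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
                rec = TranscriptRecord(
                    transcript_id=fields[3],
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                )
            if rec.contig not in contigs:
                dropped += 1
                continue
            if rec.end > contigs.length(rec.contig):
                raise ValueError(
                    f"{path}:{lineno}: transcript {rec.transcript_id} exceeds contig bounds"
                )
            records.append(rec)
    if dropped:
        log.warning("%s: dropped %d transcript(s) on contigs absent from the contig table", path, dropped)
    return records


def write_transcripts_gtf(transcripts: Iterable[TranscriptRecord], path: Pathish, source: str = "methseek") -> None:
    """Write transcripts as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.contig}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )


def write_sites_bed(sites: Sequence[MethylationSite], path: Pathish) -> None:
    """Write sites as BED4 with name ``contig:start-end``.

    Sites must be pre-sorted with unique ids (a consolidated list).
    """
    seen: set[str] = set()
    with open(path, "w") as fh:
        for s in sites:
            if s.site_id in seen:
                raise ValueError(f"duplicate site id: {s.site_id}")
            seen.add(s.site_id)
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.site_id}\n")


def read_sites_bed(path: Pathish, contigs: ContigTable | None = None) -> list[MethylationSite]:
    sites: list[MethylationSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            site = MethylationSite(fields[0], int(fields[1]), int(fields[2]))
            if contigs is not None and site.contig not in contigs:
                raise ValueError(f"{path}:{lineno}: unknown contig {site.contig!r}")
            sites.append(site)
    return sites


def write_count_matrix(matrix: CountMatrix, path: Pathish) -> None:
    """Write a count matrix as TSV: ``site`` id column, one column per sample,
    integer cells.  Condition labels go in a leading ``# condition:`` comment
    so the file round-trips to an equal in-memory object."""
    with open(path, "w") as fh:
        cond = "\t".join(f"{s}={matrix.condition[s]}" for s in matrix.samples)
        fh.write(f"# condition: {cond}\n" if matrix.condition else "# condition:\n")
        fh.write("site\t" + "\t".join(matrix.samples) + "\n")
        for i, site in enumerate(matrix.sites):
            row = "\t".join(str(int(c)) for c in matrix.counts[i])
            fh.write(f"{site.site_id}\t{row}\n" if matrix.samples else f"{site.site_id}\n")


def read_count_matrix(path: Pathish) -> CountMatrix:
    import numpy as np

    condition: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# condition:"):
            raise ValueError(f"{path}: missing '# condition:' header line")
        payload = first[len("# condition:"):].strip()
        if payload:
            for item in payload.split("\t"):
                sample, _, label = item.partition("=")
                condition[sample] = label
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "site":
            raise ValueError(f"{path}: first column must be 'site'")
        samples = header[1:]
        site_ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            site_ids.append(fields[0])
            rows.append([int(x) for x in fields[1:]])
    sites = [_site_from_id(sid) for sid in site_ids]
    counts = np.asarray(rows, dtype=int).reshape(len(sites), len(samples))
    return CountMatrix(sites=sites, samples=samples, counts=counts, condition=condition)


def _site_from_id(site_id: str) -> MethylationSite:
    contig, _, span = site_id.rpartition(":")
    start, _, end = span.partition("-")
    if not contig or not start or not end:
        raise ValueError(f"malformed site id: {site_id!r}")
    return MethylationSite(contig, int(start), int(end))
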