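"""End-to-end orchestration: peaks per sample -> master list -> merge ->
count -> screen, with plain-text intermediates between every stage."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as gio
from .annotation import WindowParams, build_windows
from .consolidate import CountMatrix, MergeParams, compile_master_list, count_reads_per_site, merge_sites
from .core import AlignmentInterval, ContigTable, MethylationSite
from .peaks import PeakParams, call_sample_peaks
from .screen import ScreenParams, run_screen

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    master_sites: list[MethylationSite]
    matrix: CountMatrix
    screen_table: pd.DataFrame
    per_sample_peaks: dict[str, list[MethylationSite]] = field(default_factory=dict)


def run_pipeline(
    alignments_by_sample: Mapping[str, Sequence[AlignmentInterval]],
    transcripts,
    contigs: ContigTable,
    condition: Mapping[str, str],
    window_params: WindowParams = WindowParams(),
    peak_params: PeakParams = PeakParams(),
    merge_params: MergeParams = MergeParams(),
    screen_params: ScreenParams = ScreenParams(),
    region: str = "promoter",
    permutations: bool = True,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage in memory; if *outdir* is given, also write each
    stage's output (per-sample peak BEDs, master.bed, counts.tsv,
    screen.tsv) so any stage can be swapped for an external tool."""
    windows = build_windows(transcripts, contigs, window_params, region)
    log.info("built %d %s window(s) from %d transcript(s)", len(windows), region, len(transcripts))

    per_sample: dict[str, list[MethylationSite]] = {}
    for sample, alns in alignments_by_sample.items():
        peaks = call_sample_peaks(alns, windows, peak_params, sample)
        log.info("sample %s: %d peak(s)", sample, len(peaks))
        per_sample[sample] = peaks

    master = compile_master_list(list(per_sample.values()), contigs)
    log.info("master list: %d site(s)", len(master))
    merged = merge_sites(master, merge_params, contigs)
    log.info("consolidated: %d site(s) after merging", len(merged))

    samples = list(alignments_by_sample)
    matrix = count_reads_per_site(alignments_by_sample, merged, samples, condition)
    table = run_screen(matrix, screen_params, permutations=permutations)
    log.info("screen: %d of %d site(s) flagged", int(table["flagged"].sum()), len(table))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, peaks in per_sample.items():
            gio.write_sites_bed(peaks, outdir / f"{sample}.peaks.bed")
        gio.write_sites_bed(merged, outdir / "master.bed")
        gio.write_count_matrix(matrix, outdir / "counts.tsv")
        table.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    return PipelineResult(merged, matrix, table, per_sample)
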