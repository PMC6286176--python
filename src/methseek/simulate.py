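"""Synthetic MBD-Seq dataset generator with planted ground truth.

Emulates sonicated-fragment MBD enrichment: fragment lengths follow a
triangular distribution with hard bounds 200-500 bp and mode 350 bp
(matching a target modal sonication size of 200-500 bp), methylated
promoter regions receive Poisson fragment pile-ups at a target depth, and
a uniform Poisson background covers the rest of the genome.  Two
conditions (M1/M2) x ``n_samples_per_condition`` replicates are written as
plain BED files together with the genome, annotation and truth, so the
whole pipeline is testable offline.  Everything derives from one seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import AlignmentInterval, ContigTable, GenomicWindow, MethylationSite, TranscriptRecord
from .annotation import WindowParams, promoter_window
from . import io as gio


@dataclass(frozen=True)
class SimConfig:
    n_contigs: int = 2
    contig_length: int = 1_000_000
    n_transcripts: int = 50
    tx_len_min: int = 2000
    tx_len_max: int = 8000
    strand_fraction: float = 0.5
    planted_fraction: float = 0.4
    planted_region_width: int = 1500
    enriched_depth: float = 20.0
    background_rate: float = 1.0  # expected background fragments per kb
    frag_len_min: int = 200
    frag_len_mode: int = 350
    frag_len_max: int = 500
    n_samples_per_condition: int = 4
    differential_effect: float = 1.0
    diff_fraction: float = 0.0
    window: WindowParams = field(default_factory=WindowParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frag_len_min <= self.frag_len_mode <= self.frag_len_max):
            raise ValueError("fragment lengths must satisfy min <= mode <= max")
        for frac in (self.strand_fraction, self.planted_fraction, self.diff_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.background_rate < 0 or self.enriched_depth < 0:
            raise ValueError("rates must be >= 0")
        if self.planted_region_width < 1 or self.tx_len_min < 1:
            raise ValueError("widths must be >= 1")

    @property
    def mean_frag_len(self) -> float:
        return (self.frag_len_min + self.frag_len_mode + self.frag_len_max) / 3.0


@dataclass
class SimTruth:
    """Planted regions with per-region condition multipliers and the
    realized per-sample fragment counts."""

    regions: list[MethylationSite]
    multipliers: list[float]  # effect applied in condition M1
    fragment_counts: dict[str, int]

    def differential_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.multipliers) if m != 1.0]


def _footprint(t: TranscriptRecord, w: WindowParams) -> tuple[int, int]:
    """Unclipped span of the transcript plus its promoter window."""
    if t.strand == "+":
        win = (t.start - w.up, t.start + w.down)
    else:
        win = (t.end - w.down, t.end + w.up)
    return (min(t.start, win[0]), max(t.end, win[1]))


def _place_transcripts(cfg: SimConfig, contigs: ContigTable, rng: np.random.Generator) -> list[TranscriptRecord]:
    """Uniform placement by rejection sampling.

    Whole scan footprints (transcript plus promoter window) are kept
    disjoint, so planted regions of different transcripts never overlap and
    every called site attributes to a unique planted locus.
    """
    names = list(contigs)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    out: list[TranscriptRecord] = []
    attempts = 0
    max_attempts = 200 * cfg.n_transcripts + 1000
    while len(out) < cfg.n_transcripts:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place transcripts without overlap; increase contig_length"
            )
        contig = names[rng.integers(len(names))]
        length = int(rng.integers(cfg.tx_len_min, cfg.tx_len_max + 1))
        limit = contigs.length(contig) - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        strand = "+" if rng.random() < cfg.strand_fraction else "-"
        t = TranscriptRecord(f"tx{len(out) + 1:04d}", contig, start, start + length, strand)
        lo, hi = _footprint(t, cfg.window)
        if any(lo < e and hi > s for s, e in placed[contig]):
            continue
        placed[contig].append((lo, hi))
        out.append(t)
    return out


def _plant_regions(
    cfg: SimConfig,
    transcripts: Sequence[TranscriptRecord],
    contigs: ContigTable,
    rng: np.random.Generator,
) -> tuple[list[MethylationSite], list[float]]:
    """Choose methylated promoters; each planted region is centered in its
    promoter window, clipped so it stays inside the window."""
    n_planted = int(round(cfg.planted_fraction * len(transcripts)))
    order = rng.permutation(len(transcripts))[:n_planted]
    regions: list[MethylationSite] = []
    for i in sorted(order):
        t = transcripts[i]
        w = promoter_window(t, cfg.window, contigs)
        if w is None:
            continue
        width = min(cfg.planted_region_width, len(w))
        mid = (w.start + w.end) // 2
        start = max(w.start, mid - width // 2)
        end = min(w.end, start + width)
        regions.append(
            MethylationSite(w.contig, start, end, frozenset({("truth", t.transcript_id, "promoter")}))
        )
    n_diff = int(round(cfg.diff_fraction * len(regions)))
    diff_idx = set(rng.permutation(len(regions))[:n_diff].tolist())
    multipliers = [
        cfg.differential_effect if i in diff_idx else 1.0 for i in range(len(regions))
    ]
    return regions, multipliers


def _draw_fragments(
    cfg: SimConfig,
    contig: str,
    contig_len: int,
    n: int,
    region: tuple[int, int] | None,
    rng: np.random.Generator,
    sample_id: str,
) -> list[AlignmentInterval]:
    """n fragments with triangular lengths; midpoints uniform over *region*
    (or starts uniform over the contig for background).  A fragment whose
    drawn span would cross a contig edge is shifted inward, preserving its
    length (whole sonicated fragments, never truncated ones)."""
    if n == 0:
        return []
    lengths = np.rint(
        rng.triangular(cfg.frag_len_min, cfg.frag_len_mode, cfg.frag_len_max, size=n)
    ).astype(int)
    lengths = np.minimum(lengths, contig_len)
    if region is not None:
        mids = rng.integers(region[0], region[1], size=n)
        starts = mids - lengths // 2
    else:
        starts = rng.integers(0, contig_len, size=n)
    starts = np.clip(starts, 0, contig_len - lengths)
    ends = starts + lengths
    return [
        AlignmentInterval(contig, int(s), int(e), sample_id)
        for s, e in zip(starts, ends)
    ]


def simulate_alignments(
    cfg: SimConfig,
) -> tuple[ContigTable, list[TranscriptRecord], SimTruth, dict[str, list[AlignmentInterval]], dict[str, str]]:
    """Generate the whole dataset in memory.

    Returns (contigs, transcripts, truth, alignments per sample, condition
    map).  Sample ids are ``M1_rep1`` .. ``M2_repN``; the differential
    multiplier applies to condition M1 only.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs = ContigTable(
        (f"chr{i + 1}", cfg.contig_length) for i in range(cfg.n_contigs)
    )
    transcripts = _place_transcripts(cfg, contigs, rng)
    regions, multipliers = _plant_regions(cfg, transcripts, contigs, rng)

    samples: dict[str, list[AlignmentInterval]] = {}
    condition: dict[str, str] = {}
    genome_kb = contigs.total_length() / 1000.0
    for cond in ("M1", "M2"):
        for rep in range(1, cfg.n_samples_per_condition + 1):
            sid = f"{cond}_rep{rep}"
            condition[sid] = cond
            frags: list[AlignmentInterval] = []
            for region, mult in zip(regions, multipliers):
                depth = cfg.enriched_depth * (mult if cond == "M1" else 1.0)
                lam = depth * len(region) / cfg.mean_frag_len
                n = int(rng.poisson(lam))
                frags.extend(
                    _draw_fragments(
                        cfg, region.contig, contigs.length(region.contig), n,
                        (region.start, region.end), rng, sid,
                    )
                )
            for cname in contigs:
                n_bg = int(rng.poisson(cfg.background_rate * contigs.length(cname) / 1000.0))
                frags.extend(
                    _draw_fragments(cfg, cname, contigs.length(cname), n_bg, None, rng, sid)
                )
            frags.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
            samples[sid] = frags
    truth = SimTruth(regions, multipliers, {s: len(v) for s, v in samples.items()})
    return contigs, transcripts, truth, samples, condition


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write {contigs.txt, transcripts.gtf, truth.bed,
    truth.json, <sample>.bed}; all outputs pass the package's readers and
    are byte-identical across reruns with the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, transcripts, truth, samples, condition = simulate_alignments(cfg)

    paths = {
        "contigs": outdir / "contigs.txt",
        "transcripts": outdir / "transcripts.gtf",
        "truth_bed": outdir / "truth.bed",
        "truth_json": outdir / "truth.json",
    }
    gio.write_contig_sizes(contigs, paths["contigs"])
    gio.write_transcripts_gtf(transcripts, paths["transcripts"])
    gio.write_sites_bed(truth.regions, paths["truth_bed"])
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "config": asdict(cfg),
                "regions": [s.site_id for s in truth.regions],
                "multipliers": truth.multipliers,
                "fragment_counts": truth.fragment_counts,
                "condition": condition,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    for sid, frags in samples.items():
        p = outdir / f"{sid}.bed"
        gio.write_alignments_bed(frags, p)
        paths[sid] = p
    return paths


@dataclass
class RecoveryReport:
    recall: float
    precision: float
    mean_boundary_error: float
    within_tolerance: float  # fraction of recovered regions with boundary error <= tol
    n_truth: int
    n_called: int


def evaluate_recovery(
    called: Sequence[MethylationSite],
    truth: SimTruth | Sequence[MethylationSite],
    boundary_tol: int = 100,
) -> RecoveryReport:
    """Compare called sites against planted regions.

    A region is recovered when some called site overlaps it; its boundary
    error is max(|start diff|, |end diff|) against the best-overlapping
    (largest-overlap) site.  Precision is the fraction of called sites
    overlapping any planted region.
    """
    regions = truth.regions if isinstance(truth, SimTruth) else list(truth)
    errors: list[int] = []
    recovered = 0
    for region in regions:
        best, best_ov = None, 0
        for site in called:
            if site.contig != region.contig:
                continue
            ov = min(site.end, region.end) - max(site.start, region.start)
            if ov > best_ov:
                best, best_ov = site, ov
        if best is not None:
            recovered += 1
            errors.append(max(abs(best.start - region.start), abs(best.end - region.end)))
    truth_hit = sum(
        1
        for site in called
        if any(
            site.contig == r.contig and min(site.end, r.end) > max(site.start, r.start)
            for r in regions
        )
    )
    return RecoveryReport(
        recall=recovered / len(regions) if regions else float("nan"),
        precision=truth_hit / len(called) if called else float("nan"),
        mean_boundary_error=float(np.mean(errors)) if errors else float("nan"),
        within_tolerance=(sum(e <= boundary_tol for e in errors) / len(errors)) if errors else float("nan"),
        n_truth=len(regions),
        n_called=len(called),
    )
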