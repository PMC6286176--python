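# Methods

## Coordinate conventions

All coordinates inside the package are 0-based half-open (BED-native);
GTF input (1-based inclusive) is converted on read and converted back on
write. Aligned fragments are strandless spans: MBD capture pulls down
double-stranded fragments, so the sequencing strand carries no signal for
depth. "Depth" counts whole aligned fragments overlapping a base, with
duplicates assumed removed upstream.

## Scan windows

The TSS is the first transcribed base: `start` on the plus strand,
`end − 1` on the minus strand. The promoter window covers `up` bases
upstream of the TSS and `down` bases downstream *including the TSS base*,
so an unclipped window is exactly `up + down` wide (7000 bp at the
defaults up = 5000, down = 2000). On the minus strand upstream means
larger coordinates: the window is `[tss − down + 1, tss + up + 1)`.
Windows are clipped, not dropped, at contig edges, preserving promoters
near assembly ends; a window emptied entirely by clipping is skipped with
a warning. The intragenic window is the full transcript span — the term
is not standardized, and the alternative (gene body minus the downstream
promoter segment) was considered and not implemented. Windows from
different transcripts are scanned independently and may overlap;
consolidation resolves the redundancy afterwards.

## Peak calling

A peak is a maximal run of consecutive bases with depth ≥ `depth_threshold`
(default 10): the first base of a peak meets the threshold and the base
immediately past its end falls below it or lies outside the window.
Peak ends are defined left-to-right in genome coordinates regardless of
transcript strand, which keeps the two conditions symmetric. Peaks are
clipped at window boundaries, since scanning is defined within the
windows. Runs shorter than `min_width` (default 1, i.e. no filter) are
discarded. Depth is computed with a difference array (and, in the
per-sample driver, a start-sorted index so each window touches only the
fragments that can reach it); both paths are held, in tests, to a literal
per-base membership count. Identical peak intervals produced by
overlapping windows collapse to one site carrying the union of their
(sample, transcript, region-kind) provenance.

The enrichment threshold is applied to raw depth, not depth-normalized
coverage, and no input/background track enters the calling decision:
calling is purely absolute-depth based. Users with matched unenriched
input fractions should treat them as separate samples and compare
downstream.

## Consolidation

The master list is the union of per-sample peak lists across all samples
and both conditions, with exact-duplicate intervals collapsed. Two sites
are directly mergeable when |Δstart| ≤ `merge_dist` **and**
|Δend| ≤ `merge_dist` (default 100 bp) — the rule is deliberately about
both boundaries, not about interval gap, so a short peak does not get
absorbed by a distant long one sharing a single boundary. Merging takes
connected components of this relation and collapses each component to its
envelope `[min start, max end)`, repeating until a fixed point. Chains
therefore merge even when their extremes differ by more than
`merge_dist`; the result is independent of input order and idempotent,
and with `merge_dist` 0 only exactly identical intervals collapse. A
consequence worth knowing: peaks from weaker samples that cover only the
center of a region can survive as separate (contained) sites alongside
the full-span site, because their boundaries sit farther than
`merge_dist` inside it. Locus-level summaries should aggregate
overlapping sites.

Counting assigns each fragment to every consolidated site it overlaps by
at least one base; a fragment spanning two sites increments both. There
is no unique-assignment or fractional-overlap logic by default.

## The screen

The built-in screen is a deliberately lightweight substitute for a full
negative-binomial differential analysis; the canonical route remains
exporting `counts.tsv` to a dedicated tool. Its pieces:

* **Size factors** — median-of-ratios: factor_j = exp(median over sites
  with all-positive counts of log(count_ij / geometric-mean_i)). Checked
  in tests against an independent re-implementation and against
  pydeseq2's normalization. Size factors are identifiable only up to a
  common scalar; scaling one sample's library by c multiplies its factor
  *relative to every other sample's* by exactly c (the absolute factors
  move by c^((m−1)/m) and c^(−1/m) because the geometric-mean reference
  moves too), and all log2 fold changes are invariant because the common
  c^(1/m) scale on normalized counts cancels in the ratio.
* **log2FC** — log2((meanA + pc)/(meanB + pc)) of normalized group means
  with pseudocount pc = 1.0, a simple zero-safe choice in place of
  shrinkage estimators; conditions are ordered alphabetically, so with
  labels M1/M2 the ratio is M1/M2. The enrichment flag is strict:
  |log2FC| > 1.0.
* **Permutation test** — statistic |log2FC| on normalized counts; the
  null enumerates all distinct assignments of the group-A label
  (including the observed one) when there are at most `n_permutations`
  (default 10000), otherwise that many seeded random draws;
  p = (1 + #{null ≥ observed}) / (1 + #null). With 4 + 4 samples this is
  70 splits, so p-values are discrete multiples of 1/71 and the test is
  conservative at small α — the attainable level at α = 0.05 is 2/70.
* **BH adjustment** — Benjamini–Hochberg step-up (delegated to
  statsmodels, oracle-tested); chosen because it is the default of the
  standard count-based differential tools. With p-values present, the
  final flag requires both |log2FC| > 1.0 and padj < 0.05, strict.

## The simulator

The generator emulates the enrichment geometry that matters to a
depth-threshold caller, not sequencing chemistry:

* fragment lengths ~ triangular(200, 350, 500), rounded — the simplest
  distribution with hard bounds and a controllable mode matching a
  200–500 bp target modal sonication size; fragments are whole (shifted
  inward at contig edges, never truncated);
* transcripts are placed uniformly by rejection sampling with disjoint
  scan footprints (transcript plus unclipped promoter window), so planted
  loci never overlap and truth attribution is unambiguous;
* each planted region (default width 1500 bp, centered in its promoter
  window, default 40% of promoters) receives, per sample,
  Poisson(enriched_depth × width / mean_frag_len) fragments with
  midpoints uniform in the region — giving analytically checkable
  expected depths (default enriched_depth 20);
* background fragments ~ Poisson(background_rate × genome kb) with
  uniform starts; the default 1 fragment/kb corresponds to an expected
  background depth of 0.35, far below the calling threshold;
* a chosen fraction of planted regions (default 0) gets its depth
  multiplied by `differential_effect` in condition M1 only;
* two conditions × `n_samples_per_condition` (default 4) replicates,
  mirroring a 4-donor two-arm design; everything derives from one seed
  and reruns are byte-identical.

Transcript lengths are drawn uniformly from [2000, 8000] bp — a
generator-only parameter on the scale of typical mammalian gene bodies at
the simulated genome size. Default genome: 2 contigs × 1 Mb, 50
transcripts.

What the simulator does *not* model: CpG-density-dependent MBD affinity,
GC/mappability bias, read-pair structure, sequencing error, or
chromosome-scale genomes. Passing recovery tests therefore demonstrates
the pipeline's interval logic and statistical behavior under clean
enrichment, not robustness to real-data artifacts.

## Validation regimes and problem sizes

The validation suite and `scripts/acceptance.py` use three regimes, sized
so the full suite runs in well under a minute per regime:

* **separation** — 20 planted promoters on 2 × 1 Mb contigs, enrichment
  2× the threshold, background ~60× below it, 4 + 4 samples: recall is
  1.0 with mean boundary error well inside one maximal fragment length
  (measured ≈ 85–90 bp);
* **null** — ~220 planted loci (≥ 200 consolidated sites) with no
  condition effect: the permutation test rejects at its exact discrete
  level (~2.9% at nominal α = 0.05) and the joint |log2FC|/padj criterion flags
  essentially nothing;
* **effect** — 4× enrichment at 10 of 200 planted loci: the differential
  loci occupy the top-10 |log2FC| ranks (scored per locus, i.e. max
  |log2FC| over the consolidated sites overlapping a planted region).

## Known limitations

* The merge rule can leave contained sub-peaks as separate master-list
  rows (see Consolidation); consumers should aggregate per locus.
* The permutation screen is underpowered for small replicate counts
  (its p-value floor with 4 + 4 samples is 2/71) and tests a
  fold-change statistic without dispersion modeling.
* The depth threshold is absolute; libraries of very different depths
  should be subsampled or compared only downstream of counting, where
  normalization applies.
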