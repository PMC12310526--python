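# Methods

This note records the models, parameter choices and numerical conventions
behind `hetscape`, and what the synthetic benchmarks do and do not show.

## Coordinate model and interval algebra

All coordinates are 0-based half-open (BED convention); GTF input (1-based
closed) is converted on read, and every interval produced anywhere satisfies
`0 ≤ start < end ≤ chrom length` (clipped at chromosome edges). Strand is
used only to orient promoter windows — the TSS is `start` for `+` genes and
`end` for `−` genes, and the promoter is `[TSS − upstream, TSS + downstream)`
oriented by strand (default −2000/+500 bp, a common convention; the tests
rely on planted truth rather than on this default). Peak and domain logic is
strand-agnostic because histone-modification data carry no strand.

Overlap is counted per interval of the query set: a peak "overlaps" another
set if at least one partner interval intersects it by `min_overlap_bp`
(default 1 bp — interval intersection, not summit distance, and no
reciprocal-overlap requirement). Pies and partitions therefore count each
site exactly once, and every partition conserves counts by construction.

bedGraph binning takes the per-bp mean: each bp gets the mean of the records
covering it (overlapping records are averaged, with a warning), uncovered bp
count as zero, and the bin value is the mean over the bp the bin actually
spans (the terminal bin of a chromosome may be short).

## Element classification

Each peak receives exactly one of promoter / gene body / intergenic with
precedence promoter > gene body > intergenic under any-bp overlap. The
precedence rule is required because promoter windows overlap gene bodies;
single-label assignment keeps class fractions summing to 1.

## Epigenetic switch

Candidates are the null-state (day0) EZH2 peaks that do **not** overlap
day0 H3K27me3. A candidate has switched if it overlaps day1 H3K27me3; the
report also gives the fraction of switched loci co-occupied by day1 IKAROS
*and* HDAC1. With zero candidates the fraction is reported as undefined
(`None`), never as 0.

## Enhancer model

Candidate enhancers are H3K4me1 peaks merged across gaps ≤ 1 kb with
promoter-overlapping regions removed (distal requirement). States follow the
four-way mark truth table (active / primed / intermediate / poised); the
mapping is total — every enhancer gets exactly one state. Target genes are
assigned by nearest TSS from the enhancer center, capped at 100 kb, with
distance ties broken toward the lexicographically lower `gene_id`. Nearest-
TSS is an assumption, not a measured contact map; merge gap and distance cap
are configurable because no single value suits every dataset.

Group expression comparisons use two-sided Mann–Whitney rank-sum tests
against a reference group (active for state grouping; doubly unbound for
occupancy grouping, which considers active enhancers only). A gene linked by
several enhancers is counted once, under its most repressive state
(active < primed < intermediate < poised) or most occupied combination —
this prevents double counting in the group summaries. P-values are reported
raw with group sizes; with at most a handful of pairwise comparisons no
multiple-testing correction is applied.

## Broad-domain segmentation (LOCKs and BGRDs)

Input is a fixed-bin signal track (default 10 kb bins). A bin is enriched if
its value exceeds `enrichment_threshold ×` the genome-wide **median** bin
value (median rather than mean so the threshold is robust to the domains
themselves; a 0.1 pseudocount guards degenerate all-zero tracks). With a
matched input track, enrichment is instead a pseudocounted signal/input
ratio above the threshold — optional, since input normalization is not
always available.

Maximal runs of enriched bins are stitched across gaps ≤ `merge_gap`
(default 25 kb), and a stitched domain is kept iff its longest constituent
run is ≥ `min_length` (**seed-run rule**; LOCK default 100 kb, BGRD default
10 kb). The seed-run rule — rather than a length filter on the stitched
domain — was chosen because it makes the caller provably monotone: raising
`merge_gap` can only merge domains (count non-increasing, coverage
non-decreasing) and raising the threshold can only shrink coverage, and it
prevents clusters of short noise runs from assembling into a spurious
domain without a bona-fide broad seed. Defaults make "large" literal and are
fully configurable; the benchmark surface is planted-truth recovery, not
parameter fidelity.

BGRDs keep the domains covering ≥ `gene_cover_fraction` (default 0.8) of at
least one gene body, annotated with the covered genes. Expansion matches
each day1 domain to the day2 domain of maximal overlap (ties leftmost);
unmatched day2 domains are "new", day1 domains without overlap are "lost",
and a day2 domain absorbing several day1 domains is flagged as a merger.

## Repression resampling test

The universe is every gene with nonzero expression in ≥ 1 condition
("random genes" drawn uniformly — not expression-matched, the simplest
defensible null). Each of `R` resamples (default 1000, minimum 100) draws a
size-matched set without replacement and records its median; the group
summary is the median (matching boxplot-style reporting, robust to the
log-normal tail). The empirical p-value uses the add-one rule and is
one-sided in the repression direction (the scientific claim is directional;
two-sided is available). The effect is
`log2(observed median / mean of null medians)`. Everything is deterministic
per seed.

## Synthetic-data generator

The generator emulates a re-expression time course (`day0` IKAROS-null,
`day1`, `day2`) and writes exactly the formats the readers consume. Feature
classes live on dedicated chromosome territories so planted truth is
unambiguous:

- **chr1 (20 Mb), broad domains** — 20 planted LOCKs, lengths uniform in
  200–400 kb snapped to the 10 kb bin grid, one per 1 Mb slot, expanded 2×
  about their centers at day2 (so planted domains stay ≥ 2× merge-gap
  apart and the segmentation answer is unique). H3K27me3 signal is Gaussian
  background (mean 1.0, sd = `noise_sd`, default 0.2 — a typical CV for
  binned background coverage — clipped at 0) plus a +3.0 plateau over the
  domains. Snapping to the bin grid makes noise-free recovery exact rather
  than exact-minus-quantization. 15 genes are planted inside each day1
  domain (300 in total) and repressed 4× (`repression_effect = 0.25`);
  background genes sit in the slot margins outside even the day2 extents.
- **chr2 (31 Mb), enhancers** — one enhancer (1–2 kb) plus one target gene
  per 30 kb slot, geometry chosen so each enhancer's nearest TSS is provably
  its own gene and no enhancer touches a promoter. 250 enhancers per state;
  marks are emitted per the state truth table, jittered ±50 bp but always
  covering the enhancer. IKAROS/HDAC1 occupancy flags are drawn per design
  (unbound at day0); target-gene expression is multiplied by state effects
  (1 / 0.6 / 0.35 / 0.25) and, for active enhancers, occupancy effects
  (1 / 0.6 / 0.4 / 0.35) — orderings that mirror the repressive hierarchy
  the pipeline is meant to detect. State and occupancy are held constant
  across day1/day2; modelling their temporal shift would add layout
  complexity without adding testable truth.
- **chr3 (36 Mb), factor sites** — co-occupancy sites drawn per combination
  design and per element-class design, quantized by largest remainder
  (planted fractions exact to within 1/n). Promoter and gene-body sites are
  placed at distinct genes with offset ranges that guarantee the intended
  element class and no intra-timepoint overlap between loci; every factor in
  a site's combination gets its own peak (log-normal width, median 400 bp,
  clamped to ≥ 200 bp; ±50 bp jitter) so designed overlaps always survive.
  The default day designs encode the biology being modelled: day0 EZH2
  binding without H3K27me3; day1 H3K27me3 coupled to IKAROS/HDAC1; day2
  H3K27me3 mostly factor-independent, with the day2 site count chosen so the
  genome-wide H3K27me3 peak total (sites plus enhancer marks) rises ~4.4×.
- **chr4 (30 Mb), filler** — 9000 neutral genes, so the 12k-gene expression
  universe is dominated by unaffected genes as in a real transcriptome
  (~10% of genes carry planted effects). Expression is log-normal (median
  50, σ = 0.8 in log-space) with a per-condition multiplicative jitter
  (σ = 0.1) when noise is on.

The **switch scenario** plants EZH2-only loci on a dedicated genome with a
configured switch fraction: noise-free mode switches exactly `round(f·n)`
loci; noisy mode switches each candidate independently with probability `f`
(a binomial realization, which is what makes confidence-interval recovery
statements meaningful). The **knockout scenario** derives a second
single-condition landscape with IKAROS removed from all combination designs,
0.6× site count, promoter fraction 0.5 → 0.15, quartered domain count and no
enhancer occupancy — the depletion signature a loss-of-function comparison
should show.

One `numpy` generator seeded once drives all draws in a fixed code order, so
identical seeds give byte-identical output files.

### What the benchmarks do not show

The generator plants clean, well-separated structures: it has no replicate
variance, no fragment-level or GC bias, no ambiguous overlapping domains, no
enhancer–promoter contacts beyond linear proximity, and its noise is
i.i.d. Gaussian per bin. Passing tests therefore demonstrate correctness of
the algebra and estimators under the stated models — not robustness to every
artifact of real ChIP-seq, where peak-caller behaviour, library depth and
parameter choices dominate.

## Problem sizes

The default generator emits a ~117 Mb four-chromosome genome, ~13k genes,
1000–6000 factor sites per timepoint and 1000 enhancers; the test suite runs
scaled-down variants (5–20 domains, 200–1000 sites) and the full suite
completes in well under a minute. Resampling defaults: 1000 resamples for
reported effects, 200 for calibration sweeps.
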