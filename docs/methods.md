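# Methods

## Problem and model

The package screens a cultured cell line (typically an iPSC line) for
copy-number aberrations by comparing binned read-depth profiles against a
matched control (typically the parental fibroblasts). The underlying model
is the standard read-depth one: conditional on mappability and library
size, the number of reads whose leftmost position falls in a genomic bin is
proportional to the copy number of that bin. On a log2 scale relative to
the diploid baseline, copy number 2 → 0, 1 → −1, 3 → +0.585, and whole-
chromosome events appear as chromosome-wide shifts.

Assumptions: coverage is uniform enough at the megabase scale that the
median autosomal bin is a stable diploid reference; the control genome is
diploid on the autosomes; and aberrations are large relative to the bin
size (the design point is chromosome-arm to whole-chromosome events — a
1-Mb bin cannot resolve sub-megabase CNVs).

## Coordinates and binning

All coordinates are 0-based half-open (BED/bedGraph convention); SAM
positions are converted from 1-based on read. Each chromosome is tiled by
consecutive `bin_size` windows (default 1 Mb) with the final window
truncated at the chromosome end. Truncated bins are counted but excluded
from the normalization reference and from segmentation when narrower than
25% of the bin size, since their counts are disproportionately noisy.
Y-category sequences are binned but masked by default (`mask_Y`): a
fragmented, repeat-rich Y violates the uniform-depth model. No N-gap or
mappability masking is performed (it would require the sequence itself);
this is a known limitation for genomes with large assembly gaps.

## Read counting

Records are kept iff `(flag & 2308) == 0` — excluding unmapped (0x4),
secondary (0x100), and supplementary (0x800) records — and, optionally,
`MAPQ >= min_mapq` (default 0, i.e. no MAPQ filter; duplicate-marked reads
pass because 0x400 is not in the mask). Each kept record increments exactly
one bin, the one containing its leftmost mapped position; reads are never
split across bins, so totals are conserved and counting is order-invariant.
Reads on reference sequences absent from the bin grid are tallied and
skipped with a warning; a header/grid length mismatch is a hard error.

## Normalization

Within-sample mode: `v_b = log2((c_b + p)/(R + p))` with `R` the median
count over unmasked **autosomal** bins and pseudocount `p = 0.5` (configurable,
0 allowed). The median is robust to large CNVs and whole-chromosome events;
excluding allosomes from `R` keeps a male sample's autosomes at 0 and its X
near −1 rather than shifting the baseline. Test-vs-control mode is the
difference of the two within-sample tracks, i.e. `log2(t_norm / c_norm)`,
which cancels structure shared by both samples. The pseudocount keeps
zero-count bins finite at the cost of an `O(p/R)` bias, negligible at
R ≈ 75.

## Circular binary segmentation

For a data stretch `x[0..n)` treated as a circle, every arc `x[i:j]`
(0 ≤ i < j ≤ n, 0 < j−i < n) is scored with

    T(i, j) = (mean(x[i:j]) − mean(rest)) / sqrt(s² (1/(j−i) + 1/(n−(j−i))))

where `s²` is the sample variance (ddof 1) of the current stretch;
zero-variance stretches are unsplittable by definition. The maximising arc
(ties broken to the smallest `i`, then `j`, with a 1e-9 relative tolerance,
since an arc and its complement tie exactly) is assessed by permutation:
`p = (1 + #{permutations whose max |T| ≥ T_obs}) / (1 + B)`, an add-one
estimator that is never 0. If `p < α` and every resulting piece has at
least `min_bins` bins, the stretch is split at the arc boundaries — three
pieces for an interior arc, two when the arc abuts an end — and each piece
is re-examined recursively; otherwise the stretch is emitted as one
segment whose `split_pvalue` records the failed test (NaN when no test was
run). Chromosomes are segmented independently; within a chromosome each
contiguous run of unmasked bins is segmented on its own, so masked bins
never join a segment.

Defaults: α = 0.01, B = 10 000 permutations, `min_bins` = 3, mandatory
seed. No post-hoc merge ("undo") pruning is applied; adjacent segments
with similar means are left distinct, which at α = 0.01 yields an
occasional extra split inside a long noisy stretch (about one per few
hundred tests) rather than missed events.

Two implementation choices matter for reproducibility:

- **Per-stretch RNG keying.** The permutation generator for a stretch is
  seeded from (global seed, stretch bounds), not from one global stream.
  The same stretch therefore sees identical permutations regardless of
  what was decided elsewhere in the recursion, which makes the
  segmentation at a smaller α an exact coarsening of the one at a larger α
  and keeps results independent of recursion order.
- **Early-stopped permutation testing.** Permutations are drawn in chunks
  and drawing stops as soon as the exceedance count alone guarantees
  `p ≥ α` (the count can only grow), leaving the split/no-split decision
  bit-identical to the full-B test at a fraction of the cost. For an
  unsplit segment the recorded `split_pvalue` is the running estimate at
  the stopping point (always ≥ α); for split decisions the p is exact.
  The standalone `permutation_pvalue` function always draws the full B.

The arc search is the direct O(n²) scan, vectorised; at ~2 600 bins
genome-wide (≤ ~230 per chromosome) a full-genome segmentation takes well
under a second, so none of the faster CBS approximations are needed.

## Calling, X ploidy, comparison

Segment state is determined solely by its mean log2 value: loss at
≤ −0.4, gain at ≥ +0.32, neutral between. The thresholds sit roughly
midway between 0 and the one-copy expectations (−1, +0.585), leaving
margin for noise in both directions; at depth 75 and ≥ 3 bins per segment
the segment-mean standard error is ≤ ~0.05, so both planted event classes
separate cleanly. A segment spanning ≥ 90% of its chromosome's segmented
bins is flagged `whole_chromosome`.

X ploidy is the median over unmasked X-bin log2 values: `single_X` at
≤ −0.5, `double_X` at ≥ −0.25, else indeterminate. When a sample is
single_X, loss calls on the X are downgraded to neutral — expected male
hemizygosity is not an aberration.

Test and control calls match when they share chromosome and state and
overlap reciprocally by ≥ 0.5 of each call's length; matched calls are
"shared", unmatched ones sample-specific. The comparison is symmetric
under swapping the inputs.

## Synthetic data

The generator emulates the study conditions, not sequencing reads:

- **Genome.** 40 autosomes falling smoothly from ~230 Mb to ~20 Mb
  (a 20-Mb floor plus a power-law decay with exponent 4.25, chosen once so
  the autosomal total lands near 2.4 Gb), ±2% seeded jitter re-sorted to
  keep lengths monotone; an X of ~130 Mb; optionally 155 sub-megabase Y
  scaffolds. Lengths are synthetic approximations — only ordering and
  scale matter.
- **Counts.** Per-bin expectation
  `mean_depth × (width / bin_size) × CNV multiplier × allosome factor`,
  with `mean_depth` defaulting to 75 reads per full bin, the multiplier
  the length-weighted average of planted events overlapping the bin, and
  the allosome factor 0.5 for X/Y bins of an XY sample. Noise is Poisson
  by default; a negative-binomial option (variance μ + μ²/d) stress-tests
  overdispersion. All draws come from integer-seeded `numpy` Generators,
  so output is deterministic cross-platform.
- **Alignments.** A toy SAM writer realises a per-bin primary-read ledger
  (positions uniform within the bin, 1M CIGAR, placeholder sequence) plus
  requested contaminating secondary/supplementary/unmapped records, and
  returns the ledger for exact round-trip testing of the counting path.

What the generator does **not** model: GC/mappability waves, positional
autocorrelation of coverage, alignment artifacts at repeats, or breakpoints
inside bins. Passing tests therefore demonstrate the pipeline's logic and
its statistical behaviour under the stated depth/noise regime, not
robustness to real-data systematics; on real libraries a GC or mappability
correction upstream of normalization may be needed.

## Problem sizes used in tests

The test and acceptance runs use the full 41-chromosome synthetic genome
(~2 600 1-Mb bins) with 2 000 permutations and 10 seeded replicates for
the pipeline-level checks, and smaller stretches (n ≤ 100) for the
segmentation unit tests; exhaustive oracles (O(n²) arc scan, full
enumeration of all orderings at n = 7) back the CBS statistics.

## Known limitations

- Breakpoints are bin-resolution (±1 bin ≈ ±1 Mb at the default size).
- Balanced rearrangements and copy-neutral LOH are invisible to read depth.
- The diploid baseline assumes the control is not itself aneuploid over
  most of its genome (the median would shift).
- No gene-level annotation of calls; the output is coordinates, states,
  and figures.
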