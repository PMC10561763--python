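# Methods

## Model

The pipeline infers the chromosomal class of each assembly contig from the
dosage signal in male vs female whole-genome sequencing depth. The
generative assumption is a simple XX/XY system: per-cell copy counts are

| class    | female | male |
|----------|--------|------|
| autosome | 2      | 2    |
| X        | 2      | 1    |
| Y        | 0      | 1    |

and expected depth is proportional to copy count, modulated by a
multiplicative GC-dependent bias b(gc) and counting noise. Everything the
classifier consumes is a windowed mean depth; read placement, mapping and
alignment are upstream concerns (depth arrives as a bedgraph track).

Coordinates are 0-based half-open throughout. Windows tile each contig
exactly (step = width); an overlapping step is exposed for plotting but the
pipeline never uses it, because overlapping windows would double-count depth
in the contig medians.

## Windowing and profiling

Default window size is 100 kb. Window GC is (G+C)/(A+C+G+T); N bases leave
the denominator, and a window that is > 50% N (or all N, GC undefined) is
flagged *excluded*: it does not enter GC-model fitting or the depth
baseline, but still receives a corrected depth (clamped nearest-GC value,
unit correction when GC is undefined) so gappy contigs are never silently
dropped. The sample's depth baseline is the length-weighted mean raw depth
over non-excluded windows — a quantity reproducible from the track alone,
standing in for "overall sequencing depth of the input library", which is
not recoverable from a depth track.

## GC correction

Expected depth as a function of GC is fitted by LOESS — tricube-weighted
local *linear* regression (degree configurable to 0, which uses a tricube
kernel mean) over the span-nearest fraction of points, span 0.3 by default —
evaluated on a fixed 101-point GC grid and interpolated linearly, with
clamping outside the observed GC range. Grid evaluation rather than
per-point smoothing makes the correction deterministic and cheap. Fitted
values are floored at 10⁻³ of the reference depth so a pathological fit can
never divide by ~0. Fitting requires ≥ 20 usable windows (fewer → error
advising a smaller window size); zero GC variance degenerates to a constant
model.

Each sample gets its own model (male and female libraries have different
bias). The first pass fits on *all* windows — sex-linked windows shift the
depth level, not its GC slope, so the fitted shape is right but its level is
pulled below the autosomal level by the haploid/absent fraction of the
genome (about −17% under the default 2/3 autosome, 1/6 X, 1/6 Y composition,
inflating copy numbers by the reciprocal). The pipeline therefore defaults
to a **two-pass** fit: windows whose first-pass copy number lies within 25%
of diploid (cn ∈ [1.5, 2.5]) are refitted, anchoring the curve to
autosome-like windows and centering autosomal cn at 2.0 and male X/Y at 1.0.
The refit only happens when ≥ 20 windows survive the filter; at very small
window counts (tens of windows) the refit's neighborhoods become unstable
and single-pass is the better choice, which is why `fit_and_correct` itself
defaults to single-pass and only the pipeline configuration enables the
second pass.

## Copy number and classification

cn(w) = 2·corrected(w)/baseline, so the field's phrases read literally off
the scale: "single copy in males" is cn_m ≈ 1, "not detectable in females"
is cn_f ≈ 0, "twofold copy number variation in females" is cn_f/cn_m ≈ 2.
Contigs are summarized by the *median* window cn with a median-absolute-
deviation spread; the median resists collapsed-repeat and pileup windows,
which matters most on the repeat-rich Y. Contigs with fewer than 3 usable
windows are callable but flagged low-evidence. Same-sex replicates (default
3 male + 3 female, mirroring a triplicate male/female design) are combined
by averaging window cn across samples, which empirically reduces contig-level
error versus a single library.

Rules fire in a fixed order, most specific first — Y (female absence is the
sharpest signature), then X, then autosome; anything else is ambiguous:

1. Y-linked: |cn_m − 1| ≤ δ_single and cn_f ≤ absent_max
2. X-linked: 0 < cn_m ≤ 1 + δ_single, cn_f > absent_max,
   cn_f/cn_m ∈ ratio_x
3. autosomal: |cn_f/cn_m − 1| ≤ δ_auto and both cn ∈ [2 − 2δ_auto, 2 + 2δ_auto]

Defaults: δ_single = 0.35, absent_max = 0.2, ratio_x = [1.6, 2.4],
δ_auto = 0.35. The source procedure states only the idealized signatures
("single copy", "twofold", "absent"); the tolerance widths are owned here
and validated for pairwise exclusivity at construction (no (cn_m, cn_f) can
satisfy two rules; checked exhaustively on a 0.01 grid over [0,4]² in the
tests). A contig absent in both sexes (cn_m = 0) is ambiguous, not Y-linked:
the Y call requires male presence. Raising absent_max is provably monotone
in the number of Y calls. Calls are whole-contig; a per-window provisional
class dump (`window_class_bed`) is available for inspecting contigs with
pseudoautosomal-like mixtures, which are not split.

## Allelic-contig purging

Canonical k-mers (lexicographic min of k-mer and reverse complement, k = 21,
odd to avoid palindromes, N-spanning k-mers skipped) are counted over the
assembly and classed by total count: unique (1), duo (2), repeat (≥ 3). The
pair score s(a,b) = |duo(a) ∩ duo(b)| / |duo(shorter)| uses the shorter
contig's duo set as denominator so a haplotig fully contained in a longer
primary scores ≈ 1; repeat k-mers never contribute (the "non-repeat"
restriction). Pairs with s ≥ 0.6 are linked; within each connected
component the longest contig is greedily kept (ties to the
lexicographically smaller id), its neighbors purged, and the rule recurses
on the remainder — deterministic, and tested against an independent
recursive implementation on all small graphs.

Two deliberate choices: (1) duo status comes from assembly-internal counts,
not a read-based k-mer depth spectrum — the artifact must run without raw
reads, and for the planted-haplotig use case the two definitions coincide;
(2) an edge is only formed when the shorter contig has at least
`min_duo` = 20 duo k-mers: with a denominator of 1–2 the score cannot be
distinguished from a chance k-mer collision (at 21 bp, collisions between
unrelated contigs are rare but not absent, especially in low-entropy
GC-extreme segments), whereas a genuine haplotig contributes thousands.

## Assembly statistics

Nx uses the dominant ≥ convention on the descending cumulative sum (stated
explicitly because conventions differ); GC% excludes N from the denominator;
fold ratios round half-to-even to the requested precision. Worked examples
pin the arithmetic to published values: 116.4/69.3 → 1.7-fold X:Y size
ratio, 34.7/19.3 → 1.8-fold DNA:retrotransposon content ratio,
19.3 + 34.7 + 3.3 = 57.3% total repeat content.

## The simulator, and what passing tests do and do not show

`generate_genome` builds contigs from GC segments (default segment 100 kb,
GC ~ U(0.25, 0.65)) so window GC actually varies at the scale the correction
operates on; truth labels are assigned per contig and copy counts derived
from the table above, never stored. Optional allelic duplicates copy a
prefix (default 90% of the source length) with i.i.d. substitutions (default
1%).

`simulate_depth` works at window resolution: expected depth is
mean_depth · copies/2 · b(gc) with b either "peaked"
(exp(−2s·|gc − 0.5|)) or "monotone" (exp(2s·(gc − 0.5))), both with
b(0.5) = 1; the form in force is recorded in the config dump so the
correction cannot be accused of overfitting one functional shape. Noise is
applied at read-count granularity: N ~ Poisson(expected·L/read_length)
reads of `read_length` (default 10 kb, long-read scale) give depth
N·read_length/L. Per-base Poisson noise averaged over a 100-kb window would
have a relative SD of ~0.4% — invisible — whereas read-count granularity
yields the few-percent window-level scatter real long-read tracks show.
Negative-binomial noise (gamma–Poisson mixture, dispersion 0.05 by default)
models extra-Poisson variability. An absent sequence (female Y) yields
exactly zero depth at any noise setting. All randomness flows from one seed
through named substreams (genome; per-sample by sex and index), so adding a
sample never changes earlier streams.

The simulator reproduces the *statistical structure the inference assumes* —
dosage, GC bias, counting noise — and deliberately not: mappability
artifacts, repeat-driven pileups, reference bias from collapsed or expanded
repeats, pseudoautosomal homology between X and Y contigs, or real
library-prep GC curves. Passing the recovery tests therefore demonstrates
correctness of the machinery under the stated model, not performance on a
real repeat-rich genome, where the median summarization and the ambiguous
class are expected to absorb (not resolve) the violations.

## Scenario sizes

Test and acceptance scenarios are sized for a desk machine, as the package's
own defaults: the default classification scenario is 30 contigs
(20 autosomal / 5 X / 5 Y) of 0.3–1.0 Mb (≈ 21 Mbp genome) at 100-kb
windows, 30× diploid depth, GC-bias strength 0.5, Poisson noise, 3 + 3
replicates; the GC-flattening check uses 20 autosomes at 10-kb windows
(~1,000 windows) with monotone bias and no noise; the purge check uses 20
contigs of 20–50 kb with 10% planted duplicates. Across the seeds probed the
default scenario recovers ≥ 96.7% of contigs (100% at most seeds and always
in the noise-free variant), and no true X contig has ever been called
Y-linked.

## Known limitations

- Whole-contig calls: a contig that is part X-homologous and part
  Y-specific gets a single call (usually ambiguous); the window-level dump
  is the escape hatch.
- The copy-number scale presumes most of the genome is diploid; in a
  triploid or heavily duplicated assembly the two-pass anchor would latch
  onto the wrong level.
- The purger's duo classification is assembly-internal; genuine two-copy
  segmental duplications (not haplotigs) that pass the score threshold
  would be purged as if allelic.
- Thresholds are tuned for ~30× depth with triplicates; at much lower depth
  the fixed tolerance widths will misclassify more, and they should be
  widened deliberately rather than implicitly.
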