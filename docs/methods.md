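# Methods

## Scope and coordinate conventions

All genomic arithmetic is 0-based half-open (BED convention); SAM input is
converted at the IO boundary. Strand is read and stored but ignored by
overlap and pileup logic — every procedure in this pipeline is
strand-agnostic. The pipeline consumes deduplicated, blacklist-filtered
alignments (or plain fragment tables); alignment, deduplication and peak
calling (MACS2) are upstream of its scope.

## Repeat curation

RepeatMasker annotates one retroelement as several fragments. Curation
clusters fragments with pairwise gap ≤ `max_gap` (default 0: abutting
fragments merge, a 1 bp gap separates), names the merged element after its
largest member fragment — ties broken by the leftmost member, a case the
source procedure leaves unspecified — and removes merged elements shorter
than `min_len` (default 2000 bp), which eliminates solo LTRs and scraps
from the element annotation. With the length filter disabled, curation is
a pure merge and conserves union length; this is a tested invariant. Solo
LTRs are recovered separately as LTR-named fragments whose gap-free
cluster contains no internal-named fragment, optionally restricted to
those overlapping an enrichment peak set (the selection criteria for
published enriched orphan-LTR sets are not fully specified, so both knobs
are exposed rather than guessed).

Family grouping for bin/peak annotation uses a configurable repName
prefix table (`IAP*` → "IAP", etc.).

## Presence calling and the shared element set

A fragment anchors an element iff its span overlaps the element (any
overlap > 0) and max(mate MQs) > `mq_min` (default 10, strict — the
bowtie2-style "uniquely mapped" cutoff). The fragment span, not the
individual mate, is the overlap unit; single-end records participate with
their own MQ on both slots. Since curated elements are non-overlapping
and gap-separated, a fragment can touch at most a few elements; it is
counted for the one it overlaps most. Presence per dataset requires
≥ `min_anchors` (default 1) anchoring pairs; cell-line presence is the OR
over the line's datasets (ChIP and matched inputs pooled); the shared set
keeps elements present in every cell line. Raising `mq_min` or
`min_anchors`, or adding cell lines, can only shrink the shared set
(tested monotonicity).

## Coverage and normalization

Tracks are per-base float vectors per chromosome — exact at toy-genome
scale, and the contract all operations are defined against. Pileup paints
+1 over the fragment span (fragment mode) or over `[start, start+extend)`
(read mode, default extension 150 bp); with `mq_min` set, records at
MQ ≤ `mq_min` are dropped. 1x normalization multiplies by
`effective_genome_size / Σ(per-base coverage)`: the scale factor comes
from the *realized* coverage rather than read count × nominal length, so
read- and fragment-resolution tracks share one exact definition and the
genome-wide mean is 1 to machine precision (tested at 1e-6). Read-mode
tracks are tagged RPGC, fragment-mode FPGC; profile operations refuse
un-normalized tracks, since cross-sample profiles are only comparable on
the genome-average-1 scale. The default effective genome size for real
mouse data is 2,150,570,000 bp; for synthetic genomes it is the summed
chromosome length.

log2 ChIP/input ratios exclude bins (or bases) where either side is zero;
no pseudocount is applied anywhere, and exclusions are flagged rather
than imputed.

## Peaks

Consensus peaks restate "called in ≥ 2 of 3 replicates, merging
overlapping called regions" as connected components of the overlap graph
over all replicate peaks (edge = any overlap > 0, within- and
between-replicate alike): each component spanning ≥ `min_reps` distinct
replicates emits its union span. This is deterministic, invariant to
replicate order, and identical whether or not within-replicate peaks were
merged beforehand. Classification of two peak sets uses any overlap > 0
(1 bp suffices); chromatin-state annotation assigns the largest-overlap
state and requires the segmentation to partition the genome.

## Statistics

Group comparisons use the two-sided Wilcoxon rank sum test: exact null
enumeration when min(n) ≤ 8 without ties, otherwise the normal
approximation with tie and continuity corrections (the implementation
delegates to scipy; the test suite checks it against an independent full
enumeration of rank splits, and its type-I error is calibrated to
0.05 ± 0.02 over 1000 null simulations). Effect sizes are Cohen's d with
pooled SD (ddof = 1), sign = first group minus second; the "±" attached
to an effect size is reproduced as a seeded bootstrap SD, the most
plausible reading of reference values whose definition is unstated —
equality comparisons apply to the point estimate only. Paired
comparisons use the classical paired t test, with an explicit degenerate
error when the differences have zero variance. Tukey's 1.5 IQR rule uses
type-7 (linear-interpolation) quartiles — the convention of the source
statistical environment, on which the bounds depend — and is applied only
to distribution displays, never before a test.

## Profiles

Reference-point matrices anchor at floor((start+end)/2) with ±`flank`
(default 2500 bp) in `bin_width` (default 50 bp) steps; scale-body
matrices linearly rescale each locus body to `body` bp (default 6500, the
convention for full-length IAP elements) with genomic flanks appended.
Flank and body must divide evenly by the bin width. Positions off
chromosome ends are missing and excluded from column means (the
conservative choice; upstream tools make this configurable). Row order is
the descending argsort of row means and can be propagated byte-identically
from the leftmost panel of a figure row. The 50 bp position bin is chosen
to keep toy-scale matrices small while preserving profile shape; loci are
averaged unweighted. Per-state mean matrices average per-region mean
log2 ratios unweighted within each category; empty categories are flagged
absent (NaN), not errors. Heatmap rendering exists for the analysis
drivers; only the numeric matrices are contractual.

Shuffled controls conserve the length multiset, place each interval on a
chromosome chosen proportionally to its available placement space and
uniformly within it, and by default exclude the source intervals
themselves (the published analysis does not state its shuffling settings;
this is the package's choice).

## Synthetic study

The generator emulates the statistical structure the analysis assumes,
not sequence: a 3 × 2 Mb genome carrying 36 full IAP-like elements
(340 bp LTR + 4–6 kb internal + 340 bp LTR, written as separate abutting
rmsk fragments so curation has real work), 18 solo LTRs, non-IAP repeat
decoys, 30 enhancers and 30 TSS, placed ≥ 3 kb apart; a 15-state
segmentation that covers the genome exactly, with the heterochromatin
state over IAP domains. Elements are polymorphic across three strains:
the annotation derives from the reference strain, which therefore carries
every element; in each other strain one quarter of elements are
polymorphic and present with probability 0.5.

Fragments are drawn from a piecewise-constant intensity: baseline 1,
multiplied by the mark's fold over its regions — H3.3 fold 4 over
enhancer zones and over LTRs plus the adjacent 2 kb of internal sequence;
H3K9me3 fold 6 and the knockout accessibility gain fold 3 over IAP
*domains* (element ± 2.5 kb, matching the ~10 kb scale of interstitial
heterochromatin domains); input fold 1 — and zero across elements absent
from the sampled strain (no fragment overlaps an absent element,
emulating the contiguous insertion-free genome). Fragment lengths are
N(180, 30²) truncated at 50 bp; depth is 30x by default. Fragments lying
entirely within internal repeat sequence are multimapping with
probability 0.9, emulated purely through MQ 0 on both mates — sufficient
to exercise every MQ-dependent code path without multi-copy sequence.
Replicate peak calls copy the true peak regions with per-replicate
dropout (10%) and Gaussian boundary jitter (SD 50 bp). Everything is
bit-reproducible from (config, seed); per-sample randomness uses named
sub-streams of the config seed.

An optional `fold_atac_open` knob adds condition-independent ATAC
enrichment at enhancer/TSS zones. It defaults to 1 (off): with it on, the
genome-wide accessibility distribution acquires the real-data property
that its spread comes from open regulatory chromatin, but baseline bins
then sit measurably below the bin-wise mean on the 1x scale — a real
normalization phenomenon that shifts effect sizes of baseline groups by
≈ −0.2 SD at this genome scale.

### Problem sizes and what passing tests show

End-to-end checks run the full chain at the default 6 Mb genome: presence
panels (one H3K9me3 ChIP + matched input per strain) at 8x — the
anchoring-evidence recovery condition (≥ 5 anchoring fragments per
present element) is amply met there — and ATAC samples at the default
30x. Group statistics of the wildtype/knockout contrast are evaluated on
bins pooled across five simulation seeds, because a single toy genome
yields only ~65 IAP-overlapping bins and a group effect-size estimate
carries irreducible sampling noise ~1/√n ≈ 0.12 SD per seed (~0.05
pooled). The measured fold change at IAP bins is reported as the group
fold change log2(mean KO / mean WT over IAP bins); per-bin mean-of-log2
is systematically lower because bins overlapping an element by only a
sliver dilute the ratio and the log is concave.

Passing these tests shows the *procedures* are correct on data matching
the generator's assumptions: piecewise-constant enrichment, uniform
input, clean strain presence/absence, independent fragments. Real data
add GC and mappability bias, copy-number variation, overdispersion,
partial insertions and alignment artifacts that the generator does not
model, so recovery rates here are upper bounds, not forecasts. The
published full-scale quantities (3046 curated IAPs, 2640 shared, 2797
bins, knockout d ≈ 2.51) depend on those real-data properties and on the
complete mouse genome, and can only be reproduced by running this
pipeline on the original datasets.

## Degenerate inputs and numerical choices

Empty repeat input yields empty output (not an error); zero-signal tracks
refuse normalization; zero-variance paired differences and zero pooled SD
raise explicit degenerate-test errors; segmentation gaps under a peak
raise an annotation error rather than silently dropping the peak; bins
with zero coverage are excluded from ratio analyses with a recorded
reason. Ties in largest-overlap assignment break deterministically by
annotation sort order; largest-fragment naming ties break by leftmost
member. Interval placement in the shuffler and the generator uses bounded
rejection sampling and names the offending interval on failure.

## Known limitations

- Per-base track storage bounds practical genome size to tens of
  megabases; a binned backend (the contract allows it within
  bin-quantization error) would be needed for full mammalian genomes.
- Presence calling assumes the curated annotation is correct and
  non-overlapping; it detects absence of reference insertions only, not
  non-reference insertions.
- The bootstrap "±" on effect sizes is one plausible reading of reference
  values whose definition is unstated.
- The consensus rule treats replicates symmetrically; no
  irreproducible-discovery-rate weighting is attempted.
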