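# ervdyn

Analysis pipeline for chromatin dynamics at IAP endogenous retroviruses
(ERVs) in mouse embryonic stem cells.

Interstitial heterochromatin — confined H3K9me3 domains outside
pericentromeric regions, most prominently over intracisternal A-particle
(IAP) ERVs — is unusual in mouse ESCs: it carries the turnover-associated
histone variant H3.3 while keeping its DNA inaccessible, and loses that
closed state specifically when H3.3 is absent. Demonstrating this from
ChIP-seq and ATAC-seq data requires a chain of bespoke computational
steps, which this package implements as a tested, reusable library:

- **Repeat curation** — RepeatMasker-style fragments (LTR and internal
  pieces) are clustered with zero allowed gap, merged elements are named
  after their largest fragment (typically `IAPEz-int`), and clusters
  shorter than 2 kb are removed; solo LTRs (LTR clusters with no internal
  sequence) are identified separately.
- **Cross-strain presence calling** — IAP insertions are polymorphic
  between mouse strains, so reference-annotated elements are called
  present/absent per cell line from *anchoring read pairs*: a pair whose
  fragment span overlaps the element with at least one mate uniquely
  mapped (MQ > 10). One anchoring pair in any dataset of a cell line is
  evidence of presence; the *shared set* is the intersection across cell
  lines, and all cross-cell-line signal comparisons are restricted to it.
- **1x-genome-coverage normalization** — read (RPGC) or paired-end
  fragment (FPGC) pileups are scaled so the mean over the effective
  genome is 1; values above 1 are fold-enrichment over the genome
  average.
- **Bin enrichment statistics** — genome-wide 5 kb bins, log2 ChIP/input
  ratios with zero-bin exclusion (no pseudocounts), group overlays by
  largest overlap, two-sided Wilcoxon rank sum, Cohen's
  d = (x̄₁ − x̄₂)/s_pooled, paired t tests, and Tukey 1.5 IQR trimming
  for distribution displays only.
- **Replicate-consensus peaks** — peaks called in ≥ 2 of 3 replicates,
  reported as the merged span of each overlap-connected component, then
  classified (H3.3-only / H3.3+H3K9me3 / H3K9me3-only, any overlap > 0)
  and annotated with chromatin states by largest overlap.
- **Profiles and heatmaps** — reference-point (±2500 bp) and scaled-body
  (6500 bp body) coverage matrices, average profiles, row ordering
  propagated across heatmap panels, length-matched shuffled control
  regions, and per-chromatin-state mean log2-ratio matrices.
- **Synthetic data** — a seeded generator plants a toy genome with
  LTR–internal–LTR elements, solo LTRs, strain polymorphism,
  multimapping (MQ 0) inside internal sequence, mark-specific fold
  enrichments and replicate peak calls with jitter/dropout, recording
  ground truth so every stage is scored without external downloads.

## Worked example

The analysis drivers under `analysis/` run the full chain on the
synthetic study and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_curate_repeats.py
python analysis/03_presence_calling.py --seed 1
python analysis/04_bin_enrichment.py --seed 1
python analysis/05_consensus_peaks.py --seed 1
python analysis/06_profiles_heatmaps.py --seed 1
```

Selected output at seed 1:

```
curated 36 IAP elements from 136 fragments (coordinates match planted truth: True)
presence calls match planted truth: 1.000 (anchoring evidence at depth 8x)
shared set: 31 elements present in all strains (31 all-true rows)
1200 bins of 5 kb; 65 overlap the 31 shared IAP elements
KO/WT log2 fold change at IAP bins: 1.296 (planted accessibility gain: log2(3) = 1.585)
IAP bins vs genome-wide -- WT: d = -0.084, p = 0.371; KO: d = 3.691, p = 4.76e-37
H3.3: 99 consensus peaks from [92, 94, 92] replicate calls; base-pair Jaccard vs truth 0.941
KO plateau over shuffled-control baseline: 2.99 (planted fold 3.0; ...)
```

Reading these numbers: curation reassembles exactly the planted
elements; presence calling recovers the strain polymorphism perfectly and
the shared set equals the truth intersection; bins overlapping shared
IAPs are indistinguishable from the genome-wide accessibility
distribution in wildtype (d ≈ 0, p = 0.37) but strongly shifted in the
H3.3 knockout (d = 3.7); the measured fold gain at IAP bins (log2 FC
1.30) sits below the planted log2(3) = 1.58 because 5 kb bins only
partially overlap element domains and 1x normalization redistributes the
gained signal mass; the scaled-body profile over element bodies recovers
the planted threefold gain against the shuffled control (2.99).

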