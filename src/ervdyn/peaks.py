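"""Replicate-consensus peaks and overlap-based peak classification.

Peak calls from individual replicates (MACS2 broadPeak files) are combined
into a consensus: peaks from all replicates are placed in an overlap graph
(edge = any overlap > 0, within- and between-replicate alike) and each
connected component supported by the required number of distinct
replicates emits one consensus peak spanning the component. This restates
"called in at least two out of three replicates" plus "merging the
overlapping called peak regions" in a form that is well defined for chains
of partially overlapping peaks and invariant to replicate order.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .errors import AnnotationError, ParameterError
from .genome import (
    GenomicInterval,
    IntervalSet,
    assign_by_largest_overlap,
    UNASSIGNED,
)

__all__ = ["consensus_peaks", "classify_by_overlap", "annotate_chromhmm"]


def consensus_peaks(replicates: Sequence[IntervalSet], min_reps: int = 2) -> IntervalSet:
    """Merge replicate peak calls into consensus peaks.

    Returns consensus peaks (sorted) with a ``"support"`` attribute giving
    the set of replicate indices contributing to each peak. Components
    supported by fewer than ``min_reps`` distinct replicates are dropped.
    """
    if min_reps < 1:
        raise ParameterError(f"min_reps must be >= 1, got {min_reps}")
    if min_reps > len(replicates):
        raise ParameterError(
            f"min_reps={min_reps} exceeds the {len(replicates)} replicates given"
        )
    tagged: List[Tuple[GenomicInterval, int]] = [
        (iv, r) for r, reps in enumerate(replicates) for iv in reps
    ]
    tagged.sort(key=lambda t: t[0].key)
    out: List[GenomicInterval] = []
    support: List[frozenset] = []
    cur_start = cur_end = None
    cur_chrom = None
    cur_reps: set = set()
    n = 0

    def flush() -> None:
        nonlocal n
        if cur_chrom is not None and len(cur_reps) >= min_reps:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end, f"consensus_{n}"))
            support.append(frozenset(cur_reps))
            n += 1

    for iv, r in tagged:
        # strict overlap chains a component; abutting peaks do not connect
        if cur_chrom == iv.chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
            cur_reps.add(r)
        else:
            flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_reps = {r}
    flush()
    # renumber deterministically in sorted order (already sorted by sweep)
    return IntervalSet(out, {"support": support})


def classify_by_overlap(
    primary: IntervalSet,
    secondary: IntervalSet,
    labels: Tuple[str, str, str] = ("H3.3-only", "H3.3+H3K9me3", "H3K9me3-only"),
) -> Dict[str, IntervalSet]:
    """Partition two peak sets into only/shared classes by any overlap > 0.

    Each primary peak is labeled shared if it overlaps any secondary peak
    (1 bp suffices), otherwise primary-only; secondary peaks with no
    primary overlap form the secondary-only class. Classes are mutually
    exclusive and exhaustive over the two inputs; counts are Venn-ready.
    """
    only_p, shared, only_s = [], [], []
    for iv in primary:
        (shared if secondary.overlapping(iv.chrom, iv.start, iv.end) else only_p).append(iv)
    for iv in secondary:
        if not primary.overlapping(iv.chrom, iv.start, iv.end):
            only_s.append(iv)
    return {
        labels[0]: IntervalSet(only_p),
        labels[1]: IntervalSet(shared),
        labels[2]: IntervalSet(only_s),
    }


def annotate_chromhmm(peaks: IntervalSet, segmentation: IntervalSet) -> List[str]:
    """Assign each peak the chromatin state it overlaps the most.

    The segmentation must be a partition of the genome, so every peak
    falls in at least one state; a peak covered by no segment raises an
    error. Multi-state peaks take the state with the largest overlap.
    """
    labels = assign_by_largest_overlap(peaks, segmentation)
    for iv, label in zip(peaks, labels):
        if label == UNASSIGNED:
            raise AnnotationError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} overlaps no segment; "
                "the segmentation is not a partition of the genome"
            )
    return labels
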