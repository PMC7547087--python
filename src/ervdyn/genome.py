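"""Genome model and interval algebra.

All coordinates are 0-based, half-open (BED convention). Strand is stored
but ignored by every overlap and pileup operation; the procedures built on
top of this module are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError, PlacementError

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "IntervalSet",
    "make_bins",
    "overlap_length",
    "merge_intervals",
    "assign_by_largest_overlap",
    "shuffle_matched",
    "overlap_counts",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths and an effective genome size.

    The effective genome size is the denominator of 1x-coverage
    normalization. For the mouse reference the published analyses use
    2,150,570,000 bp; for synthetic genomes it defaults to the summed
    chromosome length.
    """

    lengths: Mapping[str, int]
    effective_genome_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ParameterError("genome must contain at least one chromosome")
        if len(set(self.lengths)) != len(list(self.lengths)):
            raise ParameterError("chromosome names must be unique")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ParameterError(f"chromosome {name!r} has non-positive length {length}")
        total = sum(self.lengths.values())
        egs = self.effective_genome_size
        if egs is None:
            object.__setattr__(self, "effective_genome_size", total)
        elif not (0 < egs <= total):
            raise ParameterError(
                f"effective genome size {egs} must be in (0, {total}]"
            )

    @property
    def chromosomes(self) -> List[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ParameterError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional metadata."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ParameterError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


class IntervalSet:
    """A sortable collection of :class:`GenomicInterval`.

    ``attrs`` is an optional per-interval attribute map: each key holds a
    list aligned with the interval order; it is re-ordered with the
    intervals on :meth:`sorted`.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        attrs: Optional[Dict[str, List]] = None,
    ) -> None:
        self.intervals: List[GenomicInterval] = list(intervals)
        self.attrs: Dict[str, List] = attrs or {}
        for key, values in self.attrs.items():
            if len(values) != len(self.intervals):
                raise ParameterError(
                    f"attribute {key!r} has {len(values)} values for "
                    f"{len(self.intervals)} intervals"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals)"

    def sorted(self) -> "IntervalSet":
        """Return a copy ordered (chrom, start, end)-lexicographically."""
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i].key)
        return self.subset(order)

    def subset(self, indices: Sequence[int]) -> "IntervalSet":
        return IntervalSet(
            [self.intervals[i] for i in indices],
            {k: [v[i] for i in indices] for k, v in self.attrs.items()},
        )

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def overlapping(self, chrom: str, start: int, end: int) -> List[int]:
        """Indices of member intervals with overlap length > 0 with the query."""
        hits = []
        for i, iv in enumerate(self.intervals):
            if iv.chrom == chrom and iv.start < end and start < iv.end:
                hits.append(i)
        return hits

    def total_span(self) -> int:
        """Total base pairs covered (overlaps counted once)."""
        merged = merge_intervals(self, max_gap=0)
        return sum(iv.length for iv in merged)

    def names(self) -> List[str]:
        return [iv.name for iv in self.intervals]


def make_bins(genome: GenomeModel, width: int) -> IntervalSet:
    """Tile every chromosome with non-overlapping bins of ``width`` bp.

    The last bin of each chromosome is truncated at the chromosome end.
    Bins are named ``"{chrom}:{index}"``.
    """
    if width < 1:
        raise ParameterError(f"bin width must be >= 1, got {width}")
    bins = []
    for chrom, length in genome.lengths.items():
        for i, start in enumerate(range(0, length, width)):
            bins.append(
                GenomicInterval(chrom, start, min(start + width, length), f"{chrom}:{i}")
            )
    return IntervalSet(bins)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose pairwise gap is <= ``max_gap``.

    Abutting intervals have gap 0, so the default merges them ("allowing
    for no gaps") while a 1 bp gap keeps intervals apart. The result is
    sorted, idempotent under re-merging, and carries a ``"members"``
    attribute listing the input intervals merged into each output.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    svals = intervals.sorted()
    merged: List[GenomicInterval] = []
    members: List[List[GenomicInterval]] = []
    for iv in svals:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end), prev.name
            )
            members[-1].append(iv)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.name))
            members.append([iv])
    return IntervalSet(merged, {"members": members})


def assign_by_largest_overlap(
    queries: IntervalSet, annotations: IntervalSet
) -> List[str]:
    """Label each query with the annotation it overlaps the most.

    Queries with no overlap receive ``"unassigned"``. Ties are broken by
    the (chrom, start, end, name) order of the annotations, which makes
    the assignment deterministic and independent of input order.
    """
    anns = sorted(annotations, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in anns:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in by_chrom.items()}
    labels = []
    for q in queries:
        if q.chrom not in by_chrom:
            labels.append(UNASSIGNED)
            continue
        ov = np.minimum(ends[q.chrom], q.end) - np.maximum(starts[q.chrom], q.start)
        best = -1
        best_len = 0
        for i in np.nonzero(ov > 0)[0]:
            if ov[i] > best_len:
                best, best_len = i, int(ov[i])
        labels.append(by_chrom[q.chrom][best].name if best >= 0 else UNASSIGNED)
    return labels


def shuffle_matched(
    source: IntervalSet,
    genome: GenomeModel,
    seed: int,
    exclude: Optional[IntervalSet] = None,
    max_attempts: int = 1000,
) -> IntervalSet:
    """Place length-matched random control regions, as for shuffled controls.

    Each source interval is re-placed on a chromosome chosen with
    probability proportional to the number of valid start positions
    (``length - interval length + 1``), then uniformly within it. Placements
    overlapping ``exclude`` are rejected and redrawn. By default the source
    intervals themselves are excluded, so controls never sit on the regions
    they are matched to. Identical seeds give identical output.
    """
    if exclude is None:
        exclude = source
    rng = np.random.default_rng(seed)
    excl_by_chrom = exclude.by_chrom()
    out = []
    chroms = genome.chromosomes
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    for iv in source:
        if iv.length >= max(lengths):
            raise ParameterError(
                f"interval {iv.name or iv.key} is longer than every chromosome"
            )
        space = np.maximum(lengths - iv.length + 1, 0)
        p = space / space.sum()
        placed = None
        for _ in range(max_attempts):
            ci = rng.choice(len(chroms), p=p)
            chrom = chroms[ci]
            start = int(rng.integers(0, genome.lengths[chrom] - iv.length + 1))
            end = start + iv.length
            clash = any(
                e.start < end and start < e.end for e in excl_by_chrom.get(chrom, [])
            )
            if not clash:
                placed = GenomicInterval(chrom, start, end, iv.name)
                break
        if placed is None:
            raise PlacementError(
                f"could not place interval {iv.name or iv.key} "
                f"after {max_attempts} attempts"
            )
        out.append(placed)
    return IntervalSet(out)


def overlap_counts(
    sets: Mapping[str, IntervalSet]
) -> Dict[str, Dict[Tuple[str, ...], int]]:
    """Venn-style membership counts for 2-4 named interval sets.

    For each set, every member interval is assigned the combination of set
    names it overlaps (any overlap > 0; its own set is always included),
    and intervals are counted per combination. Counts are interval counts
    from each set's perspective, not base pairs, so perspectives of the
    same combination can differ.
    """
    if not (2 <= len(sets) <= 4):
        raise ParameterError(f"overlap_counts takes 2-4 sets, got {len(sets)}")
    result: Dict[str, Dict[Tuple[str, ...], int]] = {}
    for name, ivs in sets.items():
        combos: Dict[Tuple[str, ...], int] = {}
        for iv in ivs:
            combo = {name}
            for other, oset in sets.items():
                if other == name:
                    continue
                if oset.overlapping(iv.chrom, iv.start, iv.end):
                    combo.add(other)
            key = tuple(sorted(combo))
            combos[key] = combos.get(key, 0) + 1
        result[name] = combos
    return result
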