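"""Cross-strain presence calling for reference-annotated ERV insertions.

IAP ERVs are polymorphic between mouse strains: an element annotated in
the reference genome may be absent from the strain a cell line derives
from. Signal comparisons across cell lines are therefore restricted to
elements present in every strain. Presence is evidenced by "anchoring"
read pairs: pairs whose fragment span overlaps the reference element while
at least one mate maps uniquely (MQ strictly greater than 10). One or more
anchoring pairs in any dataset of a cell line marks the element present in
that strain; the shared set is the intersection across cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParameterError
from .genome import IntervalSet

__all__ = [
    "PresenceMatrix",
    "extract_anchoring_pairs",
    "call_presence",
    "pool_by_cell_line",
    "shared_elements",
]


@dataclass
class PresenceMatrix:
    """Element x unit presence calls with the anchoring counts behind them.

    ``level`` records whether columns are datasets or cell lines. Rows are
    indexed by element name in the coordinate order of ``elements``.
    """

    elements: IntervalSet
    counts: pd.DataFrame
    presence: pd.DataFrame
    level: str = "dataset"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.presence.index):
            raise ParameterError("counts and presence must share an index")


def _check_nonoverlapping(elements: IntervalSet) -> IntervalSet:
    svals = elements.sorted()
    prev = None
    for iv in svals:
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
            raise ParameterError(
                f"elements overlap: {prev.name} and {iv.name}; presence calling "
                "requires the non-overlapping curated annotation"
            )
        prev = iv
    return svals


def extract_anchoring_pairs(
    fragments: pd.DataFrame,
    elements: IntervalSet,
    mq_min: int = 10,
) -> pd.DataFrame:
    """Count anchoring pairs per (element, dataset).

    A fragment anchors an element iff its span overlaps the element
    (overlap > 0) and max(mq1, mq2) > ``mq_min`` (strict, matching the
    "MQ > 10" unique-mate rule). Fragments spanning two elements are
    counted once, for the element with the larger overlap. Single-end
    records can be passed with mq2 = mq1.

    Returns a counts DataFrame indexed by element name with one column per
    dataset id, in element coordinate order.
    """
    if (fragments["start"] >= fragments["end"]).any():
        raise DataError("fragment with start >= end")
    elements = _check_nonoverlapping(elements)
    names = elements.names()
    if len(set(names)) != len(names):
        raise ParameterError("element names must be unique; use coordinate-tagged ids")
    datasets = sorted(fragments["dataset"].unique())
    counts = pd.DataFrame(0, index=pd.Index(names, name="element"), columns=datasets)

    by_chrom: Dict[str, List[int]] = {}
    for i, iv in enumerate(elements):
        by_chrom.setdefault(iv.chrom, []).append(i)
    anchored = fragments[np.maximum(fragments["mq1"], fragments["mq2"]) > mq_min]
    for (chrom, dataset), grp in anchored.groupby(["chrom", "dataset"], sort=True):
        idx = by_chrom.get(chrom)
        if not idx:
            continue
        el_starts = np.array([elements[i].start for i in idx])
        el_ends = np.array([elements[i].end for i in idx])
        fs = grp["start"].to_numpy()
        fe = grp["end"].to_numpy()
        # elements are sorted and disjoint: overlapping elements for a
        # fragment form the contiguous run [lo, hi)
        lo = np.searchsorted(el_ends, fs, side="right")
        hi = np.searchsorted(el_starts, fe, side="left")
        single = hi - lo == 1
        if single.any():
            hits = np.bincount(lo[single], minlength=len(idx))
            counts.loc[np.array(names)[np.array(idx)], dataset] += hits
        multi = np.nonzero(hi - lo > 1)[0]
        for k in multi:
            cand = np.arange(lo[k], hi[k])
            ov = np.minimum(el_ends[cand], fe[k]) - np.maximum(el_starts[cand], fs[k])
            best = cand[int(np.argmax(ov))]
            counts.loc[names[idx[best]], dataset] += 1
    return counts


def call_presence(
    counts: pd.DataFrame,
    elements: IntervalSet,
    min_anchors: int = 1,
) -> PresenceMatrix:
    """Dataset-level presence: count >= ``min_anchors`` anchoring pairs."""
    if min_anchors < 1:
        raise ParameterError(f"min_anchors must be >= 1, got {min_anchors}")
    presence = counts >= min_anchors
    return PresenceMatrix(elements=elements, counts=counts, presence=presence)


def pool_by_cell_line(
    matrix: PresenceMatrix,
    dataset_to_cell_line: Mapping[str, str],
) -> PresenceMatrix:
    """Pool dataset-level evidence into cell-line calls (logical OR).

    Evidence from all datasets of a cell line (ChIP and matched inputs) is
    used collectively; anchoring counts are summed per cell line.
    """
    unmapped = [d for d in matrix.counts.columns if d not in dataset_to_cell_line]
    if unmapped:
        raise ConfigurationError(f"datasets not mapped to a cell line: {unmapped}")
    groups = pd.Series({d: dataset_to_cell_line[d] for d in matrix.counts.columns})
    counts = matrix.counts.T.groupby(groups).sum().T
    presence = matrix.presence.T.groupby(groups).any().T
    return PresenceMatrix(
        elements=matrix.elements, counts=counts, presence=presence, level="cell_line"
    )


def shared_elements(matrix: PresenceMatrix) -> IntervalSet:
    """Elements present in every cell line (all-true rows), with coordinates."""
    if matrix.presence.shape[1] < 1:
        raise ParameterError("at least one cell line is required")
    keep_names = set(matrix.presence.index[matrix.presence.all(axis=1)])
    idx = [i for i, iv in enumerate(matrix.elements) if iv.name in keep_names]
    return matrix.elements.subset(idx)
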