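"""Curation of fragmented repeat annotation into full-length elements.

RepeatMasker annotates retroelements as separate LTR and internal
fragments. Full-length IAP-class elements are reassembled by clustering
abutting fragments (gap 0 by default), naming each cluster after its
largest member (typically the internal sequence, e.g. IAPEz-int), and
discarding clusters shorter than a minimum length (2 kb by default), which
removes solo LTRs and small scraps from the element annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .errors import ParameterError
from .genome import GenomicInterval, IntervalSet, merge_intervals

__all__ = [
    "CuratedRepeatElement",
    "curate_repeats",
    "identify_solo_ltrs",
    "family_of",
    "DEFAULT_FAMILY_PREFIXES",
]

# Prefix table mapping repName prefixes to family group labels used for
# bin/peak annotation. Configurable; this default groups the IAP LTR and
# internal names under one "IAP" label.
DEFAULT_FAMILY_PREFIXES: Dict[str, str] = {
    "IAP": "IAP",
    "ETn": "ETn",
    "MusD": "MusD",
    "MMERVK": "MMERVK",
}


def family_of(rep_name: str, prefixes: Optional[Dict[str, str]] = None) -> str:
    """Family group label for a repName, by longest matching prefix."""
    table = DEFAULT_FAMILY_PREFIXES if prefixes is None else prefixes
    best = ""
    label = "other"
    for prefix, fam in table.items():
        if rep_name.startswith(prefix) and len(prefix) > len(best):
            best, label = prefix, fam
    return label


@dataclass(frozen=True)
class CuratedRepeatElement:
    """A merged repeat cluster named after its largest member fragment."""

    interval: GenomicInterval
    name: str
    members: Tuple[GenomicInterval, ...]
    family: str
    solo_ltr: bool = False

    @property
    def length(self) -> int:
        return self.interval.length


def curate_repeats(
    fragments: IntervalSet,
    max_gap: int = 0,
    min_len: int = 2000,
    families: Optional[Sequence[str]] = None,
    family_prefixes: Optional[Dict[str, str]] = None,
    ltr_names: Optional[Set[str]] = None,
    internal_names: Optional[Set[str]] = None,
) -> List[CuratedRepeatElement]:
    """Merge repeat fragments into curated elements.

    Parameters
    ----------
    fragments:
        Repeat fragments; the interval ``name`` is the repName.
    max_gap:
        Maximum gap between clustered fragments. 0 merges abutting
        fragments only; a 1 bp gap separates clusters.
    min_len:
        Minimum merged element length; shorter clusters are dropped
        (2 kb removes solo LTRs from the element annotation). 0 disables
        the filter, making curation a pure merge.
    families:
        Optional repName prefixes; fragments not matching any prefix are
        ignored before clustering (e.g. ``["IAP"]``).
    ltr_names / internal_names:
        Optional disjoint repName sets used to flag elements whose members
        contain an LTR name but no internal name as solo LTRs.

    Returns curated elements sorted by coordinate; member composition is
    retained on each element.
    """
    if min_len < 0:
        raise ParameterError(f"min_len must be >= 0, got {min_len}")
    if ltr_names and internal_names and (set(ltr_names) & set(internal_names)):
        raise ParameterError("ltr_names and internal_names must be disjoint")
    if families is not None:
        keep = [
            i for i, iv in enumerate(fragments)
            if any(iv.name.startswith(p) for p in families)
        ]
        fragments = fragments.subset(keep)
    merged = merge_intervals(fragments, max_gap=max_gap)
    elements: List[CuratedRepeatElement] = []
    for iv, members in zip(merged, merged.attrs["members"]):
        if iv.length < min_len:
            continue
        # largest member names the element; length ties -> leftmost member
        largest = max(members, key=lambda m: (m.length, -m.start))
        solo = False
        if ltr_names:
            has_ltr = any(m.name in ltr_names for m in members)
            has_int = bool(internal_names) and any(
                m.name in internal_names for m in members
            )
            solo = has_ltr and not has_int
        elements.append(
            CuratedRepeatElement(
                interval=iv.with_name(largest.name),
                name=largest.name,
                members=tuple(members),
                family=family_of(largest.name, family_prefixes),
                solo_ltr=solo,
            )
        )
    return elements


def elements_to_intervals(elements: Iterable[CuratedRepeatElement]) -> IntervalSet:
    """IntervalSet view of curated elements with unique coordinate ids.

    Names are ``repName|chrom:start-end`` so downstream matrices indexed by
    name stay unambiguous when a family name recurs.
    """
    ivs = []
    for el in elements:
        iv = el.interval
        ivs.append(iv.with_name(f"{el.name}|{iv.chrom}:{iv.start}-{iv.end}"))
    return IntervalSet(ivs, {"element": list(elements)})


def identify_solo_ltrs(
    fragments: IntervalSet,
    ltr_names: Set[str],
    internal_names: Set[str],
    enrichment_peaks: Optional[IntervalSet] = None,
) -> IntervalSet:
    """LTR fragments whose gap-free cluster contains no internal sequence.

    These are the orphan ("solo") LTRs left behind by recombination of a
    full-length element. When ``enrichment_peaks`` is given, only solo LTRs
    with any overlap > 0 with a peak are returned, mirroring selection of
    enriched orphan LTRs.
    """
    if set(ltr_names) & set(internal_names):
        raise ParameterError("ltr_names and internal_names must be disjoint")
    merged = merge_intervals(fragments, max_gap=0)
    solos: List[GenomicInterval] = []
    for members in merged.attrs["members"]:
        if any(m.name in internal_names for m in members):
            continue
        solos.extend(m for m in members if m.name in ltr_names)
    if enrichment_peaks is not None:
        solos = [
            iv for iv in solos
            if enrichment_peaks.overlapping(iv.chrom, iv.start, iv.end)
        ]
    return IntervalSet(sorted(solos, key=lambda iv: iv.key))
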