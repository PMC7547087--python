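"""Coverage tracks, 1x-genome normalization and binned log2 enrichment.

Tracks are stored per-base (float64) per chromosome, which is exact for
the toy genomes this package targets; all operations are defined on
per-base semantics. Normalization to 1x genome coverage divides by the
realized mean over the effective genome, so values above 1 are
fold-enrichment over the genome average and values below 1 depletion.
Read-resolution tracks are tagged RPGC, fragment-resolution tracks FPGC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, NormalizationError, ParameterError
from .genome import GenomeModel, IntervalSet

__all__ = [
    "CoverageTrack",
    "pileup",
    "normalize_1x",
    "mean_per_interval",
    "log2_ratio_bins",
    "log2_ratio_track",
    "bin_table",
]


@dataclass
class CoverageTrack:
    """Per-base signal vectors per chromosome with a normalization tag."""

    genome: GenomeModel
    data: Dict[str, np.ndarray]
    norm: str = "raw"  # raw | RPGC | FPGC | log2ratio
    provenance: Dict[str, object] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def genome_mean(self) -> float:
        return self.total() / self.genome.effective_genome_size

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.genome, {c: v.copy() for c, v in self.data.items()},
            self.norm, dict(self.provenance),
        )

    @classmethod
    def zeros(cls, genome: GenomeModel, norm: str = "raw") -> "CoverageTrack":
        return cls(genome, {c: np.zeros(l) for c, l in genome.lengths.items()}, norm)


def pileup(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    mode: str = "fragments",
    extend: int = 150,
    mq_min: Optional[int] = None,
) -> CoverageTrack:
    """Paint +1 per record over its footprint.

    mode="fragments": each record covers its fragment span [start, end).
    mode="reads": single-end semantics; each record covers
    [start, start + extend) clipped at the chromosome end (records already
    carrying a paired fragment span can equivalently use mode="fragments",
    where coverage is extended to the true fragment length).

    When ``mq_min`` is set, records with MQ <= mq_min are excluded (strict,
    so "MQ > 10" is retained with mq_min=10); the record MQ is
    max(mq1, mq2). Records running past the chromosome end are clipped and
    counted in ``provenance["clipped"]``.
    """
    if mode not in ("fragments", "reads"):
        raise ParameterError(f"unknown pileup mode {mode!r}")
    if mode == "reads" and extend < 1:
        raise ParameterError("extend must be >= 1 in read mode")
    track = CoverageTrack.zeros(genome)
    frags = fragments
    if mq_min is not None:
        frags = frags[np.maximum(frags["mq1"], frags["mq2"]) > mq_min]
    clipped = 0
    for chrom, grp in frags.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ParameterError(f"fragment on unknown chromosome {chrom!r}")
        length = genome.lengths[chrom]
        starts = grp["start"].to_numpy(dtype=np.int64)
        if mode == "reads":
            ends = starts + extend
        else:
            ends = grp["end"].to_numpy(dtype=np.int64)
        clipped += int((ends > length).sum() + (starts < 0).sum())
        starts = np.clip(starts, 0, length)
        ends = np.clip(ends, 0, length)
        ok = ends > starts
        diff = np.zeros(length + 1)
        np.add.at(diff, starts[ok], 1.0)
        np.add.at(diff, ends[ok], -1.0)
        track.data[chrom] = np.cumsum(diff[:-1])
    if clipped:
        warnings.warn(f"{clipped} records clipped at chromosome ends")
    track.provenance.update(
        mode=mode, extend=extend if mode == "reads" else None,
        mq_min=mq_min, clipped=clipped,
    )
    return track


def normalize_1x(track: CoverageTrack, genome: Optional[GenomeModel] = None) -> CoverageTrack:
    """Scale a raw track so its mean over the effective genome is 1.

    The scale factor is effective_genome_size / sum(per-base coverage),
    computed from the realized coverage (after any MQ filtering and
    clipping), so read- and fragment-resolution tracks share one exact
    definition. The tag becomes RPGC for read-mode pileups and FPGC for
    fragment-mode pileups.
    """
    genome = genome or track.genome
    total = track.total()
    if total <= 0:
        raise NormalizationError("cannot 1x-normalize a track with zero total signal")
    scale = genome.effective_genome_size / total
    out = track.copy()
    for chrom in out.data:
        out.data[chrom] *= scale
    if track.norm in ("RPGC", "FPGC"):
        out.norm = track.norm  # re-normalizing is a no-op in exact arithmetic
    else:
        out.norm = "RPGC" if track.provenance.get("mode") == "reads" else "FPGC"
    out.provenance["scale_1x"] = scale
    return out


def mean_per_interval(
    track: CoverageTrack, intervals: IntervalSet, nan_aware: bool = False
) -> np.ndarray:
    """Arithmetic mean of per-base values over each interval.

    With ``nan_aware`` missing values (NaN, as in log2-ratio tracks) are
    excluded from both numerator and denominator; an interval with no
    finite base yields NaN.
    """
    csums: Dict[str, np.ndarray] = {}
    cnts: Dict[str, np.ndarray] = {}
    for chrom, vals in track.data.items():
        if nan_aware:
            finite = np.isfinite(vals)
            csums[chrom] = np.concatenate(([0.0], np.cumsum(np.where(finite, vals, 0.0))))
            cnts[chrom] = np.concatenate(([0], np.cumsum(finite)))
        else:
            csums[chrom] = np.concatenate(([0.0], np.cumsum(vals)))
    out = np.empty(len(intervals))
    for i, iv in enumerate(intervals):
        if iv.chrom not in track.data:
            raise ParameterError(f"interval on unknown chromosome {iv.chrom!r}")
        cs = csums[iv.chrom]
        if iv.end > len(cs) - 1:
            raise ParameterError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
            )
        total = cs[iv.end] - cs[iv.start]
        if nan_aware:
            n = cnts[iv.chrom][iv.end] - cnts[iv.chrom][iv.start]
            out[i] = total / n if n > 0 else np.nan
        else:
            out[i] = total / iv.length
    return out


def log2_ratio_bins(
    chip: np.ndarray, input_: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """log2(ChIP/input) per bin, excluding zero bins instead of pseudocounting.

    Returns (values, excluded): ``values`` is NaN wherever either side is
    zero and ``excluded`` is the boolean exclusion mask. Negative values
    are a data error; no pseudocount is ever applied.
    """
    chip = np.asarray(chip, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if chip.shape != input_.shape:
        raise ParameterError("chip and input bin vectors differ in length")
    if (chip < 0).any() or (input_ < 0).any():
        raise DataError("negative coverage values")
    excluded = (chip == 0) | (input_ == 0)
    values = np.full(chip.shape, np.nan)
    ok = ~excluded
    values[ok] = np.log2(chip[ok] / input_[ok])
    return values, excluded


def log2_ratio_track(chip: CoverageTrack, input_: CoverageTrack) -> CoverageTrack:
    """Per-base log2(ChIP/input) track; bases with a zero on either side are NaN."""
    if set(chip.data) != set(input_.data):
        raise ParameterError("tracks are on different genomes")
    out = CoverageTrack(chip.genome, {}, "log2ratio")
    for chrom, c in chip.data.items():
        i = input_.data[chrom]
        if (c < 0).any() or (i < 0).any():
            raise DataError("negative coverage values")
        vals = np.full(c.shape, np.nan)
        ok = (c > 0) & (i > 0)
        vals[ok] = np.log2(c[ok] / i[ok])
        out.data[chrom] = vals
    return out


def bin_table(
    tracks: Dict[str, CoverageTrack], bins: IntervalSet
) -> pd.DataFrame:
    """Mean coverage per bin for each named track, as a tidy table.

    Columns: chrom/start/end/name plus one column per track. This is the
    bin-level container behind the genome-wide 5 kb analyses.
    """
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in bins],
            "start": [iv.start for iv in bins],
            "end": [iv.end for iv in bins],
            "name": bins.names(),
        }
    )
    for name, track in tracks.items():
        df[name] = mean_per_interval(track, bins, nan_aware=track.norm == "log2ratio")
    return df
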