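"""Readers and writers for the coordinate formats the pipeline consumes.

Supported: BED3/BED6, ENCODE broadPeak, two-column chrom.sizes, UCSC
RepeatMasker table export (rmsk TSV), plain fragment tables, bedGraph, and
SAM via pysam. All writers emit deterministic, (chrom, start, end)-sorted
output. SAM 1-based coordinates are converted to 0-based half-open at this
boundary; everything inside the package is BED convention.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .genome import GenomeModel, GenomicInterval, IntervalSet

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_broadpeak",
    "write_broadpeak",
    "read_rmsk",
    "write_rmsk",
    "read_fragments_tsv",
    "write_fragments_tsv",
    "read_fragments_sam",
    "write_fragments_sam",
    "write_bedgraph",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mq1", "mq2", "dataset"]


def read_chrom_sizes(path: str, effective_genome_size: Optional[int] = None) -> GenomeModel:
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: expected two tab-separated columns")
            lengths[fields[0]] = int(fields[1])
    return GenomeModel(lengths, effective_genome_size)


def write_chrom_sizes(genome: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str) -> IntervalSet:
    """Read BED3/BED6. Extra columns are ignored."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise DataError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                name = f[3] if len(f) > 3 else "."
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                strand = f[5] if len(f) > 5 else "."
                ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand, score))
            except (ValueError,) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(ivs)


def write_bed(intervals: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals.sorted():
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_broadpeak(path: str) -> IntervalSet:
    """Read an ENCODE broadPeak file (9 tab-separated columns)."""
    ivs = []
    attrs: Dict[str, List] = {"signalValue": [], "pValue": [], "qValue": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise DataError(f"{path}:{lineno}: broadPeak needs 9 columns, got {len(f)}")
            ivs.append(
                GenomicInterval(
                    f[0], int(f[1]), int(f[2]), f[3],
                    f[5] if f[5] in "+-." else ".",
                    float(f[4]),
                )
            )
            attrs["signalValue"].append(float(f[6]))
            attrs["pValue"].append(float(f[7]))
            attrs["qValue"].append(float(f[8]))
    return IntervalSet(ivs, attrs)


def write_broadpeak(intervals: IntervalSet, path: str) -> None:
    sig = intervals.attrs.get("signalValue", [0.0] * len(intervals))
    with open(path, "w") as fh:
        order = sorted(range(len(intervals)), key=lambda i: intervals[i].key)
        for i in order:
            iv = intervals[i]
            score = int(iv.score) if iv.score is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}"
                f"\t{sig[i]:g}\t-1\t-1\n"
            )


def read_rmsk(path: str) -> IntervalSet:
    """Read a UCSC rmsk-style table with genoName/genoStart/genoEnd/repName.

    repClass/repFamily columns are optional and kept as attributes when
    present. A header line is detected by the ``genoName`` column name.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"genoName", "genoStart", "genoEnd", "repName"}
    if not required.issubset(df.columns):
        raise DataError(
            f"{path}: rmsk table must contain columns {sorted(required)}"
        )
    ivs = []
    for row in df.itertuples(index=False):
        try:
            ivs.append(
                GenomicInterval(
                    str(row.genoName), int(row.genoStart), int(row.genoEnd),
                    str(row.repName),
                )
            )
        except Exception as exc:
            raise DataError(f"{path}: malformed rmsk record {row!r}: {exc}") from exc
    attrs = {}
    for col in ("repClass", "repFamily"):
        if col in df.columns:
            attrs[col] = [str(v) for v in df[col]]
    return IntervalSet(ivs, attrs)


def write_rmsk(intervals: IntervalSet, path: str) -> None:
    classes = intervals.attrs.get("repClass", ["."] * len(intervals))
    families = intervals.attrs.get("repFamily", ["."] * len(intervals))
    order = sorted(range(len(intervals)), key=lambda i: intervals[i].key)
    with open(path, "w") as fh:
        fh.write("genoName\tgenoStart\tgenoEnd\trepName\trepClass\trepFamily\n")
        for i in order:
            iv = intervals[i]
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{classes[i]}\t{families[i]}\n"
            )


def read_fragments_tsv(path: str) -> pd.DataFrame:
    """Read a fragment table (chrom, start, end, mq1, mq2, dataset)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: fragment table missing columns {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise DataError(f"{path}: fragment with start >= end")
    if (df[["mq1", "mq2"]] < 0).any().any():
        raise DataError(f"{path}: negative mapping quality")
    return df[FRAGMENT_COLUMNS]


def write_fragments_tsv(fragments: pd.DataFrame, path: str) -> None:
    out = fragments[FRAGMENT_COLUMNS].sort_values(["chrom", "start", "end"], kind="stable")
    out.to_csv(path, sep="\t", index=False)


def write_fragments_sam(fragments: pd.DataFrame, genome: GenomeModel, path: str,
                        read_length: int = 50) -> None:
    """Emit each fragment as a properly paired SAM record pair (text SAM)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.lengths[c]} for c in genome.chromosomes],
    }
    order = {c: i for i, c in enumerate(genome.chromosomes)}
    frags = fragments.sort_values(
        ["chrom", "start", "end"], kind="stable",
        key=lambda s: s.map(order) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for i, row in enumerate(frags.itertuples(index=False)):
            tid = order[row.chrom]
            span = int(row.end) - int(row.start)
            rlen = min(read_length, span)
            for mate in (0, 1):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}:{row.dataset}"
                a.reference_id = tid
                a.next_reference_id = tid
                a.flag = (99 if mate == 0 else 147)
                a.reference_start = int(row.start) if mate == 0 else int(row.end) - rlen
                a.next_reference_start = int(row.end) - rlen if mate == 0 else int(row.start)
                a.mapping_quality = int(row.mq1 if mate == 0 else row.mq2)
                a.cigarstring = f"{rlen}M"
                a.template_length = span if mate == 0 else -span
                a.query_sequence = "N" * rlen
                out.write(a)


def read_fragments_sam(path: str, dataset: Optional[str] = None) -> pd.DataFrame:
    """Reconstruct fragment spans from proper pairs in a SAM/BAM file.

    Unpaired or unmapped records are skipped (their count is recorded in
    the returned frame's ``attrs["skipped"]``). The fragment span is taken
    from the leftmost mate's start and the template length.
    """
    import pysam

    rows = []
    skipped = 0
    mq_by_name: Dict[str, int] = {}
    with pysam.AlignmentFile(path, "r") as fh:
        for rec in fh:
            if rec.is_unmapped or not rec.is_proper_pair or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if rec.template_length > 0:
                rows.append(
                    (rec.reference_name, rec.reference_start,
                     rec.reference_start + rec.template_length,
                     rec.mapping_quality, rec.query_name)
                )
            else:
                mq_by_name[rec.query_name] = rec.mapping_quality
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mq1", "qname"])
    df["mq2"] = df["qname"].map(mq_by_name).fillna(0).astype(int)
    df["dataset"] = dataset if dataset is not None else os.path.basename(path)
    df = df[FRAGMENT_COLUMNS]
    df.attrs["skipped"] = skipped
    return df


def write_bedgraph(track, path: str) -> None:
    """Write a coverage track as bedGraph, collapsing constant runs."""
    with open(path, "w") as fh:
        for chrom in track.genome.chromosomes:
            vals = track.data[chrom]
            if len(vals) == 0:
                continue
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
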