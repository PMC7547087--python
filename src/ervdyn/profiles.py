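"""Reference-point and scaled-body coverage matrices and mean profiles.

A profile matrix has one row per locus and one column per position bin.
Reference-point mode anchors the window at the locus midpoint with a
fixed flank on each side; scale-body mode linearly rescales each locus
body to a common length (6500 bp by default, the convention for
full-length IAP elements) and appends genomic flanks. Positions falling
off a chromosome end are missing and excluded from column means. Row
sorting by mean coverage can be propagated from one matrix to others in
the same figure row. Heatmap/profile rendering is provided for the
analysis drivers but only the numeric matrices are contractual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, mean_per_interval
from .errors import ContractError, ParameterError
from .genome import IntervalSet

__all__ = [
    "ProfileMatrix",
    "build_matrix",
    "summarize_matrix",
    "element_average_coverage",
    "state_mean_matrix",
    "write_matrix_tsv",
    "plot_heatmap",
]


@dataclass
class ProfileMatrix:
    """Loci x position-bin matrix with row metadata for sorting/grouping."""

    values: np.ndarray  # (n_loci, n_cols), NaN = missing
    mode: str  # "reference-point" | "scale-body"
    flank: int
    body: int  # 0 in reference-point mode
    bin_width: int
    loci: IntervalSet
    row_meta: pd.DataFrame  # columns: name, row_mean, group (optional)

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def _binned_means(csum: np.ndarray, edges: np.ndarray, length: int) -> np.ndarray:
    """Mean of per-base values between consecutive edges; NaN off-chromosome."""
    ncols = len(edges) - 1
    out = np.full(ncols, np.nan)
    valid = (edges[:-1] >= 0) & (edges[1:] <= length)
    idx = np.nonzero(valid)[0]
    if idx.size:
        lo = edges[idx]
        hi = edges[idx + 1]
        out[idx] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def build_matrix(
    track: CoverageTrack,
    loci: IntervalSet,
    mode: str = "reference-point",
    flank: int = 2500,
    body: int = 6500,
    bin_width: int = 50,
    groups: Optional[Sequence[str]] = None,
) -> ProfileMatrix:
    """Build a coverage matrix over loci.

    Reference-point mode: columns tile [center - flank, center + flank)
    where center = floor((start + end) / 2). Scale-body mode: each locus
    body is linearly rescaled to ``body`` bp and flanked by ``flank`` bp
    of real genomic sequence on both sides. ``flank`` and ``body`` must be
    multiples of ``bin_width``. Missing positions (off chromosome ends)
    are NaN.
    """
    if mode not in ("reference-point", "scale-body"):
        raise ParameterError(f"unknown matrix mode {mode!r}")
    if len(loci) == 0:
        raise ParameterError("loci must be non-empty")
    if bin_width < 1 or flank % bin_width or (mode == "scale-body" and body % bin_width):
        raise ParameterError(
            f"flank ({flank}) and body ({body}) must divide evenly by "
            f"bin width ({bin_width})"
        )
    nf = flank // bin_width
    csums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.data.items()}
    if mode == "reference-point":
        ncols = 2 * nf
    else:
        ncols = 2 * nf + body // bin_width
    values = np.full((len(loci), ncols), np.nan)
    for i, iv in enumerate(loci):
        if iv.chrom not in track.data:
            raise ParameterError(f"locus on unknown chromosome {iv.chrom!r}")
        length = len(track.data[iv.chrom])
        cs = csums[iv.chrom]
        if mode == "reference-point":
            center = (iv.start + iv.end) // 2
            edges = center - flank + bin_width * np.arange(ncols + 1)
            values[i] = _binned_means(cs, edges, length)
        else:
            left = iv.start - flank + bin_width * np.arange(nf + 1)
            values[i, :nf] = _binned_means(cs, left, length)
            right = iv.end + bin_width * np.arange(nf + 1)
            values[i, ncols - nf:] = _binned_means(cs, right, length)
            src = track.data[iv.chrom][iv.start:iv.end]
            # nearest-rank resample of the body to `body` bp, then bin-average
            pos = np.floor(np.arange(body) * iv.length / body).astype(np.int64)
            values[i, nf:ncols - nf] = src[pos].reshape(-1, bin_width).mean(axis=1)
    row_meta = pd.DataFrame(
        {
            "name": loci.names(),
            "row_mean": np.nanmean(np.where(np.isnan(values), np.nan, values), axis=1)
            if values.size else [],
        }
    )
    if groups is not None:
        if len(groups) != len(loci):
            raise ParameterError("groups must align with loci")
        row_meta["group"] = list(groups)
    return ProfileMatrix(
        values=values,
        mode=mode,
        flank=flank,
        body=0 if mode == "reference-point" else body,
        bin_width=bin_width,
        loci=loci,
        row_meta=row_meta,
    )


def summarize_matrix(
    matrix: ProfileMatrix, order_from: Optional[ProfileMatrix] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Average profile (column means, missing excluded) and row order.

    The row order is the descending argsort of per-locus row means, taken
    from ``order_from`` when given (the leftmost heatmap of a figure row),
    so the same ordering is propagated identically across panels.
    ``order_from`` must be over the identical loci.
    """
    if order_from is not None:
        if order_from.loci.names() != matrix.loci.names() or [
            iv.key for iv in order_from.loci
        ] != [iv.key for iv in matrix.loci]:
            raise ParameterError("order_from is over different loci")
        source = order_from
    else:
        source = matrix
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix.values, axis=0)
        row_means = np.nanmean(source.values, axis=1)
    order = np.argsort(-row_means, kind="stable")
    return profile, order


def element_average_coverage(
    track: CoverageTrack,
    elements: IntervalSet,
    control: Optional[IntervalSet] = None,
    flank: int = 2500,
    body: int = 6500,
    bin_width: int = 50,
) -> Dict[str, np.ndarray]:
    """Scaled-body average coverage profile over an element set.

    The track must be 1x-normalized (FPGC or RPGC): profiles from
    different samples are only comparable on the genome-average-1 scale.
    When a matched shuffled control set is given, its profile is computed
    with identical parameters under key ``"control"``.
    """
    if track.norm not in ("FPGC", "RPGC"):
        raise ContractError(
            f"average coverage profiles require a 1x-normalized track, got {track.norm!r}"
        )
    out: Dict[str, np.ndarray] = {}
    m = build_matrix(track, elements, "scale-body", flank, body, bin_width)
    out["elements"], _ = summarize_matrix(m)
    if control is not None:
        mc = build_matrix(track, control, "scale-body", flank, body, bin_width)
        out["control"], _ = summarize_matrix(mc)
    return out


def state_mean_matrix(
    tracks: Mapping[str, CoverageTrack],
    categories: Mapping[str, IntervalSet],
) -> pd.DataFrame:
    """Mean log2(ChIP/input) per annotation category per sample.

    Rows are categories (e.g. the 15 chromatin states plus extra region
    classes such as co-enriched peak regions), columns samples. Each entry
    is the unweighted mean over the category's regions of the per-region
    mean log2 ratio. Empty categories are NaN (flagged absent, not an
    error).
    """
    rows = {}
    for cat, regions in categories.items():
        entry = {}
        for sample, track in tracks.items():
            if len(regions) == 0:
                entry[sample] = np.nan
            else:
                vals = mean_per_interval(track, regions, nan_aware=True)
                entry[sample] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        rows[cat] = entry
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tracks))


def write_matrix_tsv(matrix: ProfileMatrix, path: str) -> None:
    """Write a profile matrix as TSV with a JSON header comment line."""
    header = {
        "mode": matrix.mode,
        "flank": matrix.flank,
        "body": matrix.body,
        "bin_width": matrix.bin_width,
        "n_loci": len(matrix.loci),
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        cols = "\t".join(f"bin{j}" for j in range(matrix.n_cols))
        fh.write(f"name\t{cols}\n")
        for name, row in zip(matrix.loci.names(), matrix.values):
            vals = "\t".join("nan" if np.isnan(v) else f"{v:.6g}" for v in row)
            fh.write(f"{name}\t{vals}\n")


def plot_heatmap(
    matrix: ProfileMatrix,
    path: str,
    order: Optional[np.ndarray] = None,
    title: str = "",
) -> None:
    """Render a heatmap with its average profile on top (cosmetic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profile, own_order = summarize_matrix(matrix)
    order = own_order if order is None else order
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(4, 6), height_ratios=[1, 4], sharex=True
    )
    x = np.arange(matrix.n_cols)
    ax0.plot(x, profile)
    ax0.set_title(title)
    ax1.imshow(matrix.values[order], aspect="auto", interpolation="nearest")
    ax1.set_xlabel("position bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
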