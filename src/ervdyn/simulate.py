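"""Seeded synthetic study generator with known ground truth.

Generates a toy genome carrying full-length IAP-like retroelements
(LTR-internal-LTR), solo LTRs, enhancers and TSS; strain-polymorphic
presence/absence of the elements; per-sample sequencing fragments drawn
from a piecewise-constant enrichment intensity; multimapping emulated as
zero mapping quality for fragments confined to repeat-internal sequence;
and replicate peak calls with boundary jitter and dropout. Everything is
reproducible bit-for-bit from (config, seed), and the planted truth is
recorded so every downstream stage can be scored without re-derivation.

The enrichment model is a piecewise-constant Poisson-like intensity over
regions: fragment midpoints are drawn proportional to a per-base weight
that is 1 (baseline) everywhere, multiplied by a mark- and
condition-specific fold over its enriched regions, and 0 across elements
absent from the sampled strain. This is the simplest model that
reproduces plateau-shaped average profiles over element bodies without
modeling nucleosome positioning.
"""

from __future__ import annotations

import zlib
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError
from .genome import GenomeModel, GenomicInterval, IntervalSet, merge_intervals

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SimulatedAnnotation",
    "simulate_genome_and_annotation",
    "simulate_sample_fragments",
    "simulate_replicate_peaks",
]

LTR_NAME_5 = "IAPLTR1a"
LTR_NAME_INT = "IAPEz-int"
SOLO_NAME = "IAPLTR2"
OTHER_NAME = "MTA_Mm"

BACKGROUND_STATES = [
    "E2_TssFlank", "E3_Transcribed", "E4_WeakTx", "E5_EnhancerPoised",
    "E6_EnhancerWeak", "E8_Insulator", "E9_BivalentTss", "E10_PolycombWeak",
    "E11_Polycomb", "E12_QuiescentGene", "E14_QuiescentLow", "E15_Quiescent",
]
STATE_TSS = "E1_TssActive"
STATE_ENH = "E7_EnhancerActive"
STATE_HET = "E13_Heterochromatin"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and samples.

    Defaults encode the structure the analysis assumes: ~340 bp LTRs
    flanking a 4-6 kb internal sequence; heterochromatin domains of
    roughly 10 kb (element plus 2.5 kb flanks); H3.3 enrichment (fold 4)
    at enhancers and over LTRs plus the adjacent 2 kb of internal
    sequence; H3K9me3 (fold 6) across the domains; a threefold
    accessibility gain over the domains in the H3.3-knockout condition
    with no gain (fold 1) in wildtype; uniform input; 30x fragment depth;
    fragment lengths ~N(180, 30) truncated at 50 bp; and 0.9 probability
    that a fragment confined to internal sequence is multimapping (MQ 0).
    Polymorphism: the annotation derives from the reference strain, which
    therefore carries every element; in each other strain a polymorphic
    subset of elements is present with the stated probability.
    """

    seed: int = 0
    chrom_lengths: Tuple[int, ...] = (2_000_000, 2_000_000, 2_000_000)
    n_full_elements: int = 36
    n_solo_ltrs: int = 18
    n_other_repeats: int = 10
    n_enhancers: int = 30
    n_tss: int = 30
    ltr_len: int = 340
    internal_len_range: Tuple[int, int] = (4000, 6000)
    strains: Tuple[str, ...] = ("B6", "129S1", "CAST")
    reference_strain: str = "B6"
    frac_polymorphic: float = 0.25
    presence_prob: float = 0.5
    domain_flank: int = 2500
    turnover_internal: int = 2000
    enhancer_flank: int = 500
    fold_h33: float = 4.0
    fold_k9: float = 6.0
    fold_atac_wt: float = 1.0
    fold_atac_ko: float = 3.0
    # optional ATAC enrichment at open regulatory chromatin (enhancer/TSS
    # zones), identical in WT and KO; 1.0 = flat background outside IAPs
    fold_atac_open: float = 1.0
    depth_x: float = 30.0
    frag_len_mean: float = 180.0
    frag_len_sd: float = 30.0
    frag_len_min: int = 50
    p_multi: float = 0.9
    jitter_sd: float = 50.0
    dropout: float = 0.1
    n_replicates: int = 3
    feature_margin: int = 3000  # min distance between planted features
    absent_margin: int = 400  # zero-signal halo around absent elements

    def __post_init__(self) -> None:
        for name in ("fold_h33", "fold_k9", "fold_atac_wt", "fold_atac_ko"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("frac_polymorphic", "presence_prob", "p_multi"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")
        if self.reference_strain not in self.strains:
            raise ConfigurationError("reference_strain must be one of strains")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("chrom_lengths", "internal_len_range", "strains"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh, sort_keys=True,
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic sub-stream of the config seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode()) % 2**31])


@dataclass
class TruthTables:
    """Planted coordinates and per-strain/per-mark ground truth."""

    elements: IntervalSet  # full elements, named repName|chrom:start-end
    solo_ltrs: IntervalSet
    presence: pd.DataFrame  # element id x strain, bool
    domains: IntervalSet  # element +/- domain_flank, aligned with elements
    turnover_zones: IntervalSet  # H3.3 zones inside elements (merged per element)
    internal_regions: IntervalSet  # internal fragments, for the MQ model
    enhancer_zones: IntervalSet
    open_chromatin: IntervalSet  # enhancer + TSS zones accessible in all conditions
    true_peaks: Dict[str, IntervalSet]  # mark -> regions a caller should find
    folds: Dict[str, float]


@dataclass
class SimulatedAnnotation:
    genome: GenomeModel
    rmsk: IntervalSet  # fragmented repeat annotation (LTR/internal pieces)
    enhancers: IntervalSet
    tss: IntervalSet
    segmentation: IntervalSet  # 15-state partition of the genome
    truth: TruthTables
    config: SimulationConfig


def _place_features(cfg: SimulationConfig, rng: np.random.Generator,
                    sizes: Sequence[Tuple[str, int]],
                    genome: GenomeModel) -> List[GenomicInterval]:
    """Place non-overlapping features, >= feature_margin apart and off ends."""
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    chroms = genome.chromosomes
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    p = lens / lens.sum()
    out = []
    m = cfg.feature_margin
    for kind, size in sizes:
        for attempt in range(5000):
            chrom = chroms[rng.choice(len(chroms), p=p)]
            hi = genome.lengths[chrom] - size - m
            if hi <= m:
                continue
            start = int(rng.integers(m, hi))
            end = start + size
            occ = occupied[chrom]
            i = bisect_left(occ, (start, end))
            clash = (i > 0 and occ[i - 1][1] + m > start) or (
                i < len(occ) and end + m > occ[i][0]
            )
            if not clash:
                insort(occ, (start, end))
                out.append(GenomicInterval(chrom, start, end, kind))
                break
        else:
            raise ConfigurationError(
                f"could not place a {kind} feature of {size} bp; "
                "genome too small for the configured feature counts"
            )
    return out


def simulate_genome_and_annotation(cfg: SimulationConfig) -> SimulatedAnnotation:
    """Build the toy genome, rmsk-style fragments, features and truth.

    Repeat fragments are written as separate abutting LTR/internal pieces
    so that curation has real work to do; the 15-category segmentation
    covers the genome exactly, with the heterochromatin state over the
    IAP domains.
    """
    genome = GenomeModel({f"chr{i + 1}": l for i, l in enumerate(cfg.chrom_lengths)})
    rng = cfg.rng("genome")
    internal_lens = rng.integers(
        cfg.internal_len_range[0], cfg.internal_len_range[1] + 1, cfg.n_full_elements
    )
    sizes = (
        [("full", 2 * cfg.ltr_len + int(l)) for l in internal_lens]
        + [("solo", cfg.ltr_len)] * cfg.n_solo_ltrs
        + [("other", 500)] * cfg.n_other_repeats
        + [("enh", 1000)] * cfg.n_enhancers
        + [("tss", 200)] * cfg.n_tss
    )
    placed = _place_features(cfg, rng, sizes, genome)
    full = [iv for iv in placed if iv.name == "full"]
    solos = [iv.with_name(SOLO_NAME) for iv in placed if iv.name == "solo"]
    others = [iv.with_name(OTHER_NAME) for iv in placed if iv.name == "other"]
    enhancers = IntervalSet(
        sorted((iv.with_name("enh") for iv in placed if iv.name == "enh"),
               key=lambda x: x.key)
    )
    tss = IntervalSet(
        sorted((iv.with_name("tss") for iv in placed if iv.name == "tss"),
               key=lambda x: x.key)
    )

    rmsk: List[GenomicInterval] = []
    elements: List[GenomicInterval] = []
    domains: List[GenomicInterval] = []
    zones: List[GenomicInterval] = []
    internals: List[GenomicInterval] = []
    for iv in full:
        s, e = iv.start, iv.end
        i0, i1 = s + cfg.ltr_len, e - cfg.ltr_len
        rmsk.append(GenomicInterval(iv.chrom, s, i0, LTR_NAME_5))
        rmsk.append(GenomicInterval(iv.chrom, i0, i1, LTR_NAME_INT))
        rmsk.append(GenomicInterval(iv.chrom, i1, e, LTR_NAME_5))
        internals.append(GenomicInterval(iv.chrom, i0, i1, LTR_NAME_INT))
        eid = f"{LTR_NAME_INT}|{iv.chrom}:{s}-{e}"
        elements.append(GenomicInterval(iv.chrom, s, e, eid))
        domains.append(
            GenomicInterval(
                iv.chrom,
                max(0, s - cfg.domain_flank),
                min(genome.lengths[iv.chrom], e + cfg.domain_flank),
                eid,
            )
        )
        # H3.3 turnover zones: both LTRs plus adjacent internal sequence
        z = cfg.ltr_len + cfg.turnover_internal
        if 2 * z >= e - s:
            zones.append(GenomicInterval(iv.chrom, s, e, eid))
        else:
            zones.append(GenomicInterval(iv.chrom, s, s + z, eid))
            zones.append(GenomicInterval(iv.chrom, e - z, e, eid))
    rmsk.extend(solos)
    rmsk.extend(others)
    rmsk_set = IntervalSet(sorted(rmsk, key=lambda x: x.key))
    rmsk_set.attrs["repClass"] = ["LTR"] * len(rmsk_set)

    element_set = IntervalSet(sorted(elements, key=lambda x: x.key))
    domain_set = IntervalSet(sorted(domains, key=lambda x: x.key))
    zone_set = IntervalSet(sorted(zones, key=lambda x: x.key))
    internal_set = IntervalSet(sorted(internals, key=lambda x: x.key))
    enh_zones = IntervalSet(
        [
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - cfg.enhancer_flank),
                min(genome.lengths[iv.chrom], iv.end + cfg.enhancer_flank),
                "enh",
            )
            for iv in enhancers
        ]
    )

    # strain presence: the reference strain carries every annotated element
    prng = cfg.rng("presence")
    ids = element_set.names()
    polymorphic = prng.random(len(ids)) < cfg.frac_polymorphic
    presence = pd.DataFrame(True, index=pd.Index(ids, name="element"),
                            columns=list(cfg.strains))
    for strain in cfg.strains:
        if strain == cfg.reference_strain:
            continue
        keep = np.where(polymorphic, prng.random(len(ids)) < cfg.presence_prob, True)
        presence[strain] = keep

    tss_zones = IntervalSet(
        [
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - 300),
                min(genome.lengths[iv.chrom], iv.end + 300),
                "tss",
            )
            for iv in tss
        ]
    )
    open_chromatin = merge_intervals(IntervalSet(list(enh_zones) + list(tss_zones)))

    true_peaks = {
        "H3.3": merge_intervals(IntervalSet(list(zone_set) + list(enh_zones))),
        "H3K9me3": merge_intervals(domain_set),
        "ATAC_KO": merge_intervals(domain_set),
    }

    segmentation = _build_segmentation(genome, domain_set, enh_zones, tss)
    truth = TruthTables(
        elements=element_set,
        solo_ltrs=IntervalSet(sorted(solos, key=lambda x: x.key)),
        presence=presence,
        domains=domain_set,
        turnover_zones=zone_set,
        internal_regions=internal_set,
        enhancer_zones=enh_zones,
        open_chromatin=open_chromatin,
        true_peaks=true_peaks,
        folds={
            "H3.3": cfg.fold_h33,
            "H3K9me3": cfg.fold_k9,
            "ATAC_WT": cfg.fold_atac_wt,
            "ATAC_KO": cfg.fold_atac_ko,
            "input": 1.0,
        },
    )
    return SimulatedAnnotation(
        genome=genome, rmsk=rmsk_set, enhancers=enhancers, tss=tss,
        segmentation=segmentation, truth=truth, config=cfg,
    )


def _build_segmentation(
    genome: GenomeModel,
    domains: IntervalSet,
    enh_zones: IntervalSet,
    tss: IntervalSet,
    chunk: int = 10_000,
) -> IntervalSet:
    """15-state partition: painted feature states, round-robin background."""
    painted: Dict[str, List[Tuple[int, int, str]]] = {c: [] for c in genome.chromosomes}
    for iv in domains:
        painted[iv.chrom].append((iv.start, iv.end, STATE_HET))
    for iv in enh_zones:
        painted[iv.chrom].append((iv.start, iv.end, STATE_ENH))
    for iv in tss:
        s = max(0, iv.start - 300)
        e = min(genome.lengths[iv.chrom], iv.end + 300)
        painted[iv.chrom].append((s, e, STATE_TSS))
    out: List[GenomicInterval] = []
    bg = 0
    for chrom in genome.chromosomes:
        segs = sorted(painted[chrom])
        pos = 0
        length = genome.lengths[chrom]
        for s, e, state in segs + [(length, length, "")]:
            while pos < s:
                nxt = min(pos + chunk, s)
                out.append(
                    GenomicInterval(chrom, pos, nxt,
                                    BACKGROUND_STATES[bg % len(BACKGROUND_STATES)])
                )
                bg += 1
                pos = nxt
            if e > s:
                out.append(GenomicInterval(chrom, s, e, state))
                pos = e
    return IntervalSet(out)


def _enriched_regions(
    cfg: SimulationConfig, truth: TruthTables, mark: str, condition: str, strain: str
) -> List[Tuple[GenomicInterval, float]]:
    present = set(truth.presence.index[truth.presence[strain]])
    regions: List[Tuple[GenomicInterval, float]] = []
    if mark == "H3.3":
        regions += [(iv, cfg.fold_h33) for iv in truth.turnover_zones if iv.name in present]
        regions += [(iv, cfg.fold_h33) for iv in truth.enhancer_zones]
    elif mark == "H3K9me3":
        regions += [(iv, cfg.fold_k9) for iv in truth.domains if iv.name in present]
    elif mark == "ATAC":
        fold = cfg.fold_atac_ko if condition == "KO" else cfg.fold_atac_wt
        regions += [(iv, fold) for iv in truth.domains if iv.name in present]
        regions += [(iv, cfg.fold_atac_open) for iv in truth.open_chromatin]
    elif mark == "input":
        pass
    else:
        raise ParameterError(f"unknown mark {mark!r}")
    return regions


def simulate_sample_fragments(
    cfg: SimulationConfig,
    ann: SimulatedAnnotation,
    mark: str,
    condition: str = "WT",
    strain: Optional[str] = None,
    depth_x: Optional[float] = None,
    dataset: Optional[str] = None,
) -> pd.DataFrame:
    """Draw one sample's fragments from the enrichment intensity model.

    Midpoints follow the per-base weight (baseline 1, region folds,
    zero across elements absent from ``strain``); lengths are truncated
    normal; fragments confined to internal repeat sequence are flagged
    multimapping (both mates MQ 0) with probability ``p_multi``, all other
    fragments carry MQ 42 on both mates. No fragment overlaps an absent
    element, emulating the contiguous (insertion-free) strain genome.
    """
    strain = strain or cfg.reference_strain
    if strain not in cfg.strains:
        raise ConfigurationError(f"unknown strain {strain!r}")
    genome = ann.genome
    truth = ann.truth
    dataset = dataset or f"{mark}_{condition}_{strain}"
    rng = cfg.rng(f"sample:{dataset}")
    depth = cfg.depth_x if depth_x is None else depth_x

    chroms = genome.chromosomes
    weights = {c: np.ones(genome.lengths[c]) for c in chroms}
    for iv, fold in _enriched_regions(cfg, truth, mark, condition, strain):
        weights[iv.chrom][iv.start:iv.end] = fold
    absent_ids = set(truth.presence.index[~truth.presence[strain]])
    absent: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for iv in truth.elements:
        if iv.name in absent_ids:
            s = max(0, iv.start - cfg.absent_margin)
            e = min(genome.lengths[iv.chrom], iv.end + cfg.absent_margin)
            weights[iv.chrom][s:e] = 0.0
            absent[iv.chrom].append((iv.start, iv.end))

    wcat = np.concatenate([weights[c] for c in chroms])
    total_w = wcat.sum()
    if total_w <= 0:
        raise ConfigurationError("intensity has zero support")
    cum = np.cumsum(wcat)
    bounds = np.cumsum([0] + [genome.lengths[c] for c in chroms])

    n = int(round(depth * genome.total_length / cfg.frag_len_mean))
    u = rng.random(n) * total_w
    mids = np.searchsorted(cum, u, side="right")

    lens = rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, n)
    bad = lens < cfg.frag_len_min
    while bad.any():
        lens[bad] = rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, int(bad.sum()))
        bad = lens < cfg.frag_len_min
    lens = np.round(lens).astype(np.int64)

    ci = np.searchsorted(bounds, mids, side="right") - 1
    local = mids - bounds[ci]
    chrom_lens = np.array([genome.lengths[c] for c in chroms])[ci]
    starts = np.clip(local - lens // 2, 0, None)
    ends = np.minimum(starts + lens, chrom_lens)
    starts = np.maximum(np.minimum(starts, ends - 1), 0)

    keep = np.ones(n, dtype=bool)
    internal_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        spans = [(iv.start, iv.end) for iv in truth.internal_regions if iv.chrom == c]
        internal_by_chrom[c] = (
            np.array([s for s, _ in spans] or [0]),
            np.array([e for _, e in spans] or [0]),
        )
    mq1 = np.full(n, 42, dtype=np.int64)
    for k, c in enumerate(chroms):
        on_c = ci == k
        if not on_c.any():
            continue
        s_c, e_c = starts[on_c], ends[on_c]
        # drop fragments touching an absent element (disjoint sorted spans:
        # only the nearest span to the left of the fragment end can overlap)
        if absent[c]:
            a_s = np.array([s for s, _ in absent[c]])
            a_e = np.array([e for _, e in absent[c]])
            j = np.searchsorted(a_s, e_c, side="left") - 1
            hit = (j >= 0) & (a_e[np.clip(j, 0, None)] > s_c)
            sub = np.nonzero(on_c)[0][hit]
            keep[sub] = False
        i_s, i_e = internal_by_chrom[c]
        j = np.searchsorted(i_s, s_c, side="right") - 1
        inside = (j >= 0) & (i_e[np.clip(j, 0, None)] >= e_c) & (
            i_s[np.clip(j, 0, None)] <= s_c
        )
        sub = np.nonzero(on_c)[0][inside]
        multi = rng.random(sub.size) < cfg.p_multi
        mq1[sub[multi]] = 0

    chrom_col = np.array(chroms, dtype=object)[ci]
    df = pd.DataFrame(
        {
            "chrom": chrom_col[keep],
            "start": starts[keep],
            "end": ends[keep],
            "mq1": mq1[keep],
            "mq2": mq1[keep],
            "dataset": dataset,
        }
    )
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def simulate_replicate_peaks(
    true_peaks: IntervalSet,
    genome: GenomeModel,
    jitter_sd: float = 50.0,
    dropout: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
) -> List[IntervalSet]:
    """Replicate peak calls: truth with boundary jitter and dropout.

    Each replicate contains each true peak with probability 1 - dropout;
    boundaries are perturbed by Gaussian jitter (rounded, clipped to the
    chromosome, never inverted below 1 bp).
    """
    if not 0 <= dropout < 1:
        raise ParameterError("dropout must be in [0, 1)")
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be >= 0")
    rng = np.random.default_rng([seed, zlib.crc32(b"replicate_peaks") % 2**31])
    reps = []
    for r in range(n_reps):
        ivs = []
        for i, iv in enumerate(true_peaks):
            if rng.random() < dropout:
                continue
            length = genome.lengths[iv.chrom]
            s = int(np.clip(round(iv.start + rng.normal(0, jitter_sd)), 0, length - 1))
            e = int(np.clip(round(iv.end + rng.normal(0, jitter_sd)), s + 1, length))
            ivs.append(GenomicInterval(iv.chrom, s, e, f"rep{r + 1}_peak{i}", ".", 0.0))
        reps.append(IntervalSet(sorted(ivs, key=lambda x: x.key)))
    return reps
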