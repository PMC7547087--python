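#!/usr/bin/env python
"""Replicate-consensus peak calling and class annotation.

Simulates three noisy replicate broadPeak files per mark (10% dropout,
50 bp boundary jitter), merges peaks called in at least two replicates into
consensus regions, scores recovery against the planted truth, classifies
H3.3 consensus peaks by H3K9me3 co-occurrence, and annotates each peak with
its majority chromatin state.
"""

import argparse
import json
import os
import sys
from collections import Counter

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ervdyn import io
from ervdyn.peaks import annotate_chromhmm, classify_by_overlap
from ervdyn.simulate import SimulationConfig, simulate_genome_and_annotation
from ervdyn.study import peak_consensus_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/peaks")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    ann = simulate_genome_and_annotation(cfg)

    consensus = {}
    for mark in ("H3.3", "H3K9me3"):
        res = peak_consensus_study(cfg, ann, mark=mark)
        consensus[mark] = res.consensus
        for r, rep in enumerate(res.replicates, 1):
            io.write_broadpeak(
                rep, os.path.join(args.outdir, f"{mark}_rep{r}.broadPeak")
            )
        io.write_bed(
            res.consensus, os.path.join(args.outdir, f"{mark}_consensus.bed")
        )
        print(f"{mark}: {len(res.consensus)} consensus peaks from "
              f"{[len(r) for r in res.replicates]} replicate calls; "
              f"base-pair Jaccard vs truth {res.jaccard:.3f}")

    classes = classify_by_overlap(consensus["H3.3"], consensus["H3K9me3"])
    counts = {label: len(ivs) for label, ivs in classes.items()}
    with open(os.path.join(args.outdir, "peak_classes.json"), "w") as fh:
        json.dump(counts, fh, indent=2)
    print(f"peak classes: {counts}")

    states = annotate_chromhmm(consensus["H3.3"], ann.segmentation)
    shared_states = Counter(
        s for s, ivs in zip(states, consensus["H3.3"])
        if classes["H3.3+H3K9me3"].overlapping(ivs.chrom, ivs.start, ivs.end)
    )
    print(f"chromatin states of H3.3+H3K9me3 peaks: {dict(shared_states)} "
          "(co-enriched peaks land in heterochromatin, as planted)")


if __name__ == "__main__":
    main()
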