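#!/usr/bin/env python
"""Generate the synthetic study: toy genome, fragmented repeat annotation,
features, chromatin-state segmentation and ground truth.

Writes the study inputs the later analysis steps consume, in the same text
formats the real pipeline would ingest (chrom.sizes, rmsk-style TSV, BEDs).
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ervdyn import io
from ervdyn.simulate import SimulationConfig, simulate_genome_and_annotation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/sim")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    ann = simulate_genome_and_annotation(cfg)

    cfg.to_yaml(os.path.join(args.outdir, "sim_config.yaml"))
    io.write_chrom_sizes(ann.genome, os.path.join(args.outdir, "genome.chrom.sizes"))
    io.write_rmsk(ann.rmsk, os.path.join(args.outdir, "rmsk.tsv"))
    io.write_bed(ann.segmentation, os.path.join(args.outdir, "segmentation.bed"))
    io.write_bed(ann.enhancers, os.path.join(args.outdir, "enhancers.bed"))
    io.write_bed(ann.tss, os.path.join(args.outdir, "tss.bed"))
    io.write_bed(ann.truth.elements, os.path.join(args.outdir, "truth_elements.bed"))
    ann.truth.presence.to_csv(os.path.join(args.outdir, "truth_presence.tsv"), sep="\t")

    n_states = len({iv.name for iv in ann.segmentation})
    print(f"genome: {len(ann.genome.chromosomes)} chromosomes, "
          f"{ann.genome.total_length/1e6:.1f} Mb")
    print(f"rmsk fragments: {len(ann.rmsk)} "
          f"({len(ann.truth.elements)} full elements as LTR-internal-LTR triplets, "
          f"{len(ann.truth.solo_ltrs)} solo LTRs)")
    print(f"segmentation: {n_states} states, partition verified "
          f"({sum(iv.length for iv in ann.segmentation)} bp)")
    print(f"presence truth: {ann.truth.presence.to_numpy().mean()*100:.1f}% of "
          f"(element, strain) pairs present; written to {args.outdir}/")


if __name__ == "__main__":
    main()
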