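#!/usr/bin/env python
"""Call per-strain presence of curated IAP elements and intersect to the
shared set.

Simulates one H3K9me3 ChIP and one matched input per strain, counts
anchoring pairs (fragment overlaps the element, at least one mate MQ > 10),
pools evidence per cell line and keeps elements present in every strain.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ervdyn import io
from ervdyn.simulate import SimulationConfig, simulate_genome_and_annotation
from ervdyn.study import presence_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--depth", type=float, default=8.0,
                    help="sequencing depth (x) per presence-panel sample")
    ap.add_argument("--outdir", default="results/presence")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    ann = simulate_genome_and_annotation(cfg)
    res = presence_study(cfg, ann, depth_x=args.depth)

    res.cell_line_matrix.counts.to_csv(
        os.path.join(args.outdir, "anchoring_counts.tsv"), sep="\t"
    )
    res.cell_line_matrix.presence.astype(int).to_csv(
        os.path.join(args.outdir, "presence_matrix.tsv"), sep="\t"
    )
    io.write_bed(res.shared, os.path.join(args.outdir, "iap_shared.bed"))

    pres = res.cell_line_matrix.presence
    print(f"{len(res.elements)} curated elements x {pres.shape[1]} cell lines")
    print(f"presence calls match planted truth: {res.accuracy:.3f} "
          f"(anchoring evidence at depth {args.depth:g}x)")
    print(f"shared set: {len(res.shared)} elements present in all strains "
          f"({pres.all(axis=1).sum()} all-true rows)")
    for strain in pres.columns:
        print(f"  {strain}: {int(pres[strain].sum())} elements present")


if __name__ == "__main__":
    main()
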