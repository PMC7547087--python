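#!/usr/bin/env python
"""ATAC accessibility over 5 kb bins: wildtype vs H3.3 knockout.

Builds 1x-normalized (FPGC) fragment-coverage tracks for both conditions,
summarizes them over genome-wide 5 kb bins, overlays bins overlapping the
shared IAP elements, and reports the rank-sum test, Cohen's d and the
KO/WT fold change for the IAP group, plus Tukey-trimmed violin summaries.
"""

import argparse
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ervdyn.simulate import SimulationConfig, simulate_genome_and_annotation
from ervdyn.stats import tukey_filter
from ervdyn.study import atac_bin_study, presence_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/bins")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    ann = simulate_genome_and_annotation(cfg)
    pres = presence_study(cfg, ann)
    atac = atac_bin_study(cfg, ann, pres.shared)

    import pandas as pd

    table = pd.DataFrame(
        {
            "chrom": [b.chrom for b in atac.bins],
            "start": [b.start for b in atac.bins],
            "end": [b.end for b in atac.bins],
            "atac_wt_fpgc": atac.wt_values,
            "atac_ko_fpgc": atac.ko_values,
            "iap_overlapping": atac.iap_bin_mask.astype(int),
        }
    )
    table.to_csv(os.path.join(args.outdir, "bins_5kb.tsv"), sep="\t", index=False)

    rows = []
    for cond, vals in (("WT", atac.wt_values), ("KO", atac.ko_values)):
        for group, mask in (("IAP", atac.iap_bin_mask),
                            ("genome-wide", np.ones(len(vals), bool))):
            trimmed, removed = tukey_filter(vals[mask])
            rows.append(
                (cond, group, mask.sum(), np.median(vals[mask]),
                 trimmed.mean(), removed)
            )
    pd.DataFrame(
        rows, columns=["condition", "group", "n_bins", "median",
                       "trimmed_mean", "outliers_removed"],
    ).to_csv(os.path.join(args.outdir, "violin_summaries.tsv"), sep="\t", index=False)

    n_iap = int(atac.iap_bin_mask.sum())
    print(f"{len(atac.bins)} bins of 5 kb; {n_iap} overlap the "
          f"{len(pres.shared)} shared IAP elements")
    print(f"KO/WT log2 fold change at IAP bins: {atac.log2fc_iap:.3f} "
          f"(planted accessibility gain: log2(3) = {np.log2(3):.3f})")
    print(f"IAP bins vs genome-wide -- WT: d = {atac.d_wt:.3f}, "
          f"p = {atac.p_wt:.3g}; KO: d = {atac.d_ko:.3f}, p = {atac.p_ko:.3g}")
    print("interpretation: IAP bins are indistinguishable from the genome "
          "average in WT and strongly shifted in the H3.3 KO")


if __name__ == "__main__":
    main()
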