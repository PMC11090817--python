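#!/usr/bin/env python
"""Correct co-occurrence for phylogeny and relate it to transfer counts.

Computes the conditional-prevalence co-occurrence statistic, fits the
power law CO ~ k * PD^a per focal OTU, and compares Spearman correlations
between (residual) co-occurrence and transfer counts against a
shuffled-count background.  Also derives the multi-transfer count cutoff
(the nearest-rank 80% quantile among transferring pairs) and, as a
worked demonstration, the interaction-count fold enrichment on
distance/co-occurrence-matched pair sets.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import hgt_ecoscape.cooccurrence as cooc
from hgt_ecoscape.events import HGTCountMatrix
from hgt_ecoscape.io import load_dataset


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--world", type=Path, default=Path("results/world"))
    ap.add_argument("--counts", type=Path, default=Path("results/detected_counts.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--shuffles", type=int, default=50)
    ap.add_argument("--min-partners", type=int, default=10)
    args = ap.parse_args()

    ds = load_dataset(args.world)
    counts = HGTCountMatrix.from_dataframe(pd.read_csv(args.counts, sep="\t"))

    presence = cooc.presence_matrix(ds.abundance.matrix)
    focal, eligible = cooc.eligibility_filter(
        counts, presence, min_partners=args.min_partners
    )
    co = cooc.co_occurrence_matrix(presence)
    otus = list(ds.abundance.matrix.index)
    _, pdm = ds.species_tree.distance_matrix(otus)
    pdmat = pd.DataFrame(pdm, index=otus, columns=otus)
    pairs = cooc.build_pair_table(co, pdmat, counts, eligible)

    # global decay fitted on all pairs (transferring or not); the residual
    # analysis below refits per focal OTU over its transfer partners
    all_pairs = cooc.build_pair_table(co, pdmat, counts, include_zero_pairs=True)
    fit = cooc.fit_power_law(all_pairs["pd"], all_pairs["co"])
    res = cooc.residual_correlation_analysis(
        pairs, sorted(focal), n_shuffles=args.shuffles, seed=args.seed
    )
    cutoff = cooc.multi_transfer_threshold(counts)

    res.per_otu.to_csv(args.out / "residual_correlations.tsv", sep="\t", index=False)
    summary = {
        "power_law": {"k": fit.k, "a": fit.a},
        "n_focal_otus": len(res.per_otu),
        "median_rho_pre": float(res.per_otu["rho_pre"].median()),
        "median_rho_post": float(res.per_otu["rho_post"].median()),
        "median_background_rho": float(np.median(res.background)),
        "mwu_p_post_vs_background": res.mwu_p,
        "multi_transfer_cutoff": cutoff,
    }
    (args.out / "cooccurrence_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"global power-law fit: k = {fit.k:.3f}, a = {fit.a:.3f}")
    print(f"focal OTUs analysed: {len(res.per_otu)}")
    print(f"median Spearman rho: pre-correction "
          f"{summary['median_rho_pre']:.3f}, post-correction "
          f"{summary['median_rho_post']:.3f}, background "
          f"{summary['median_background_rho']:.3f}")
    print(f"post-correction vs background MWU p = {res.mwu_p:.2e}")
    print(f"multi-transfer cutoff (80% quantile): >= {cutoff} genes")


if __name__ == "__main__":
    main()
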