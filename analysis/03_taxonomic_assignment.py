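#!/usr/bin/env python
"""Barcode-gap calibration and taxonomic rank recovery.

Runs the assignment chain under two library geometries: a clean barcode gap
(within-taxon divergence 0.005 vs between-taxon 0.10), where error-free
reads should come back at species rank, and overlapping clusters
(0.08 vs 0.06), where every assignment should fall back to genus (COI-5P)
or genus/family (rbcLa). Writes the recovery table.
"""

from pathlib import Path

import pandas as pd

from jaydiet.experiments import rank_recovery

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240424


def main():
    rows = []
    for marker, n_taxa in (("COI-5P", 6), ("rbcLa", 8)):
        for label, intra, inter in (("clean_gap", 0.005, 0.10),
                                    ("no_gap", 0.08, 0.06)):
            r = rank_recovery(marker, intra=intra, inter=inter,
                              n_taxa=n_taxa, seed=SEED)
            rows.append({"marker": marker, "geometry": label,
                         "intra": intra, "inter": inter, **r})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "rank_recovery.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    clean = df[df.geometry == "clean_gap"]
    nogap = df[df.geometry == "no_gap"]
    print(f"\nclean gap: {clean.frac_true_species.min():.0%} of reads "
          "recover their true species at species rank;")
    print(f"no gap: {nogap.frac_species_rank.max():.0%} species-rank calls "
          "— every assignment is pulled back to a coarser rank.")


if __name__ == "__main__":
    main()
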