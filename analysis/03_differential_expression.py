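#!/usr/bin/env python
"""Differential expression and the dectin-1 / NFAT Venn set algebra.

Tests curdlan vs untreated and curdlan+FK506 vs curdlan (Welch t, BH),
filters at fold change >= 1.5 and adjusted p < 0.05, and reports the
overlap of dectin-1- and NFAT-dependent gene sets.  Writes de_stim.tsv,
de_inhib.tsv, gene_sets.tsv and venn_summary.tsv under results/expression/.
"""

from pathlib import Path

import pandas as pd

from nfatseq import diffexpr, io_formats
from nfatseq.io_formats import RunConfig

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main():
    cfg = RunConfig(rng_seed=SEED)
    expr = io_formats.read_expression(BASE / "dataset" / "expr.tsv")
    samples = io_formats.read_sample_sheet(BASE / "dataset" / "samples.tsv")
    out = BASE / "expression"
    out.mkdir(parents=True, exist_ok=True)

    sets = diffexpr.nfat_dependent_sets(expr, samples, cfg)
    io_formats.write_table(sets["de_stim"].reset_index(), out / "de_stim.tsv")
    io_formats.write_table(sets["de_inhib"].reset_index(), out / "de_inhib.tsv")
    rows = [{"set": k, "gene_id": g}
            for k in ("dectin_up", "dectin_down", "nfat_up", "nfat_down")
            for g in sorted(sets[k])]
    io_formats.write_table(pd.DataFrame(rows), out / "gene_sets.tsv")
    summ = diffexpr.venn_summary(sets["dectin_up"], sets["dectin_down"],
                                 sets["nfat_up"], sets["nfat_down"])
    io_formats.write_table(summ, out / "venn_summary.tsv")
    s = summ.iloc[0]
    print(summ.to_string(index=False))
    print(f"\n{s['n_common_up']} genes are up-regulated by both dectin-1 "
          f"stimulation and the NFAT pathway: {s['pct_common_of_dectin_up']}% "
          f"of dectin-1-activated and {s['pct_common_of_nfat_up']}% of "
          f"NFAT-activated genes")


if __name__ == "__main__":
    main()
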