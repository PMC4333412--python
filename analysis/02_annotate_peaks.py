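#!/usr/bin/env python
"""Annotate the stimulated-condition peaks by genomic location.

Classifies every curdlan peak into intragenic / 5' proximal / 5' distal /
3' proximal / 3' distal / gene desert (100-kb flanks, summit-referenced)
and profiles signed summit-to-TSS distances.  Writes annotations.tsv,
category_summary.tsv and tss_profile.tsv under results/annotation/.
"""

from pathlib import Path

import pandas as pd

from nfatseq import annotation, io_formats
from nfatseq.io_formats import RunConfig

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main():
    cfg = RunConfig(rng_seed=SEED)
    peaks = io_formats.read_peaks(BASE / "dataset" / "peaks_curdlan.bed", "curdlan")
    genes = io_formats.read_gene_models(BASE / "dataset" / "genes.tsv")
    out = BASE / "annotation"
    out.mkdir(parents=True, exist_ok=True)

    anns, summary = annotation.annotate_all(peaks, genes, cfg)
    io_formats.write_table(pd.DataFrame([a.__dict__ for a in anns]),
                           out / "annotations.tsv")
    io_formats.write_table(summary, out / "category_summary.tsv")
    prof = annotation.tss_distance_profile(anns, cfg)
    io_formats.write_table(prof, out / "tss_profile.tsv")

    print(summary.round({"percent": 2}).to_string(index=False))
    near = prof[prof["bin_start"].abs() <= 10_000]["count"].sum()
    print(f"\n{near} of {prof['count'].sum()} annotated summits lie within "
          f"10 kb of the nearest TSS")


if __name__ == "__main__":
    main()
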