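"""Six-way genomic-location classification of binding sites and TSS-distance profiles.

A peak (represented by its summit) is *intragenic* when the summit falls
inside a transcriptional unit; otherwise it is classified by its stranded
distance to the nearest unit boundary: within ``flank_proximal_bp`` of the
5' end it is 5'-proximal, within (proximal, ``flank_distal_bp``] it is
5'-distal, mirrored for the 3' end, and summits farther than the distal
flank from every unit fall in a *gene desert*.

Distances count bases between the summit and the nearest base of the unit
(half-open aware): a summit on the boundary base itself is distance 0 and
intragenic; the first base outside is distance 1.  The signed TSS distance
is oriented along the gene: negative = upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak, RunConfig, ValidationError, log

CATEGORIES = (
    "intragenic",
    "five_prime_proximal",
    "five_prime_distal",
    "three_prime_proximal",
    "three_prime_distal",
    "gene_desert",
)

# tie-break priority: 5' before 3' at equal distance
_SIDE_PRIORITY = {"five_prime": 0, "three_prime": 1}


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    category: str
    nearest_gene_id: str | None
    signed_tss_distance_bp: int | None


def signed_tss_distance(summit: int, gene: GeneModel) -> int:
    """Summit position relative to the TSS in gene orientation (negative = upstream)."""
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def _boundary_distance_and_side(summit: int, gene: GeneModel) -> tuple[int, str]:
    """(bases between summit and the unit, genomic-left/right resolved to 5'/3')."""
    if gene.start <= summit < gene.end:
        return 0, "inside"
    if summit < gene.start:
        d = gene.start - summit
        side = "five_prime" if gene.strand == "+" else "three_prime"
    else:
        d = summit - (gene.end - 1)
        side = "three_prime" if gene.strand == "+" else "five_prime"
    return d, side


class _ChromIndex:
    """Per-chromosome vectorized gene lookup for summit classification."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self.start = np.array([g.start for g in genes], dtype=np.int64)
        self.end = np.array([g.end for g in genes], dtype=np.int64)
        self.plus = np.array([g.strand == "+" for g in genes])
        self.gene_ids = np.array([g.gene_id for g in genes])

    def classify(self, summit: int, cfg: RunConfig) -> PeakAnnotation | None:
        if len(self.genes) == 0:
            return None
        inside = (self.start <= summit) & (summit < self.end)
        if inside.any():
            idx = np.flatnonzero(inside)
            cand = sorted(
                idx,
                key=lambda i: (abs(signed_tss_distance(summit, self.genes[i])), self.gene_ids[i]),
            )
            g = self.genes[cand[0]]
            return PeakAnnotation("", "intragenic", g.gene_id, signed_tss_distance(summit, g))
        # distance to nearest unit base, per gene
        d_left = self.start - summit          # >0 when summit left of gene
        d_right = summit - (self.end - 1)     # >0 when summit right of gene
        dist = np.maximum(d_left, d_right)
        five_side = np.where(self.plus, d_left > 0, d_right > 0)
        dmin = dist.min()
        if dmin > cfg.flank_distal_bp:
            return PeakAnnotation("", "gene_desert", None, None)
        idx = np.flatnonzero(dist == dmin)
        cand = sorted(idx, key=lambda i: (0 if five_side[i] else 1, self.gene_ids[i]))
        i = cand[0]
        g = self.genes[i]
        side = "five_prime" if five_side[i] else "three_prime"
        kind = "proximal" if dmin <= cfg.flank_proximal_bp else "distal"
        return PeakAnnotation("", f"{side}_{kind}", g.gene_id, signed_tss_distance(summit, g))


def _build_indexes(genes: list[GeneModel]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return {c: _ChromIndex(gs) for c, gs in by_chrom.items()}


def classify_peak(peak: Peak, genes: list[GeneModel], config: RunConfig,
                  chrom_names: set[str] | None = None,
                  _index: dict[str, _ChromIndex] | None = None) -> PeakAnnotation:
    """Classify one peak against a gene set.

    Containment wins over flank assignment; among flank candidates the
    smallest boundary distance wins, ties broken toward the 5' assignment
    then lexicographic gene id.  Known chromosomes without genes are gene
    desert; a chromosome outside the namespace (``chrom_names`` if given,
    else the gene set's chromosomes) is a :class:`ValidationError`.
    """
    namespace = chrom_names if chrom_names is not None else {g.chrom for g in genes}
    if namespace and peak.chrom not in namespace:
        raise ValidationError(f"peak {peak.peak_id}: unknown chromosome {peak.chrom!r}")
    index = _index if _index is not None else _build_indexes(genes)
    ci = index.get(peak.chrom)
    ann = ci.classify(peak.summit, config) if ci else None
    if ann is None:
        ann = PeakAnnotation(peak.peak_id, "gene_desert", None, None)
    else:
        ann = PeakAnnotation(peak.peak_id, ann.category, ann.nearest_gene_id,
                             ann.signed_tss_distance_bp)
    return ann


def annotate_all(peaks: list[Peak], genes: list[GeneModel], config: RunConfig,
                 chrom_names: set[str] | None = None,
                 ) -> tuple[list[PeakAnnotation], pd.DataFrame]:
    """Annotate every peak and summarize category percentages.

    Returns the per-peak annotations and a summary frame with counts and
    percentages (summing to 100 within rounding).
    """
    index = _build_indexes(genes)
    anns = [classify_peak(p, genes, config, chrom_names=chrom_names, _index=index)
            for p in peaks]
    if not anns:
        log.warning("annotate_all: no peaks given; empty summary")
        return [], pd.DataFrame(columns=["category", "n", "percent"])
    counts = pd.Series([a.category for a in anns]).value_counts()
    rows = [
        {"category": c, "n": int(counts.get(c, 0)),
         "percent": 100.0 * counts.get(c, 0) / len(anns)}
        for c in CATEGORIES
    ]
    return anns, pd.DataFrame(rows)


def tss_distance_profile(annotations: list[PeakAnnotation], config: RunConfig,
                         bin_bp: int = 1000) -> pd.DataFrame:
    """Histogram of signed TSS distances over [-flank_distal_bp, +flank_distal_bp).

    Bins are half-open ``[lo, lo + bin_bp)``; the total count equals the
    number of annotated peaks with a nearest gene.  Distances beyond the
    profiled range (possible for distal sites measured across a long gene
    body) are clipped into the terminal bins so the profile conserves mass.
    """
    if bin_bp <= 0:
        raise ValidationError("bin_bp must be > 0")
    lo, hi = -config.flank_distal_bp, config.flank_distal_bp
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    dists = np.array([a.signed_tss_distance_bp for a in annotations
                      if a.signed_tss_distance_bp is not None], dtype=np.int64)
    clipped = np.clip(dists, lo, edges[-1] - 1) if len(dists) else dists
    counts, _ = np.histogram(clipped, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})
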