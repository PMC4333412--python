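import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nfatseq.io_formats import GeneModel, Peak, RunConfig

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def config():
    return RunConfig()


# ---------------------------------------------------------------------------
# independent brute-force classifier used as the annotation oracle
# ---------------------------------------------------------------------------

def brute_force_classify(summit: int, genes: list[GeneModel], config: RunConfig):
    """Exhaustive scan over all genes computing every boundary distance
    directly from first principles; returns (category, nearest_gene_id)."""
    containing = [g for g in genes if g.start <= summit < g.end]
    if containing:
        containing.sort(key=lambda g: (abs(summit - g.tss if g.strand == "+" else g.tss - summit),
                                       g.gene_id))
        return "intragenic", containing[0].gene_id
    best = None  # (distance, side_rank, gene_id, side)
    for g in genes:
        if summit < g.start:
            d = g.start - summit
            side = "five_prime" if g.strand == "+" else "three_prime"
        else:
            d = summit - (g.end - 1)
            side = "three_prime" if g.strand == "+" else "five_prime"
        key = (d, 0 if side == "five_prime" else 1, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g, side)
    if best is None or best[0][0] > config.flank_distal_bp:
        return "gene_desert", None
    kind = "proximal" if best[0][0] <= config.flank_proximal_bp else "distal"
    return f"{best[2]}_{kind}", best[1].gene_id


def random_annotation_fixture(rng: np.random.Generator, max_genes=50, max_peaks=200,
                              chrom_len=400_000):
    """Random small gene/peak sets on one chromosome (dense enough that all
    six categories occur across fixtures)."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_len - 5000))
        length = int(rng.integers(200, 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:03d}", "chr1", strand, start, start + length))
    n_peaks = int(rng.integers(1, max_peaks + 1))
    peaks = []
    for i in range(n_peaks):
        s = int(rng.integers(0, chrom_len))
        peaks.append(Peak(f"p{i:03d}", "chr1", max(0, s - 50), s + 51, s,
                          float(rng.uniform(0, 100))))
    return genes, peaks
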