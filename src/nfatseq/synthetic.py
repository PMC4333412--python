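"""Ground-truthed synthetic data: genomes, gene models, condition-coupled peak
sets, replicate expression matrices, and planted motifs.

The generator emulates the statistical structure the downstream analysis
assumes: a stimulated condition (curdlan) with increased binding at planted
direct-target genes, an inhibited condition (curdlan + FK506) with that
binding reduced, differential-expression gene sets with exactly controlled
cardinalities and overlap, and concrete realizations of the NFAT consensus
(NANWGGAAAANN) planted near peak summits.  Every generator is a pure
function of its parameters and seed, and records what it planted in a
:class:`TruthManifest` so recovery is machine-checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (CONDITIONS, GeneModel, GenomeAssembly, Peak, RunConfig,
                         ValidationError, log)
from .motif import IUPAC_CODES, revcomp

NFAT_CONSENSUS = "NANWGGAAAANN"


class SizingError(ValueError):
    """Requested counts do not fit the requested genome/gene space."""


@dataclass
class SimParams:
    """Study-scale defaults: a sparse 500-Mb, 20-chromosome genome carrying
    6,000 genes, ~10,000 peaks per condition, 50 direct targets, and the
    observed differential-expression cardinalities (515 up / 323 down by
    stimulation; 171 up / 82 down NFAT-dependently; 135 common up)."""

    n_genes: int = 6000
    n_chroms: int = 20
    chrom_length_bp: int = 25_000_000
    n_peaks: int = 10_000
    n_direct_targets: int = 50
    de_cardinalities: dict = field(default_factory=lambda: {
        "dectin_up": 515, "dectin_down": 323,
        "nfat_up": 171, "nfat_down": 82,
        "common_up": 135, "common_down": 60,
    })
    n_replicates: int = 5
    effect_size_log2: float = 1.5
    noise_sd_log2: float = 0.25
    motif_plant_rate: float = 0.8
    background_gc: float = 0.5
    min_gap_bp: int = 1000
    gene_length_range: tuple[int, int] = (2000, 50_000)
    bound_bias_rate: float = 0.6
    with_sequence: bool = False
    jitter_summits: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        c = self.de_cardinalities
        if c["common_up"] > min(c["dectin_up"], c["nfat_up"]):
            raise ValidationError("common_up exceeds a parent set")
        if c.get("common_down", 0) > min(c["dectin_down"], c["nfat_down"]):
            raise ValidationError("common_down exceeds a parent set")
        if not (0 <= self.motif_plant_rate <= 1 and 0 < self.background_gc < 1):
            raise ValidationError("rates must lie in [0, 1]")
        n_distinct = (c["dectin_up"] + c["dectin_down"]
                      + c["nfat_up"] - c["common_up"]
                      + c["nfat_down"] - c.get("common_down", 0))
        if n_distinct > self.n_genes:
            raise SizingError(f"{n_distinct} DE genes requested but only {self.n_genes} genes")
        if self.n_direct_targets > self.n_genes:
            raise SizingError("more direct targets than genes")


@dataclass
class TruthManifest:
    """What the generator planted, for recovery checks."""

    direct_target_ids: set[str] = field(default_factory=set)
    de_sets: dict[str, set[str]] = field(default_factory=dict)
    motif_positions: list[dict] = field(default_factory=list)
    binding_coupling: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "direct_target_ids": sorted(self.direct_target_ids),
            "de_sets": {k: sorted(v) for k, v in self.de_sets.items()},
            "motif_positions": self.motif_positions,
            "binding_coupling": self.binding_coupling,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            direct_target_ids=set(data["direct_target_ids"]),
            de_sets={k: set(v) for k, v in data["de_sets"].items()},
            motif_positions=data["motif_positions"],
            binding_coupling=data["binding_coupling"],
        )


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def simulate_genome(params: SimParams) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Non-overlapping genes (>= ``min_gap_bp`` apart, random strand) on an
    i.i.d. background genome at ``background_gc``; sequence only when
    ``with_sequence`` is set (coordinate-only genomes cover most analyses)."""
    rng = np.random.default_rng(params.rng_seed)
    total = params.n_chroms * params.chrom_length_bp
    lo_len, hi_len = params.gene_length_range
    if params.n_genes * (hi_len + params.min_gap_bp) > total:
        raise SizingError(
            f"{params.n_genes} genes x {hi_len + params.min_gap_bp} bp exceed genome ({total} bp)")
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chroms)]
    lengths = {c: params.chrom_length_bp for c in chrom_names}

    per_chrom = np.full(params.n_chroms, params.n_genes // params.n_chroms)
    per_chrom[: params.n_genes % params.n_chroms] += 1

    genes: list[GeneModel] = []
    gid_width = len(str(max(params.n_genes, 1)))
    gidx = 0
    for ci, chrom in enumerate(chrom_names):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        glens = rng.integers(lo_len, hi_len + 1, size=k)
        occupied = int(glens.sum()) + k * params.min_gap_bp
        slack = params.chrom_length_bp - occupied
        if slack < 0:
            raise SizingError(f"{chrom}: {k} genes do not fit")
        extra = np.sort(rng.integers(0, slack + 1, size=k))
        pos = 0
        for j in range(k):
            start = int(extra[j]) + pos + params.min_gap_bp
            end = start + int(glens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gidx:0{gid_width}d}", chrom, strand, start, end))
            pos = pos + params.min_gap_bp + int(glens[j])
            gidx += 1

    sequence = None
    if params.with_sequence:
        sequence = {c: random_sequence(params.chrom_length_bp, params.background_gc, rng)
                    for c in chrom_names}
    return GenomeAssembly(chrom_names, lengths, sequence), genes


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# peaks with condition-dependent heights
# ---------------------------------------------------------------------------

def _isolated_genes(genes: list[GeneModel], min_tss_gap: int) -> list[GeneModel]:
    """Genes whose TSS is > min_tss_gap from every other TSS."""
    out = []
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    sorted_tss = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}
    for g in genes:
        arr = sorted_tss[g.chrom]
        i = np.searchsorted(arr, g.tss)
        near = [arr[j] for j in (i - 1, i, i + 1) if 0 <= j < len(arr) and arr[j] != g.tss]
        if all(abs(t - g.tss) > min_tss_gap for t in near):
            out.append(g)
    return out


def simulate_peaks(genes: list[GeneModel], genome: GenomeAssembly, params: SimParams,
                   config: RunConfig | None = None
                   ) -> tuple[dict[str, list[Peak]], TruthManifest]:
    """Per-condition peak sets with planted direct targets.

    Each direct-target gene gets a matched peak triplet: summit within the
    direct-target distance of its TSS (and, for unambiguous ground truth,
    farther than that distance from every other TSS), heights satisfying
    curdlan/untreated >= binding_up_ratio and fk506/curdlan <=
    binding_down_ratio even after the +1 pseudocount.  Decoys are flat
    (condition-invariant, heights uniform over [0, 100] to populate all
    height strata), up-only (induced but not FK506-sensitive), or
    qualifying-but-distant (> direct-target distance from every TSS).
    Matched peaks share ids; ``jitter_summits`` instead gives per-condition
    ids and summits offset <= 50 bp to exercise positional matching.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(params.rng_seed + 1)
    d = cfg.direct_target_distance_bp

    if params.n_direct_targets > 0:
        candidates = _isolated_genes(genes, 2 * d)
        if len(candidates) < params.n_direct_targets:
            raise SizingError(
                f"only {len(candidates)} genes with TSS isolation > {2 * d} bp; "
                f"{params.n_direct_targets} direct targets requested")
        order = rng.permutation(len(candidates))
        targets = [candidates[i] for i in order[: params.n_direct_targets]]
    else:
        targets = []

    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    def min_tss_dist(chrom: str, pos: int) -> int:
        arr = tss_by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return 10 ** 12
        i = np.searchsorted(arr, pos)
        return min(abs(int(arr[j]) - pos) for j in (i - 1, i) if 0 <= j < len(arr))

    manifest = TruthManifest()
    peaks: dict[str, list[Peak]] = {c: [] for c in CONDITIONS}
    pid = 0

    # peaks keep >= 500 bp summit separation (callers merge closer events),
    # which also keeps positional matching unambiguous in jittered mode
    min_sep = 500

    def is_free(chrom: str, pos: int) -> bool:
        b = pos // min_sep
        return not any(abs(pos - q) < min_sep
                       for bb in (b - 1, b, b + 1)
                       for q in buckets[chrom].get(bb, ()))

    buckets: dict[str, dict[int, list[int]]] = {c: {} for c in genome.chrom_names}

    def reserve(chrom: str, pos: int) -> None:
        buckets[chrom].setdefault(pos // min_sep, []).append(pos)

    def add_triplet(chrom: str, summit: int, heights: dict[str, float]):
        nonlocal pid
        name = f"p{pid:06d}"
        pid += 1
        clen = genome.chrom_lengths[chrom]
        for cond in CONDITIONS:
            s = summit
            peak_id = name
            if params.jitter_summits and cond != "curdlan":
                s = int(np.clip(summit + rng.integers(-50, 51), 0, clen - 1))
                peak_id = f"{name}_{cond}"
            start = max(0, s - 200)
            end = min(clen, s + 201)
            peaks[cond].append(Peak(peak_id, chrom, start, end, s, float(heights[cond]), cond))
        return name

    for g in targets:
        lo = max(0, g.tss - d)
        hi = min(genome.chrom_lengths[g.chrom] - 1, g.tss + d)
        summit = int(rng.integers(lo, hi + 1))
        while not is_free(g.chrom, summit):
            summit = int(rng.integers(lo, hi + 1))
        reserve(g.chrom, summit)
        hu = float(rng.uniform(5, 15))
        hc = hu * float(rng.uniform(2.5, 4.0))
        hf = hc * float(rng.uniform(0.2, 0.45))
        heights = {"untreated": hu, "curdlan": hc, "curdlan_fk506": hf}
        add_triplet(g.chrom, summit, heights)
        manifest.direct_target_ids.add(g.gene_id)
        manifest.binding_coupling[g.gene_id] = heights

    n_decoys = params.n_peaks - params.n_direct_targets
    if n_decoys < 0:
        raise SizingError("n_peaks smaller than n_direct_targets")
    kinds = rng.choice(["flat", "up_only", "far"], size=n_decoys, p=[0.5, 0.3, 0.2])
    chrom_arr = rng.choice(genome.chrom_names, size=n_decoys)
    for kind, chrom in zip(kinds, chrom_arr):
        clen = genome.chrom_lengths[chrom]
        summit = int(rng.integers(0, clen))
        if kind == "far":
            for _ in range(200):
                if min_tss_dist(chrom, summit) > d and is_free(chrom, summit):
                    break
                summit = int(rng.integers(0, clen))
            else:  # pragma: no cover - genome too dense for far decoys
                kind = "flat"
        while not is_free(chrom, summit):
            summit = int(rng.integers(0, clen))
        reserve(chrom, summit)
        if kind == "flat":
            h = float(rng.uniform(0, 100))
            heights = {c: h for c in CONDITIONS}
        elif kind == "up_only":
            hu = float(rng.uniform(5, 15))
            hc = hu * float(rng.uniform(2.0, 3.0))
            heights = {"untreated": hu, "curdlan": hc,
                       "curdlan_fk506": hc * float(rng.uniform(0.9, 1.1))}
        else:  # far, qualifying pattern but out of range
            hu = float(rng.uniform(5, 15))
            hc = hu * float(rng.uniform(2.5, 4.0))
            heights = {"untreated": hu, "curdlan": hc,
                       "curdlan_fk506": hc * float(rng.uniform(0.2, 0.45))}
        add_triplet(chrom, summit, heights)

    return peaks, manifest


# ---------------------------------------------------------------------------
# expression with exact planted cardinalities
# ---------------------------------------------------------------------------

def simulate_expression(genes: list[GeneModel], params: SimParams,
                        manifest: TruthManifest | None = None,
                        prefer_common_up: set[str] | None = None
                        ) -> tuple[pd.DataFrame, pd.Series, TruthManifest]:
    """Replicate log2 expression matrix with planted DE memberships.

    Condition effects (log2, relative to untreated): dectin-only genes gain
    ``effect_size_log2`` under both curdlan and curdlan+FK506; NFAT-dependent
    (common) genes keep only 25% of the curdlan effect under FK506;
    NFAT-only genes carry a sub-threshold curdlan effect (half the
    fold-change cutoff in log2 units) that FK506 removes entirely, so they
    appear in the inhibitor contrast but not the stimulation contrast.
    Down-regulated sets mirror this.  Gaussian noise (``noise_sd_log2``) is
    added per replicate.  ``prefer_common_up`` seeds the common up-set (e.g.
    with direct-target genes) so binding and expression can be coupled.
    """
    rng = np.random.default_rng(params.rng_seed + 2)
    c = params.de_cardinalities
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)

    manifest = manifest or TruthManifest()
    sub = 0.5 * np.log2(1.5)  # sub-threshold curdlan effect for NFAT-only genes
    E = params.effect_size_log2
    if E < np.log2(1.5) / 0.75:
        log.warning("effect_size_log2=%.3g: FK506 attenuation to 25%% may fall below "
                    "the 1.5-fold detection threshold", E)

    pool = list(gene_ids)
    rng.shuffle(pool)
    prefer = [g for g in (prefer_common_up or ()) if g in set(gene_ids)]
    pool = prefer + [g for g in pool if g not in set(prefer)]

    def take(k: int) -> set[str]:
        nonlocal pool
        if k > len(pool):
            raise SizingError("DE cardinalities exceed available genes")
        out, pool = set(pool[:k]), pool[k:]
        return out

    common_up = take(c["common_up"])
    dectin_up_only = take(c["dectin_up"] - c["common_up"])
    nfat_up_only = take(c["nfat_up"] - c["common_up"])
    common_down = take(c.get("common_down", 0))
    dectin_down_only = take(c["dectin_down"] - c.get("common_down", 0))
    nfat_down_only = take(c["nfat_down"] - c.get("common_down", 0))

    effects = {cond: pd.Series(0.0, index=gene_ids) for cond in CONDITIONS}
    for gid in common_up:
        effects["curdlan"][gid] = E
        effects["curdlan_fk506"][gid] = 0.25 * E
    for gid in dectin_up_only:
        effects["curdlan"][gid] = E
        effects["curdlan_fk506"][gid] = E
    for gid in nfat_up_only:
        effects["curdlan"][gid] = sub
        effects["curdlan_fk506"][gid] = sub - E
    for gid in common_down:
        effects["curdlan"][gid] = -E
        effects["curdlan_fk506"][gid] = -0.25 * E
    for gid in dectin_down_only:
        effects["curdlan"][gid] = -E
        effects["curdlan_fk506"][gid] = -E
    for gid in nfat_down_only:
        effects["curdlan"][gid] = -sub
        effects["curdlan_fk506"][gid] = -sub + E

    baseline = rng.uniform(4, 10, size=n)
    cols, data, sample_rows = [], [], []
    for cond in CONDITIONS:
        for r in range(params.n_replicates):
            name = f"{cond}_r{r + 1}"
            cols.append(name)
            sample_rows.append({"sample": name, "condition": cond})
            noise = (rng.normal(0, params.noise_sd_log2, size=n)
                     if params.noise_sd_log2 > 0 else np.zeros(n))
            data.append(baseline + effects[cond].to_numpy() + noise)
    expr = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"),
                        columns=cols)
    samples = pd.DataFrame(sample_rows).set_index("sample")["condition"]

    manifest.de_sets = {
        "dectin_up": dectin_up_only | common_up,
        "dectin_down": dectin_down_only | common_down,
        "nfat_up": nfat_up_only | common_up,
        "nfat_down": nfat_down_only | common_down,
        "common_up": common_up,
        "common_down": common_down,
    }
    return expr, samples, manifest


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def realize_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[ch])) for ch in pattern.upper())


def plant_motifs(peaks: list[Peak], genome: GenomeAssembly, params: SimParams,
                 manifest: TruthManifest | None = None,
                 pattern: str = NFAT_CONSENSUS,
                 config: RunConfig | None = None) -> tuple[GenomeAssembly, TruthManifest]:
    """Overwrite genome sequence with concrete consensus realizations near summits.

    A ``motif_plant_rate`` fraction of the given peaks receives one
    realization of the IUPAC pattern, fully inside ±``motif_flank_bp`` of the
    summit, on a random strand (minus strand plants the reverse complement).
    Placements that would cross a chromosome end are clipped toward the
    inside and logged.
    """
    if genome.sequence is None:
        raise ValidationError("plant_motifs requires a genome with sequence")
    cfg = config or RunConfig()
    rng = np.random.default_rng(params.rng_seed + 3)
    manifest = manifest or TruthManifest()
    w = len(pattern)
    flank = cfg.motif_flank_bp
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequence.items()}

    chosen = [p for p in peaks if rng.random() < params.motif_plant_rate]
    for p in chosen:
        clen = genome.chrom_lengths[p.chrom]
        lo = p.summit - flank
        hi = p.summit + flank + 1 - w
        clo, chi = max(0, lo), min(clen - w, hi)
        if (clo, chi) != (lo, hi):
            log.info("plant_motifs: placement window clipped for peak %s", p.peak_id)
        if chi < clo:
            continue
        start = int(rng.integers(clo, chi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        realization = realize_iupac(pattern, rng)
        inserted = realization if strand == "+" else revcomp(realization)
        seqs[p.chrom][start:start + w] = inserted.encode("ascii")
        manifest.motif_positions.append({
            "peak_id": p.peak_id, "chrom": p.chrom, "start": start,
            "strand": strand, "realization": realization,
        })
    mutated = GenomeAssembly(genome.chrom_names, dict(genome.chrom_lengths),
                             {c: s.decode("ascii") for c, s in seqs.items()})
    return mutated, manifest


# ---------------------------------------------------------------------------
# scenario fixtures with planted couplings
# ---------------------------------------------------------------------------

def simulate_bound_coupling(n_genes: int, seed: int, top_rate: float = 0.8,
                            base_rate: float = 0.2, top_decile: float = 0.1
                            ) -> tuple[list[GeneModel], list[Peak], pd.DataFrame]:
    """Genes with fold changes where the top decile is bound at ``top_rate``
    and the rest at ``base_rate`` — the structure behind the occupancy curve."""
    rng = np.random.default_rng(seed)
    spacing = 100_000
    genes = [GeneModel(f"g{i:05d}", "chr1", "+", i * spacing + 10_000, i * spacing + 12_000)
             for i in range(n_genes)]
    l2fc = np.sort(rng.normal(0, 1, size=n_genes))[::-1]
    n_top = max(1, int(round(top_decile * n_genes)))
    peaks = []
    for i, g in enumerate(genes):
        rate = top_rate if i < n_top else base_rate
        if rng.random() < rate:
            s = max(0, g.tss + int(rng.integers(-15_000, 15_001)))
            peaks.append(Peak(f"p{i:05d}", "chr1", max(0, s - 100), s + 101, s,
                              float(rng.uniform(5, 50)), "curdlan"))
    de = pd.DataFrame({"log2fc": l2fc}, index=pd.Index([g.gene_id for g in genes],
                                                       name="gene_id"))
    return genes, peaks, de


def simulate_height_activation_coupling(n_peaks: int, seed: int, odds_ratio: float = 3.0,
                                        base_rate: float = 0.08
                                        ) -> tuple[list[GeneModel], list[Peak], set[str]]:
    """One peak per gene with height uniform over [0, 100]; the gene is
    activated with probability ``base_rate`` for heights < 20 and
    ``odds_ratio``-fold that for heights >= 20 — the peak-height/activation
    structure of the strata analysis."""
    rng = np.random.default_rng(seed)
    spacing = 250_000
    genes, peaks, activated = [], [], set()
    for i in range(n_peaks):
        gid = f"g{i:05d}"
        start = i * spacing + 10_000
        genes.append(GeneModel(gid, "chr1", "+", start, start + 2_000))
        h = float(rng.uniform(0, 100))
        s = start + int(rng.integers(-5_000, 5_001))
        peaks.append(Peak(f"p{i:05d}", "chr1", max(0, s - 100), s + 101, s, h, "curdlan"))
        rate = base_rate * (odds_ratio if h >= 20 else 1.0)
        if rng.random() < rate:
            activated.add(gid)
    return genes, peaks, activated


def simulate_motif_sequences(n: int, length: int, seed: int, motif: str = "GGAAAA",
                             plant_rate: float = 1.0, gc: float = 0.5
                             ) -> tuple[dict[str, str], dict[str, int]]:
    """Random sequences with the motif planted at a random offset in a
    ``plant_rate`` fraction of them; returns sequences and planted offsets."""
    rng = np.random.default_rng(seed)
    seqs, positions = {}, {}
    for i in range(n):
        s = list(random_sequence(length, gc, rng))
        key = f"s{i:04d}"
        if rng.random() < plant_rate:
            off = int(rng.integers(0, length - len(motif) + 1))
            s[off:off + len(motif)] = list(motif)
            positions[key] = off
        seqs[key] = "".join(s)
    return seqs, positions


# ---------------------------------------------------------------------------
# full-dataset orchestrator
# ---------------------------------------------------------------------------

def add_expression_coupled_peaks(peaks: dict[str, list[Peak]],
                                 genes: list[GeneModel], gene_ids: set[str],
                                 genome: GenomeAssembly, params: SimParams,
                                 config: RunConfig | None = None
                                 ) -> dict[str, list[Peak]]:
    """Place one condition-flat peak near the TSS of a ``bound_bias_rate``
    fraction of the given genes, enriching binding among them (the
    upregulated-gene over-representation the occupancy curve displays).
    Flat heights keep these peaks out of the direct-target calls."""
    cfg = config or RunConfig()
    rng = np.random.default_rng(params.rng_seed + 4)
    gene_map = {g.gene_id: g for g in genes}
    pid = 0
    for gid in sorted(gene_ids):
        if rng.random() >= params.bound_bias_rate:
            continue
        g = gene_map[gid]
        clen = genome.chrom_lengths[g.chrom]
        lo = max(0, g.tss - cfg.occupancy_distance_bp)
        hi = min(clen - 1, g.tss + cfg.occupancy_distance_bp)
        summit = int(rng.integers(lo, hi + 1))
        h = float(rng.uniform(0, 100))
        for cond in CONDITIONS:
            start = max(0, summit - 200)
            end = min(clen, summit + 201)
            peaks[cond].append(
                Peak(f"b{pid:06d}", g.chrom, start, end, summit, h, cond))
        pid += 1
    return peaks


def simulate_dataset(params: SimParams, config: RunConfig | None = None):
    """Genome, genes, per-condition peaks, expression, and a unified manifest.

    Direct-target genes seed the NFAT-dependent (common up) expression set,
    and additional condition-flat peaks are planted near up-regulated genes,
    so binding and expression are coupled the way the integration analyses
    expect.
    """
    cfg = config or RunConfig()
    genome, genes = simulate_genome(params)
    peaks, manifest = simulate_peaks(genes, genome, params, cfg)
    expr, samples, manifest = simulate_expression(
        genes, params, manifest, prefer_common_up=manifest.direct_target_ids)
    peaks = add_expression_coupled_peaks(
        peaks, genes, manifest.de_sets.get("dectin_up", set()), genome, params, cfg)
    return genome, genes, peaks, expr, samples, manifest
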