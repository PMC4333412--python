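"""Readers/writers, coordinate conventions, domain records and run configuration.

All internal coordinates are 0-based half-open.  GFF3 (1-based closed) is
converted at the boundary: ``start -> start - 1``, ``end`` unchanged.  Peaks
arrive as BED6+1 with a MACS-style summit *offset* in the seventh column;
the absolute summit is reconstructed on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("nfatseq")

CONDITIONS = ("untreated", "curdlan", "curdlan_fk506")


class FormatError(ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A transcriptional unit; ``tss`` is the strand-dependent 5' end."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    """An enriched interval with summit position and height score."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    height: float
    condition: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"peak {self.peak_id}: empty interval [{self.start}, {self.end})")
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.peak_id}: summit {self.summit} outside [{self.start}, {self.end})")
        if self.height < 0:
            raise ValidationError(f"peak {self.peak_id}: negative height {self.height}")


@dataclass
class GenomeAssembly:
    """Chromosome names/lengths, optionally with DNA sequence over ACGTN."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) < 1:
                raise ValidationError(f"chromosome {name}: length must be >= 1")
            if self.sequence is not None and len(self.sequence[name]) != self.chrom_lengths[name]:
                raise ValidationError(f"chromosome {name}: sequence/length mismatch")


@dataclass(frozen=True)
class RunConfig:
    """All tunable analysis constants, with the study's defaults.

    Distances in bp.  ``flank_distal_bp`` bounds the annotation flanks (100 kb
    up/downstream of the transcriptional unit); ``flank_proximal_bp`` splits
    proximal from distal (5 kb, a promoter-annotation convention — the split
    itself is configurable).  The occupancy curve uses a 50-gene window and a
    20 kb bound indicator; direct targets require a site within 30 kb of a TSS.
    Expression thresholds are fold-change >= 1.5 at BH-adjusted p < 0.05; the
    binding ratios mirror the 1.5-fold symmetry.
    """

    flank_distal_bp: int = 100_000
    flank_proximal_bp: int = 5_000
    occupancy_window_genes: int = 50
    occupancy_distance_bp: int = 20_000
    direct_target_distance_bp: int = 30_000
    fc_cutoff: float = 1.5
    adj_p_cutoff: float = 0.05
    motif_flank_bp: int = 100
    motif_sample_n: int = 600
    motif_sample_groups: int = 3
    height_strata: tuple[tuple[float, float], ...] = ((0, 20), (20, 30), (30, 50), (50, 100))
    binding_up_ratio: float = 1.5
    binding_down_ratio: float = 1 / 1.5
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("flank_distal_bp", "flank_proximal_bp", "occupancy_distance_bp",
                     "direct_target_distance_bp", "motif_flank_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 < self.adj_p_cutoff < 1):
            raise ValidationError("adj_p_cutoff must lie in (0, 1)")
        if self.fc_cutoff <= 0 or self.binding_up_ratio <= 0 or self.binding_down_ratio <= 0:
            raise ValidationError("cutoffs must be > 0")
        strata = self.height_strata
        for (lo, hi), (lo2, _hi2) in zip(strata, strata[1:]):
            if hi > lo2 or lo >= hi:
                raise ValidationError("height strata must be ascending and non-overlapping")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "height_strata" in data:
            data["height_strata"] = tuple(tuple(b) for b in data["height_strata"])
        data.update(overrides)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        log.info("resolved config: %s", cfg)
        return cfg

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GENE_TSV_COLS = ["gene_id", "chrom", "strand", "start", "end"]


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (rows of type ``gene``) or a TSV.

    The format is inferred from the suffix when not given.  GFF3 coordinates
    are 1-based closed and converted to the internal 0-based half-open
    convention.  Duplicate gene ids raise :class:`ValidationError`.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "gff3":
        genes = list(_iter_gff3_genes(path))
    elif format == "tsv":
        genes = list(_iter_tsv_genes(path))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _iter_gff3_genes(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.strip().startswith("ID="):
                    gene_id = kv.strip()[3:]
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene row lacks an ID attribute")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
            yield GeneModel(gene_id, chrom, strand, start_i - 1, end_i)


def _iter_tsv_genes(path: Path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_TSV_COLS:
            raise FormatError(f"{path}:1: expected header {_GENE_TSV_COLS}, got {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            gene_id, chrom, strand, start, end = parts
            try:
                yield GeneModel(gene_id, chrom, strand, int(start), int(end))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.start, g.end) for g in genes],
        columns=_GENE_TSV_COLS,
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# peaks (BED6+1: chrom start end name height strand summit_offset)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, condition: str = "") -> list[Peak]:
    """Read a BED6+1 peak file; column 7 is the summit offset from ``start``."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 BED columns, got {len(parts)}")
            chrom, start, end, name, height, _strand, offset = parts[:7]
            try:
                start_i, end_i, off_i = int(start), int(end), int(offset)
                height_f = float(height)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from e
            try:
                peaks.append(Peak(name, chrom, start_i, end_i, start_i + off_i, height_f, condition))
            except ValidationError as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from e
    if not peaks:
        log.warning("peak file %s is empty", path)
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.height:g}\t.\t{p.summit - p.start}\n")


# ---------------------------------------------------------------------------
# expression matrices, sample sheets, generic tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: rows = genes (index column ``gene_id``), columns = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return df


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Sample sheet TSV with columns ``sample`` and ``condition``."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"} <= set(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns sample, condition")
    return df.set_index("sample")["condition"]


def write_table(records, path: str | Path) -> None:
    """Write any tabular result as a UTF-8, newline-terminated TSV with header."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> GenomeAssembly:
    records = list(SeqIO.parse(str(path), "fasta"))
    names = [r.id for r in records]
    seqs = {r.id: str(r.seq).upper() for r in records}
    return GenomeAssembly(names, {n: len(seqs[n]) for n in names}, seqs)


def write_genome_fasta(genome: GenomeAssembly, path: str | Path) -> None:
    if genome.sequence is None:
        raise ValidationError("genome has no sequence to write")
    recs = [SeqRecord(Seq(genome.sequence[n]), id=n, description="") for n in genome.chrom_names]
    SeqIO.write(recs, str(path), "fasta")


def write_sequences_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def group_peaks_by_chrom(peaks: Iterable[Peak]) -> dict[str, list[Peak]]:
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        out.setdefault(p.chrom, []).append(p)
    return out
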