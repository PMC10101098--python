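"""Gene models, genome indexing, and strand-aware promoter windows.

The promoter of a gene is defined here as the fixed-width region immediately
upstream of the *translation* start site (the first translated base), the
anchor this pipeline uses throughout. All internal coordinates are 0-based
half-open on the forward strand; GFF3 input (1-based closed) is converted on
read, matching BED conventions everywhere else.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its translation-start coordinate.

    ``tss`` is the 0-based position of the first translated base on the
    forward reference strand (for a minus-strand gene this is the *highest*
    coordinate of its coding span).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be non-negative, got {self.tss}")


@dataclass
class GenomeIndex:
    """Chromosome name -> length map derived from the genome FASTA."""

    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


@dataclass(frozen=True)
class PromoterWindow:
    """0-based half-open interval upstream of a gene's translation start."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_gene_models(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read gene models from a GFF3 file or a 4/5-column TSV.

    TSV columns: gene_id, chrom, strand, tss[, name] with a header line.
    For GFF3, the translation start is taken from the CDS span of each gene
    (lowest CDS start on +, highest CDS end on -), converted to 0-based; a
    gene without CDS children falls back to its own feature span. Records
    without a strand are rejected with a warning; duplicate gene ids raise.
    """
    path = Path(path)
    if format == "tsv":
        return _read_gene_models_tsv(path)
    if format == "gff3":
        return _read_gene_models_gff3(path)
    raise ValueError(f"unknown gene-model format: {format!r}")


def _read_gene_models_tsv(path: Path) -> list[GeneModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene-model TSV missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in {path}: {dup}")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand not in STRANDS:
            logger.warning("gene %s has no valid strand (%r); skipped", row.gene_id, row.strand)
            continue
        name = getattr(row, "name", None)
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand, int(row.tss),
                               None if name is None or name != name else str(name)))
    return genes


def _read_gene_models_gff3(path: Path) -> list[GeneModel]:
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path), tmp.name, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes: list[GeneModel] = []
        seen: set[str] = set()
        for gene in db.features_of_type("gene"):
            gene_id = gene.attributes.get("ID", [gene.id])[0]
            if gene_id in seen:
                raise ValueError(f"duplicate gene ID in {path}: {gene_id}")
            if gene.strand not in STRANDS:
                logger.warning("gene %s has no strand; record rejected", gene_id)
                continue
            cds = list(db.children(gene, featuretype="CDS"))
            if cds:
                starts_1b = [c.start for c in cds]
                ends_1b = [c.end for c in cds]
            else:
                starts_1b, ends_1b = [gene.start], [gene.end]
            # GFF3 is 1-based closed: 0-based first base = start-1; last = end-1
            tss = min(starts_1b) - 1 if gene.strand == "+" else max(ends_1b) - 1
            name_attr = gene.attributes.get("Name", [None])[0]
            genes.append(GeneModel(gene_id, gene.seqid, gene.strand, tss, name_attr))
            seen.add(gene_id)
    return genes


def read_fasta(path: str | Path) -> tuple[GenomeIndex, dict[str, str]]:
    """Read a genome FASTA; return (GenomeIndex, sequences by chromosome)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeIndex({name: len(s) for name, s in seqs.items()}), seqs


def promoter_window(gene: GeneModel, genome: GenomeIndex, upstream_bp: int = 1500) -> PromoterWindow:
    """The upstream promoter window of a gene, clipped to the chromosome.

    On + the window is [tss - upstream_bp, tss); on - it is
    [tss + 1, tss + 1 + upstream_bp). The translated start base itself is
    excluded. Fully clipped windows (e.g. tss = 0 on +) come back empty and
    are logged, not rejected.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome index")
    L = genome.length(gene.chrom)
    if gene.tss >= L:
        raise ValueError(f"gene {gene.gene_id}: tss {gene.tss} beyond chromosome length {L}")
    if gene.strand == "+":
        start, end = max(0, gene.tss - upstream_bp), gene.tss
    else:
        start, end = gene.tss + 1, min(L, gene.tss + 1 + upstream_bp)
    if start == end:
        logger.info("gene %s: promoter window fully clipped", gene.gene_id)
    return PromoterWindow(gene.gene_id, gene.chrom, start, end)


def promoter_windows(genes: list[GeneModel], genome: GenomeIndex,
                     upstream_bp: int = 1500) -> list[PromoterWindow]:
    """Promoter windows for all genes, dropping empty (fully clipped) ones."""
    out = []
    for g in genes:
        w = promoter_window(g, genome, upstream_bp)
        if len(w) > 0:
            out.append(w)
    return out


def write_bed(intervals, path: str | Path) -> None:
    """Write BED4 lines (chrom, start, end, name) for windows or peaks."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "gene_id", None) or getattr(iv, "peak_id", ".")
            if iv.start >= iv.end:
                raise ValueError(f"BED interval with start >= end: {iv}")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[PromoterWindow]:
    """Read BED4 intervals back as named windows (coordinate-exact)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED line with fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{i}: BED interval with start >= end")
            name = parts[3] if len(parts) > 3 else "."
            out.append(PromoterWindow(name, chrom, start, end))
    return out
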