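"""Readers, writers and the shared interval model.

All coordinates inside the toolkit are 0-based half-open (BED convention);
conversion from GFF3's 1-based closed coordinates happens at the reader
boundary and nowhere else. FASTA case is preserved on read because lowercase
carries soft-masking state on write.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

UNANNOTATED = "UNANNOTATED"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path, mode: str = "rt"):
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class GenomeSequence:
    """A single FASTA record; residue case carries masking state."""

    seq_id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a sequence; length = end - start."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatInterval:
    """A called (and possibly classified) repeat.

    score is the mean k-mer count over the repeat's word-start positions;
    te_class is the library classification or UNANNOTATED.
    """

    interval: GenomicInterval
    score: float = 0.0
    te_class: str = UNANNOTATED

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("repeat score must be non-negative")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class GeneFeature:
    """A protein-coding gene with the exons of one transcript."""

    gene_id: str
    gene_interval: GenomicInterval
    exon_intervals: list[GenomicInterval] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self):
        for ex in self.exon_intervals:
            if ex.start < self.gene_interval.start or ex.end > self.gene_interval.end:
                raise ValueError(
                    f"exon {ex.start}-{ex.end} outside gene bounds of {self.gene_id}"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read FASTA records preserving order and residue case.

    seq_id is the header token before the first whitespace; the full header
    is kept as description. Duplicate ids and empty files are errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(GenomeSequence(rec.id, str(rec.seq), rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 60) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            header = rec.description if rec.description else rec.seq_id
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Sequence[RepeatInterval], path) -> None:
    """Write repeats as BED6: chrom start end te_class score strand.

    Scores are written with repr so float values round-trip losslessly.
    """
    with _open_text(path, "wt") as out:
        for riv in intervals:
            iv = riv.interval
            out.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{riv.te_class}\t"
                f"{riv.score!r}\t{iv.strand}\n"
            )


def read_bed(path) -> list[RepeatInterval]:
    out: list[RepeatInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            seq_id, start, end = cols[0], int(cols[1]), int(cols[2])
            te_class = cols[3] if len(cols) > 3 else UNANNOTATED
            score = float(cols[4]) if len(cols) > 4 else 0.0
            strand = cols[5] if len(cols) > 5 else "."
            out.append(
                RepeatInterval(GenomicInterval(seq_id, start, end, strand), score, te_class)
            )
    return out


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read a BED file as bare intervals (e.g. NLR loci from an NLR caller)."""
    return [r.interval for r in read_bed(path)]


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(path) -> list[GeneFeature]:
    """Extract one GeneFeature per gene from a GFF3 file.

    Exons are taken from the transcript tagged canonical (an attribute value
    containing 'canonical'), otherwise from the longest transcript by genomic
    span (ties broken by transcript id). GFF 1-based closed coordinates are
    converted to 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneFeature] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_iv = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        chosen = None
        for tx in transcripts:
            attr_values = [v.lower() for vals in tx.attributes.values() for v in vals]
            if any("canonical" in v for v in attr_values):
                chosen = tx
                break
        if chosen is None and transcripts:
            chosen = min(transcripts, key=lambda t: (-(t.end - t.start + 1), t.id))
        exons: list[GenomicInterval] = []
        parent = chosen if chosen is not None else gene
        for ex in db.children(parent, featuretype="exon", order_by="start"):
            exons.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand))
        feat = GeneFeature(gene.id, gene_iv, exons, gene.strand if gene.strand in "+-" else "+")
        genes.append(feat)
    return genes


# ---------------------------------------------------------------------------
# PAF


@dataclass(frozen=True)
class PafRecord:
    """One line of minimap2-style PAF output (0-based half-open spans)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0


def read_paf(path) -> list[PafRecord]:
    records: list[PafRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: PAF needs >= 12 columns, got {len(cols)}"
                )
            records.append(
                PafRecord(
                    cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4],
                    cols[5], int(cols[6]), int(cols[7]), int(cols[8]),
                    int(cols[9]), int(cols[10]), int(cols[11]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# GFF writing (used by the fixture generator and round-trip tests)


def write_gff_genes(genes: Iterable[GeneFeature], path) -> None:
    """Write gene/mRNA/exon GFF3 with one transcript per gene."""
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            iv = g.gene_interval
            out.write(
                f"{iv.seq_id}\ttemasker\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            tx_id = f"{g.gene_id}.t1"
            out.write(
                f"{iv.seq_id}\ttemasker\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\tID={tx_id};Parent={g.gene_id};tag=canonical\n"
            )
            for i, ex in enumerate(g.exon_intervals, 1):
                out.write(
                    f"{ex.seq_id}\ttemasker\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={tx_id}.exon{i};Parent={tx_id}\n"
                )
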