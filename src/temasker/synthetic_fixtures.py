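"""Synthetic genomes with planted TE families for end-to-end testing.

The generator emulates the repeat structure the two-step protocol assumes:
interspersed, mutated copies of a handful of TE families inserted on both
strands of an i.i.d. background, a gene annotation in which a configurable
subset of genes overlaps repeats (creating a domain-enrichment signal), NLR
loci placed in repeat-free background, and a classified truth library. Every
output is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np

from .repeat_annotator import LibrarySequence
from .sequence_io import (
    GeneFeature,
    GenomeSequence,
    GenomicInterval,
    RepeatInterval,
    reverse_complement,
    write_bed,
    write_fasta,
    write_gff_genes,
)

TE_CLASSES = ("LTR/Gypsy", "LTR/Copia", "DNA/Mutator", "LINE/L1")

# synthetic Pfam-like accessions: one TE-associated domain planted in genes
# that overlap repeats, and a pool of housekeeping domains for the rest
TE_DOMAIN = "PF07727"  # reverse-transcriptase-like marker
BACKGROUND_DOMAINS = ("PF00069", "PF00067", "PF00201", "PF03106", "PF00847", "PF02362")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the default synthetic genome.

    1 Mbp of background at 40% GC carrying 5 TE families x 20 copies of
    300-3000 bp, each copy independently substituted at 2% (no indels by
    default), plus 200 genes of which 20 overlap repeat copies and 10
    repeat-free NLR loci.
    """

    genome_length: int = 1_000_000
    n_families: int = 5
    copies_per_family: int = 20
    family_length_range: tuple[int, int] = (300, 3000)
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    n_genes: int = 200
    n_te_genes: int = 20
    n_nlr: int = 10
    gc_content: float = 0.40
    seed: int = 42

    def __post_init__(self):
        if not (0 <= self.substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("mutation rates must be in [0, 1)")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_te_genes > self.n_genes:
            raise ValueError("n_te_genes cannot exceed n_genes")


@dataclass
class SimulatedDataset:
    """All truth objects for one simulated genome."""

    genome: list[GenomeSequence]
    truth_repeats: list[RepeatInterval]
    library: list[LibrarySequence]
    genes: list[GeneFeature]
    nlr_loci: list[GenomicInterval]
    gene_domains: dict[str, set[str]]
    params: SimulationParams

    @property
    def planted_fraction(self) -> float:
        planted = sum(r.length for r in self.truth_repeats)
        return planted / sum(len(g) for g in self.genome)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "repeats": outdir / "truth_repeats.bed",
            "library": outdir / "truth_library.fa",
            "genes": outdir / "genes.gff3",
            "nlr": outdir / "nlr.bed",
            "domains": outdir / "gene_domains.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_bed(self.truth_repeats, paths["repeats"])
        write_fasta(
            [
                GenomeSequence(e.lib_id, e.residues, f"{e.lib_id}#{e.te_class}")
                for e in self.library
            ],
            paths["library"],
        )
        write_gff_genes(self.genes, paths["genes"])
        write_bed(
            [RepeatInterval(iv, 0.0, "NLR") for iv in self.nlr_loci], paths["nlr"]
        )
        with open(paths["domains"], "w") as out:
            for gene_id in sorted(self.gene_domains):
                for acc in sorted(self.gene_domains[gene_id]):
                    out.write(f"{gene_id}\t{acc}\n")
        return paths


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(arr.size) < sub_rate)
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    out = arr.tobytes().decode("ascii")
    if indel_rate > 0:
        chars = list(out)
        result = []
        for ch in chars:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # single-bp deletion
            result.append(ch)
            if indel_rate / 2 <= r < indel_rate:
                result.append("ACGT"[rng.integers(4)])  # single-bp insertion
        out = "".join(result)
    return out


def simulate_genome(params: SimulationParams | None = None) -> SimulatedDataset:
    """Build a genome with planted TE copies plus all truth annotations.

    Copies are placed non-overlapping (no nested insertions); the genome
    length equals params.genome_length exactly when indel_rate is 0, and
    within a few bp of it otherwise (indels change copy lengths after the
    background budget is fixed).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    chrom = "chr1"

    # family consensus sequences and their mutated copies
    library: list[LibrarySequence] = []
    copies: list[tuple[str, str, str]] = []  # (family_id, class, residues) per copy
    for fi in range(params.n_families):
        length = int(
            rng.integers(params.family_length_range[0], params.family_length_range[1] + 1)
        )
        consensus = _random_seq(rng, length, params.gc_content)
        fam_id = f"fam{fi + 1}"
        te_class = TE_CLASSES[fi % len(TE_CLASSES)]
        library.append(LibrarySequence(fam_id, consensus, "truth", te_class))
        for _ in range(params.copies_per_family):
            copy = _mutate(rng, consensus, params.substitution_rate, params.indel_rate)
            copies.append((fam_id, te_class, copy))

    total_copy_bp = sum(len(c) for _, _, c in copies)
    if total_copy_bp > 0.9 * params.genome_length:
        raise ValueError(
            f"planted repeat bp ({total_copy_bp}) exceeds 90% of genome length"
        )
    background_bp = params.genome_length - total_copy_bp

    order = rng.permutation(len(copies))
    n_gaps = len(copies) + 1
    weights = rng.random(n_gaps) + 0.25
    gap_sizes = np.floor(weights / weights.sum() * background_bp).astype(int)
    gap_sizes[0] += background_bp - int(gap_sizes.sum())

    pieces: list[str] = []
    truth: list[RepeatInterval] = []
    gaps: list[GenomicInterval] = []  # repeat-free background segments
    pos = 0
    for slot in range(n_gaps):
        gl = int(gap_sizes[slot])
        if gl > 0:
            pieces.append(_random_seq(rng, gl, params.gc_content))
            gaps.append(GenomicInterval(chrom, pos, pos + gl))
            pos += gl
        if slot < len(copies):
            fam_id, te_class, copy = copies[order[slot]]
            strand = "+" if rng.random() < 0.5 else "-"
            placed = copy if strand == "+" else reverse_complement(copy)
            pieces.append(placed)
            truth.append(
                RepeatInterval(
                    GenomicInterval(chrom, pos, pos + len(placed), strand), 0.0, te_class
                )
            )
            pos += len(placed)
    residues = "".join(pieces)
    genome = [GenomeSequence(chrom, residues)]

    nlr_loci = _place_in_gaps(rng, gaps, params.n_nlr, 2000, 4000, margin=100)
    occupied = list(nlr_loci)
    genes: list[GeneFeature] = []
    gene_domains: dict[str, set[str]] = {}

    # genes overlapping planted repeats: anchored across a repeat copy edge
    te_copy_idx = rng.choice(len(truth), size=min(params.n_te_genes, len(truth)), replace=False)
    for gi, ci in enumerate(sorted(te_copy_idx)):
        riv = truth[ci].interval
        gstart = max(0, riv.start - 200)
        gend = min(len(residues), riv.start + min(1000, riv.length))
        gene_id = f"teg{gi + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, gstart, gend, strand)
        exons = [GenomicInterval(chrom, gstart, gend, strand)]
        genes.append(GeneFeature(gene_id, iv, exons, strand))
        gene_domains[gene_id] = {TE_DOMAIN, str(rng.choice(BACKGROUND_DOMAINS))}
        occupied.append(iv)  # keep background genes clear of TE-overlap genes

    # background genes in repeat-free gaps
    n_bg = params.n_genes - len(te_copy_idx)
    bg_genes = _place_in_gaps(rng, gaps, n_bg, 800, 2500, margin=150, avoid=occupied)
    for gi, iv in enumerate(bg_genes):
        gene_id = f"g{gi + 1}"
        n_exons = int(rng.integers(1, 4))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(iv.seq_id, iv.start, iv.end, strand)
        exons = [
            GenomicInterval(e.seq_id, e.start, e.end, strand)
            for e in _split_exons(rng, iv, n_exons)
        ]
        genes.append(GeneFeature(gene_id, iv, exons, strand))
        n_dom = int(rng.integers(1, 3))
        gene_domains[gene_id] = set(
            rng.choice(BACKGROUND_DOMAINS, size=n_dom, replace=False)
        )
    if len(bg_genes) < n_bg:
        warnings.warn(
            f"placed only {len(bg_genes)}/{n_bg} background genes (insufficient gap space)"
        )
    genes.sort(key=lambda g: g.gene_interval.start)

    return SimulatedDataset(genome, truth, library, genes, nlr_loci, gene_domains, params)


def _place_in_gaps(
    rng: np.random.Generator,
    gaps: list[GenomicInterval],
    n: int,
    min_len: int,
    max_len: int,
    margin: int,
    avoid: list[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Carve n non-overlapping intervals out of background gaps."""
    avoid = list(avoid or [])
    placed: list[GenomicInterval] = []
    order = rng.permutation(len(gaps))
    cursors = {}
    gi = 0
    attempts = 0
    while len(placed) < n and attempts < 20 * max(n, 1):
        attempts += 1
        gap = gaps[order[gi % len(gaps)]]
        gi += 1
        cur = cursors.get(gap.start, gap.start + margin)
        length = int(rng.integers(min_len, max_len + 1))
        if cur + length + margin > gap.end:
            continue
        iv = GenomicInterval(gap.seq_id, cur, cur + length)
        if any(iv.overlap(other) for other in avoid):
            cursors[gap.start] = cur + length + margin
            continue
        placed.append(iv)
        avoid.append(iv)
        cursors[gap.start] = cur + length + margin
    placed.sort()
    return placed


def _split_exons(
    rng: np.random.Generator, gene: GenomicInterval, n_exons: int
) -> list[GenomicInterval]:
    if n_exons == 1 or gene.length < 6 * n_exons:
        return [gene]
    cuts = np.sort(rng.choice(np.arange(gene.start + 2, gene.end - 2), size=2 * (n_exons - 1), replace=False))
    bounds = [gene.start, *cuts.tolist(), gene.end]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(gene.seq_id, s, e))
    return exons or [gene]


def evaluate_against_truth(
    called: list[RepeatInterval], truth: list[GenomicInterval]
) -> tuple[float, float, float]:
    """Base-level (recall, precision, F1) of repeat calls against truth.

    Computed on per-base sets via merged-interval arithmetic. Empty truth is
    an error; empty calls give recall 0 and, by convention, precision 1 with
    a warning (no called base is wrong).
    """
    from .benchmark_stats import _merged_starts_ends, _overlap_with_merged

    if not truth:
        raise ValueError("recall undefined for empty truth")
    truth_by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in truth:
        truth_by_seq.setdefault(iv.seq_id, []).append(iv)
    called_by_seq: dict[str, list[GenomicInterval]] = {}
    for r in called:
        called_by_seq.setdefault(r.interval.seq_id, []).append(r.interval)

    truth_bp = called_bp = inter_bp = 0
    for seq_id, t_ivs in truth_by_seq.items():
        ts, te = _merged_starts_ends(t_ivs)
        truth_bp += int(np.sum(te - ts))
        cs, ce = _merged_starts_ends(called_by_seq.get(seq_id, []))
        for s, e in zip(cs, ce):
            inter_bp += _overlap_with_merged(GenomicInterval(seq_id, int(s), int(e)), ts, te)
    for ivs in called_by_seq.values():
        cs, ce = _merged_starts_ends(ivs)
        called_bp += int(np.sum(ce - cs))

    recall = inter_bp / truth_bp
    if called_bp == 0:
        warnings.warn("no called repeats; precision reported as 1 by convention")
        precision = 1.0
    else:
        precision = inter_bp / called_bp
    f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    return recall, precision, f1
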