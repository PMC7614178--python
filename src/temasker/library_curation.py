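"""Nonredundant repeat-library construction and its control-domain benchmark.

The curation procedure merges several source collections (TE libraries and
transcript sets), clusters them at 95% identity / 75% coverage of the shorter
sequence, takes the longest member of each cluster as representative, and
filters mixed TE+transcript clusters by library support and by the fraction
of members flagged as potential host genes. The resulting library is
benchmarked with positive (TE-associated) and negative (disease-resistance
gene) control Pfam domain lists.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio.Seq import Seq

from .alignment import AlignParams, align_pair
from .repeat_annotator import LibrarySequence, parse_classification, read_library


@dataclass(frozen=True)
class ClusteringParams:
    """Clustering thresholds; identity/coverage are percentages.

    Coverage is measured on the SHORTER sequence of a pair: a full-length
    fragment of a longer element still clusters with it. Length bounds are
    inclusive admissible limits applied when libraries are merged.
    """

    min_identity: float = 95.0
    min_coverage: float = 75.0
    min_len: int = 90
    max_len: int = 55000

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not 0 < self.min_coverage <= 100:
            raise ValueError("min_coverage must be in (0, 100]")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")


@dataclass
class Cluster:
    """A connected component of the similarity graph, with provenance."""

    member_ids: set[str]
    te_libraries_present: set[str] = field(default_factory=set)
    has_transcripts: bool = False
    host_gene_fraction: float = 0.0
    representative: str = ""

    @property
    def is_mixed(self) -> bool:
        return self.has_transcripts and bool(self.te_libraries_present)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Control-domain benchmark counts."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("sensitivity undefined: TP + FN = 0")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ZeroDivisionError("specificity undefined: TN + FP = 0")
        return self.tn / (self.tn + self.fp)

    def rounded(self) -> tuple[float, float]:
        """(sensitivity, specificity) at reporting precision (2 decimals)."""
        return round(self.sensitivity, 2), round(self.specificity, 2)


@dataclass(frozen=True)
class LibrarySource:
    """One input collection: FASTA path, unique tag, TE or transcript kind."""

    path: str
    tag: str
    kind: str = "TE"  # TE | transcript
    host_flag_path: str | None = None


def merge_libraries(
    sources: Sequence[LibrarySource], params: ClusteringParams | None = None
) -> list[LibrarySequence]:
    """Pool source collections, applying inclusive length bounds.

    Sequence ids are prefixed with the source tag so ids stay unique across
    collections; a per-source plain-text id list marks potential host genes.
    """
    params = params or ClusteringParams()
    if not sources:
        raise ValueError("at least one source is required")
    tags = [s.tag for s in sources]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate source tags: {sorted(tags)}")
    merged: list[LibrarySequence] = []
    for src in sources:
        flagged: set[str] = set()
        if src.host_flag_path:
            flagged = {
                line.strip() for line in open(src.host_flag_path) if line.strip()
            }
        for entry in read_library(src.path, source_library=src.tag, source_kind=src.kind):
            if not params.min_len <= len(entry) <= params.max_len:
                continue
            merged.append(
                LibrarySequence(
                    f"{src.tag}:{entry.lib_id}",
                    entry.residues,
                    src.tag,
                    entry.te_class,
                    host_gene_flag=entry.lib_id in flagged,
                    source_kind=src.kind,
                )
            )
    return merged


def pairwise_similarity(
    a: LibrarySequence, b: LibrarySequence, align_params: AlignParams | None = None
) -> tuple[float, float]:
    """(identity %, coverage %) from combined local alignments of a pair.

    Coverage is the union of aligned blocks projected on the shorter
    sequence, divided by its length; identity is matches over aligned columns
    summed across the non-redundant blocks. Both strands are searched.
    """
    if not a.residues or not b.residues:
        raise ValueError("empty sequence in pairwise_similarity")
    align_params = align_params or AlignParams()
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    blocks = align_pair(
        shorter.residues, longer.residues, longer.lib_id, align_params,
        min_span=min(30, len(shorter)), min_identity=0.5,
    )
    if not blocks:
        return 0.0, 0.0
    # greedy non-redundant selection on the shorter sequence
    blocks.sort(key=lambda h: (-h.score, h.q_start))
    covered: list[tuple[int, int]] = []
    matches = columns = 0
    for blk in blocks:
        new_bp = blk.aligned_bp - sum(
            max(0, min(blk.q_end, e) - max(blk.q_start, s)) for s, e in covered
        )
        if new_bp <= 0:
            continue
        covered.append((blk.q_start, blk.q_end))
        matches += blk.matches
        columns += blk.columns
    merged: list[list[int]] = []
    for s, e in sorted(covered):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    cov_bp = sum(e - s for s, e in merged)
    coverage = 100.0 * cov_bp / len(shorter)
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, min(coverage, 100.0)


def cluster_sequences(
    seqs: Sequence[LibrarySequence],
    params: ClusteringParams | None = None,
    align_params: AlignParams | None = None,
) -> list[Cluster]:
    """Partition sequences into connected components of the similarity graph.

    An edge joins two sequences when identity >= min_identity AND coverage of
    the shorter >= min_coverage. A shared-word prefilter (15-mers) skips
    pairs that cannot reach the identity cutoff. The partition, provenance
    summaries and representatives are deterministic and independent of input
    order.
    """
    params = params or ClusteringParams()
    if not seqs:
        raise ValueError("no sequences to cluster")
    by_id = {s.lib_id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate lib_ids in input")

    # candidate pairs share at least one exact 15-mer (on either strand)
    word = 15
    from .sequence_io import reverse_complement

    buckets: dict[str, set[str]] = {}
    for s in seqs:
        res = s.residues.upper()
        words = {res[i : i + word] for i in range(0, max(1, len(res) - word + 1), 5)}
        words |= {reverse_complement(w) for w in words}
        for w in words:
            buckets.setdefault(w, set()).add(s.lib_id)
    candidates: set[tuple[str, str]] = set()
    for ids in buckets.values():
        if len(ids) < 2:
            continue
        ordered = sorted(ids)
        for i, x in enumerate(ordered):
            for y in ordered[i + 1 :]:
                candidates.add((x, y))

    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for x, y in sorted(candidates):
        ident, cov = pairwise_similarity(by_id[x], by_id[y], align_params)
        if ident >= params.min_identity and cov >= params.min_coverage:
            graph.add_edge(x, y)

    clusters: list[Cluster] = []
    for comp in nx.connected_components(graph):
        members = set(comp)
        entries = [by_id[m] for m in members]
        te_libs = {e.source_library for e in entries if e.source_kind == "TE"}
        has_tx = any(e.source_kind == "transcript" for e in entries)
        host_frac = sum(e.host_gene_flag for e in entries) / len(entries)
        clusters.append(
            Cluster(
                member_ids=members,
                te_libraries_present=te_libs,
                has_transcripts=has_tx,
                host_gene_fraction=host_frac,
                representative=pick_representative(members, seqs),
            )
        )
    clusters.sort(key=lambda c: min(c.member_ids))
    return clusters


def pick_representative(member_ids: Iterable[str], seqs: Sequence[LibrarySequence]) -> str:
    """Longest member; length ties broken by lexicographically smallest id."""
    members = set(member_ids)
    if not members:
        raise ValueError("empty cluster")
    by_id = {s.lib_id: s for s in seqs}
    return min(members, key=lambda m: (-len(by_id[m]), m))


def filter_clusters(
    clusters: Sequence[Cluster],
    min_libraries: int = 6,
    max_host_fraction: float = 0.0,
) -> list[Cluster]:
    """Keep TE-only clusters; drop transcript-only; gate mixed clusters.

    A mixed cluster survives only with members from at least min_libraries
    distinct TE collections AND a potential-host-gene fraction no larger than
    max_host_fraction (default exactly zero).
    """
    kept = []
    for cl in clusters:
        if not cl.te_libraries_present:
            continue  # transcript-only
        if not cl.has_transcripts:
            kept.append(cl)
        elif len(cl.te_libraries_present) >= min_libraries and (
            cl.host_gene_fraction <= max_host_fraction
        ):
            kept.append(cl)
    return kept


def build_library(
    clusters: Sequence[Cluster], seqs: Sequence[LibrarySequence]
) -> list[LibrarySequence]:
    """Representatives of the kept clusters; te_class inherited from each."""
    by_id = {s.lib_id: s for s in seqs}
    return [by_id[cl.representative] for cl in clusters]


def six_frame_translate(seq: str) -> list[str]:
    """Standard-code translation in frames +1..+3 and -1..-3.

    Stops are '*'; trailing partial codons are dropped; sequences shorter
    than one codon give six empty peptides.
    """
    if len(seq) < 3:
        return [""] * 6
    peptides = []
    for template in (seq, str(Seq(seq).reverse_complement())):
        for f in range(3):
            sub = template[f : f + 3 * ((len(template) - f) // 3)]
            peptides.append(str(Seq(sub).translate()))
    return peptides


def evaluate_controls(
    found_domains: set[str],
    positive_list: Sequence[str],
    negative_list: Sequence[str],
) -> ConfusionMatrix:
    """Confusion matrix of the control-domain benchmark.

    Positives are TE-associated domains expected in the library; negatives
    are disease-resistance-gene domains expected absent. The lists may
    overlap (some zinc-finger domains occur in transposases and R genes); an
    overlap triggers a warning because such domains count on both sides.
    """
    pos, neg = set(positive_list), set(negative_list)
    if not pos or not neg:
        raise ValueError("positive and negative control lists must be non-empty")
    shared = pos & neg
    if shared:
        warnings.warn(
            f"{len(shared)} domain(s) appear in both control lists: {sorted(shared)}"
        )
    return ConfusionMatrix(
        tp=len(pos & found_domains),
        fn=len(pos - found_domains),
        tn=len(neg - found_domains),
        fp=len(neg & found_domains),
    )


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def read_domain_hits(path) -> set[tuple[str, str]]:
    """(sequence id, Pfam accession) pairs from a domtblout-dialect table.

    Columns follow hmmscan --domtblout: target name, target accession, tlen,
    query name, ... Accession version suffixes are stripped (PF02892.12 ->
    PF02892); when the accession column is '-', the target name is used.
    """
    hits: set[tuple[str, str]] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 4 columns, got {len(cols)}"
                )
            accession = cols[1] if cols[1] != "-" else cols[0]
            accession = _VERSION_SUFFIX.sub("", accession)
            hits.add((cols[3], accession))
    return hits


def scan_motifs(
    seqs: Sequence[LibrarySequence], motif_table: dict[str, str]
) -> set[tuple[str, str]]:
    """Literal peptide-motif scan over six-frame translations.

    A lightweight domain finder for fixtures and desk-scale benchmarks:
    motif_table maps an accession to a literal peptide; an entry whose
    translation (any frame) contains the peptide is assigned the accession.
    Real pipelines consume an external HMM-search table via read_domain_hits.
    """
    found: set[tuple[str, str]] = set()
    for s in seqs:
        frames = six_frame_translate(s.residues)
        for acc, motif in motif_table.items():
            if any(motif in pep for pep in frames):
                found.add((s.lib_id, acc))
    return found
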