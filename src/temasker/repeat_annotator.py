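"""Classification of called repeats against a classified repeat library.

Second step of the two-step protocol: repeats longer than 90 bp are extracted
from the genome and aligned to a repeat library whose FASTA headers carry the
classification after a hash (e.g. ``RLG_43695:mipsREdat_9.3p_ALL#LTR/Gypsy``).
Each repeat inherits the class of its best-scoring hit; repeats without a hit
stay UNANNOTATED. Alignment uses the internal seed-chain-extend aligner by
default, or externally produced PAF records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .alignment import AlignParams, LocalAlignment, align_pair
from .sequence_io import (
    UNANNOTATED,
    GenomeSequence,
    PafRecord,
    RepeatInterval,
    read_fasta,
)

UNCLASSIFIED = "UNCLASSIFIED"
NONE = "NONE"

DEFAULT_MIN_ANNOT_LEN = 90  # repeats must be strictly longer to be classified


@dataclass
class LibrarySequence:
    """A repeat-library entry with provenance and classification."""

    lib_id: str
    residues: str
    source_library: str = ""
    te_class: str = UNCLASSIFIED
    host_gene_flag: bool = False
    source_kind: str = "TE"  # TE or transcript; needed for mixed-cluster rules

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RepeatAnnotation:
    """Best-hit classification of one called repeat."""

    repeat: RepeatInterval
    best_target: str = NONE
    te_class: str = UNANNOTATED
    identity: float = 0.0
    aligned_bp: int = 0

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.aligned_bp > self.repeat.length:
            raise ValueError("aligned_bp cannot exceed repeat length")


def parse_classification(header: str) -> tuple[str, str]:
    """Split a library header at the FIRST '#': (lib_id, te_class).

    Without a '#' the class is UNCLASSIFIED; a trailing '#' likewise (with a
    warning), so malformed headers never crash a run.
    """
    if not header:
        raise ValueError("empty library header")
    if "#" not in header:
        return header, UNCLASSIFIED
    lib_id, te_class = header.split("#", 1)
    if not te_class:
        warnings.warn(f"library header {header!r} ends in '#'; class set to UNCLASSIFIED")
        return lib_id, UNCLASSIFIED
    return lib_id, te_class


def read_library(path, source_library: str = "", source_kind: str = "TE") -> list[LibrarySequence]:
    """Read a repeat-library FASTA, parsing '#'-suffixed classifications."""
    out = []
    for rec in read_fasta(path):
        lib_id, te_class = parse_classification(rec.description or rec.seq_id)
        lib_id = lib_id.split()[0]
        out.append(LibrarySequence(lib_id, rec.residues, source_library, te_class,
                                   source_kind=source_kind))
    return out


def filter_annotatable(
    repeats: list[RepeatInterval], min_len: int = DEFAULT_MIN_ANNOT_LEN
) -> list[RepeatInterval]:
    """Keep repeats strictly longer than min_len bp (default > 90 bp)."""
    return [r for r in repeats if r.length > min_len]


def align_to_library(
    repeat_seq: str, library: list[LibrarySequence], params: AlignParams | None = None
) -> list[LocalAlignment]:
    """Local alignments of a repeat sequence against every library entry.

    Both strands are searched; hits below the identity (default 0.70) or span
    (default 90 bp) floors are discarded. Results are sorted by descending
    score.
    """
    if not repeat_seq:
        raise ValueError("empty repeat sequence")
    params = params or AlignParams()
    hits: list[LocalAlignment] = []
    for entry in library:
        hits.extend(align_pair(repeat_seq, entry.residues, entry.lib_id, params))
    hits.sort(key=lambda h: (-h.score, -h.aligned_bp, h.target_id))
    return hits


def annotate_repeats(
    repeats: list[RepeatInterval],
    genomes: list[GenomeSequence],
    library: list[LibrarySequence],
    params: AlignParams | None = None,
    min_len: int = DEFAULT_MIN_ANNOT_LEN,
) -> list[RepeatAnnotation]:
    """Best-hit classification of every called repeat.

    Repeats not longer than min_len, and repeats with no qualifying hit, are
    returned UNANNOTATED so downstream fractions can use the full repeat
    space. Ties on score are broken by larger aligned span, then by
    lexicographically smallest library id, making the result independent of
    library order.
    """
    params = params or AlignParams()
    seqs = {g.seq_id: g.residues for g in genomes}
    by_class = {e.lib_id: e.te_class for e in library}
    out: list[RepeatAnnotation] = []
    for rep in repeats:
        iv = rep.interval
        if rep.length <= min_len:
            out.append(RepeatAnnotation(rep))
            continue
        repeat_seq = seqs[iv.seq_id][iv.start : iv.end]
        hits = align_to_library(repeat_seq, library, params)
        if not hits:
            out.append(RepeatAnnotation(rep))
            continue
        best = min(hits, key=lambda h: (-h.score, -h.aligned_bp, h.target_id))
        out.append(
            RepeatAnnotation(
                replace(rep, te_class=by_class[best.target_id]),
                best_target=best.target_id,
                te_class=by_class[best.target_id],
                identity=best.identity,
                aligned_bp=min(best.aligned_bp, rep.length),
            )
        )
    return out


def annotations_from_paf(
    repeats: list[RepeatInterval],
    paf_records: list[PafRecord],
    library: list[LibrarySequence],
    min_identity: float = 0.70,
    min_span: int = 90,
    min_len: int = DEFAULT_MIN_ANNOT_LEN,
) -> list[RepeatAnnotation]:
    """Classify repeats from externally produced PAF alignments.

    Query names must follow the ``seq_id:start-end`` convention used by the
    CLI when exporting repeat sequences. Best hit per repeat = most matching
    bases, ties broken as in annotate_repeats.
    """
    by_class = {e.lib_id: e.te_class for e in library}
    best: dict[str, PafRecord] = {}
    for rec in paf_records:
        span = rec.query_end - rec.query_start
        if rec.identity < min_identity or span < min_span:
            continue
        cur = best.get(rec.query_id)
        key = (-rec.matches, -(rec.query_end - rec.query_start), rec.target_id)
        if cur is None or key < (-cur.matches, -(cur.query_end - cur.query_start), cur.target_id):
            best[rec.query_id] = rec
    out = []
    for rep in repeats:
        iv = rep.interval
        name = f"{iv.seq_id}:{iv.start}-{iv.end}"
        hit = best.get(name)
        if rep.length <= min_len or hit is None:
            out.append(RepeatAnnotation(rep))
        else:
            out.append(
                RepeatAnnotation(
                    replace(rep, te_class=by_class.get(hit.target_id, UNCLASSIFIED)),
                    best_target=hit.target_id,
                    te_class=by_class.get(hit.target_id, UNCLASSIFIED),
                    identity=hit.identity,
                    aligned_bp=min(hit.query_end - hit.query_start, rep.length),
                )
            )
    return out


def annotated_fraction(
    annotations: list[RepeatAnnotation], genomes: list[GenomeSequence]
) -> tuple[float, float]:
    """(annotated bp / genome bp, annotated bp / total repeat bp).

    The repeat-space denominator includes both annotatable and short repeats,
    so the second ratio answers "how much of the called repeat space was
    classified".
    """
    genome_bp = sum(len(g) for g in genomes)
    repeat_bp = sum(a.repeat.length for a in annotations)
    annotated_bp = sum(a.repeat.length for a in annotations if a.te_class != UNANNOTATED)
    if repeat_bp == 0:
        warnings.warn("zero repeat bp; annotated fractions reported as 0")
        return 0.0, 0.0
    return annotated_bp / genome_bp, annotated_bp / repeat_bp
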