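"""K-mer-counting repeat detection and genome soft-masking.

The detector is the first step of the two-step protocol: count canonical
k-mers over the whole genome, score every position by the count of the word
starting there, and call maximal runs of repetitive positions as repeat
intervals. Counting is canonical (a word and its reverse complement share one
key) so inverted repeat copies are detected. The scoring scheme is a
transparent count threshold; the acceptance surface is planted-repeat
recovery, not equivalence with any particular published masker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import GenomeSequence, GenomicInterval, RepeatInterval

logger = logging.getLogger(__name__)

AUTO = "auto"

# 2-bit base codes; anything outside ACGT (case-insensitive) maps to 4 (invalid)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = "ACGT"


@dataclass(frozen=True)
class DetectorConfig:
    """Detector parameters.

    k may be an explicit word size (1..31) or AUTO, in which case
    k = floor(log4 genome_length) clamped to [k_min, k_max]. A k-mer seen at
    least count_threshold times genome-wide is repetitive. Runs closer than
    merge_dist bp are merged, and intervals shorter than min_repeat_len are
    dropped. merge_dist / min_repeat_len defaulting to None means
    "derive from k" (merge_dist = k, min_repeat_len = max(2k, 30)).
    """

    k: int | str = AUTO
    count_threshold: int = 3
    min_repeat_len: int | None = None
    merge_dist: int | None = None
    k_min: int = 13
    k_max: int = 16

    def __post_init__(self):
        if self.k != AUTO and not 1 <= int(self.k) <= 31:
            raise ValueError("explicit k must be in [1, 31]")
        if self.count_threshold < 2:
            raise ValueError("count_threshold must be >= 2")
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")

    def resolved(self, genome_length: int) -> "DetectorConfig":
        """Return a config with k, merge_dist and min_repeat_len made explicit."""
        k = select_k(genome_length, self)
        merge = self.merge_dist if self.merge_dist is not None else k
        min_len = self.min_repeat_len if self.min_repeat_len is not None else max(2 * k, 30)
        if min_len < k:
            raise ValueError("min_repeat_len must be >= k")
        return replace(self, k=k, merge_dist=merge, min_repeat_len=min_len)


class KmerTable:
    """Canonical k-mer counts stored as sorted packed codes + count vector."""

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        self.k = k
        self.codes = np.asarray(codes, dtype=np.uint64)
        self.counts = np.asarray(counts, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def total(self) -> int:
        """Total count mass = number of valid k-mer positions counted."""
        return int(self.counts.sum())

    def count_of(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        codes = _encode(kmer)
        if (codes == 4).any():
            return 0
        canon = _canonical_codes(codes, self.k)[0]
        i = np.searchsorted(self.codes, canon)
        if i < len(self.codes) and self.codes[i] == canon:
            return int(self.counts[i])
        return 0

    def lookup(self, canon: np.ndarray) -> np.ndarray:
        """Vectorised count lookup; unknown words get 0."""
        idx = np.searchsorted(self.codes, canon)
        idx = np.minimum(idx, len(self.codes) - 1) if len(self.codes) else idx
        out = np.zeros(len(canon), dtype=np.int64)
        if len(self.codes):
            hit = self.codes[idx] == canon
            out[hit] = self.counts[idx[hit]]
        return out

    def to_dict(self) -> dict[str, int]:
        return {
            _decode(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)
        }


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def _canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed canonical k-mer per start position, plus validity mask.

    A position is valid when its k-long window is N-free. Canonical = the
    numerically (equivalently lexicographically, since A<C<G<T map to 0<3)
    smaller of the forward word and its reverse complement.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    two = np.uint64(2)
    c = (codes & 3).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << two) | c[j : j + m]
        rev |= (np.uint64(3) - c[j : j + m]) << np.uint64(2 * j)
    bad = np.concatenate(([0], np.cumsum(codes == 4)))
    valid = (bad[k:] - bad[:-k]) == 0
    return np.minimum(fwd, rev), valid


def select_k(genome_length: int, config: DetectorConfig | None = None) -> int:
    """Word size: floor(log4 L) clamped to [k_min, k_max]; explicit k wins.

    The clamp range defaults to 13..16, the word sizes observed over genomes
    from ~0.1 to ~10 Gbp.
    """
    config = config or DetectorConfig()
    if config.k != AUTO:
        return int(config.k)
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    # integer search avoids float log rounding at exact powers of 4
    k = 0
    while 4 ** (k + 1) <= genome_length:
        k += 1
    return min(max(k, config.k_min), config.k_max)


def count_kmers(genomes: Iterable[GenomeSequence], k: int) -> KmerTable:
    """Count canonical k-mers over all N-free windows of all sequences."""
    if k < 1:
        raise ValueError("k must be >= 1")
    chunks = []
    for g in genomes:
        canon, valid = _canonical_codes(_encode(g.residues), k)
        chunks.append(canon[valid])
    if chunks:
        allc = np.concatenate(chunks)
    else:
        allc = np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(allc, return_counts=True)
    return KmerTable(k, codes, counts)


def score_positions(genome: GenomeSequence, table: KmerTable) -> np.ndarray:
    """Per-start-position canonical count vector; N-containing windows score 0."""
    canon, valid = _canonical_codes(_encode(genome.residues), table.k)
    scores = np.zeros(len(canon), dtype=np.int64)
    scores[valid] = table.lookup(canon[valid])
    return scores


def call_repeats(
    scores: np.ndarray,
    k: int,
    config: DetectorConfig,
    seq_id: str = "seq",
    seq_length: int | None = None,
) -> list[RepeatInterval]:
    """Turn a score vector into sorted, disjoint repeat intervals.

    Maximal runs of word-start positions with score >= count_threshold become
    intervals [run_start, run_end + k); runs whose intervals are separated by
    <= merge_dist bp are merged; merged intervals shorter than min_repeat_len
    are dropped. The interval score is the mean position score over the
    contributing run positions.
    """
    scores = np.asarray(scores)
    if seq_length is None:
        seq_length = len(scores) + k - 1 if len(scores) else 0
    merge_dist = config.merge_dist if config.merge_dist is not None else k
    min_len = config.min_repeat_len if config.min_repeat_len is not None else max(2 * k, 30)

    rep = scores >= config.count_threshold
    if not rep.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], rep, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # runs are [start, end) in word-start space

    merged: list[list[float]] = []  # [start, end(bp), score_sum, n_positions]
    for a, b in zip(starts, ends):
        iv_start, iv_end = int(a), min(int(b) - 1 + k, seq_length)
        s_sum = float(scores[a:b].sum())
        n_pos = int(b - a)
        if merged and iv_start - merged[-1][1] <= merge_dist:
            merged[-1][1] = max(merged[-1][1], iv_end)
            merged[-1][2] += s_sum
            merged[-1][3] += n_pos
        else:
            merged.append([iv_start, iv_end, s_sum, n_pos])

    return [
        RepeatInterval(GenomicInterval(seq_id, int(s), int(e)), score=ss / n)
        for s, e, ss, n in merged
        if e - s >= min_len
    ]


def detect_repeats(
    genomes: Sequence[GenomeSequence], config: DetectorConfig | None = None
) -> tuple[list[RepeatInterval], DetectorConfig]:
    """Full first-step pipeline: choose k, count, score, call per sequence.

    Returns the called repeats (sorted by sequence then start) and the
    resolved configuration actually used.
    """
    config = config or DetectorConfig()
    total_bp = sum(len(g) for g in genomes)
    cfg = config.resolved(total_bp)
    table = count_kmers(genomes, int(cfg.k))
    logger.info("k=%s, %d distinct canonical k-mers", cfg.k, len(table))
    repeats: list[RepeatInterval] = []
    for g in genomes:
        scores = score_positions(g, table)
        repeats.extend(call_repeats(scores, int(cfg.k), cfg, g.seq_id, len(g)))
    return repeats, cfg


def soft_mask(genome: GenomeSequence, intervals: Iterable[RepeatInterval]) -> GenomeSequence:
    """Lowercase the residues covered by the intervals; length is unchanged."""
    residues = bytearray(genome.residues, "ascii")
    for riv in intervals:
        iv = riv.interval
        if iv.seq_id != genome.seq_id:
            continue
        if iv.end > len(residues):
            raise ValueError(
                f"interval {iv.seq_id}:{iv.start}-{iv.end} exceeds sequence length "
                f"{len(residues)}"
            )
        residues[iv.start : iv.end] = residues[iv.start : iv.end].lower()
    return GenomeSequence(genome.seq_id, residues.decode("ascii"), genome.description)


def masked_fraction(
    genomes: Sequence[GenomeSequence], intervals: Sequence[RepeatInterval]
) -> float:
    """Total interval bp over total genome bp; intervals must be disjoint."""
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for riv in intervals:
        iv = riv.interval
        per_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    masked_bp = 0
    for seq_id, ivs in per_seq.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping intervals on {seq_id}: "
                    f"[{s1},{e1}) and [{s2},{e2}) — merge before computing fractions"
                )
        masked_bp += sum(e - s for s, e in ivs)
    total_bp = sum(len(g) for g in genomes)
    if total_bp == 0:
        raise ValueError("empty genome")
    return masked_bp / total_bp
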