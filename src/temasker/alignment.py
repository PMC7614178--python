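"""Internal seed-chain-extend local aligner.

Classification of called repeats and redundancy clustering both need fast
approximate local alignment at high identity (>= 70%). The aligner here
seeds with exact shared words (default length 11) on both strands, groups
seeds by diagonal, performs gapless X-drop extension of each diagonal run,
and finally chains runs on nearby diagonals so that occasional short indels
do not split an alignment. Identity is matches / aligned columns, where a
diagonal shift of g bases contributes g gap columns.

This is a deliberately transparent substitute for an external long-read
mapper; a PAF adapter lets users plug one in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import reverse_complement


@dataclass(frozen=True)
class AlignParams:
    seed_len: int = 11
    min_identity: float = 0.70
    min_span: int = 90
    xdrop: int = 12
    match_score: int = 1
    mismatch_score: int = -2
    chain_diag_band: int = 12   # max |diagonal shift| chained across
    chain_max_gap: int = 40     # max unaligned query gap chained across


@dataclass
class LocalAlignment:
    """A local alignment block (query/target spans are half-open)."""

    target_id: str
    strand: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_bp(self) -> int:
        return self.q_end - self.q_start

    @property
    def score(self) -> int:
        # matches minus mismatch/gap columns: a simple chain score
        return 2 * self.matches - self.columns


def _byte_view(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _seed_index(target: str, seed_len: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    t = target.upper()
    for i in range(len(t) - seed_len + 1):
        word = t[i : i + seed_len]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _extend_diagonal(
    q: np.ndarray, t: np.ndarray, diag: int, lo: int, hi: int, params: AlignParams
) -> tuple[int, int, int]:
    """Gapless X-drop extension of the query run [lo, hi) on one diagonal.

    Returns (q_start, q_end, matches) for the best-scoring extension.
    """
    def walk(rng) -> int:
        best, cur, best_pos, last = 0, 0, None, None
        for qi in rng:
            ti = qi - diag
            if ti < 0 or ti >= len(t) or qi < 0 or qi >= len(q):
                break
            cur += params.match_score if q[qi] == t[ti] else params.mismatch_score
            last = qi
            if cur > best:
                best, best_pos = cur, qi
            if cur < best - params.xdrop:
                break
        return best_pos

    right = walk(range(hi, len(q)))
    left = walk(range(lo - 1, -1, -1))
    q_start = left if left is not None else lo
    q_end = (right + 1) if right is not None else hi
    t_lo, t_hi = q_start - diag, q_end - diag
    matches = int(np.count_nonzero(q[q_start:q_end] == t[t_lo:t_hi]))
    return q_start, q_end, matches


def align_pair(
    query: str, target: str, target_id: str = "target", params: AlignParams | None = None,
    min_span: int | None = None, min_identity: float | None = None,
) -> list[LocalAlignment]:
    """All local alignments of query against target, both strands."""
    params = params or AlignParams()
    min_span = params.min_span if min_span is None else min_span
    min_identity = params.min_identity if min_identity is None else min_identity
    results: list[LocalAlignment] = []
    index = _seed_index(target, params.seed_len)
    tb = _byte_view(target)
    for strand, qseq in (("+", query), ("-", reverse_complement(query))):
        qup = qseq.upper()
        qb = _byte_view(qseq)
        # seeds grouped by diagonal
        diags: dict[int, list[int]] = {}
        for qi in range(len(qup) - params.seed_len + 1):
            for ti in index.get(qup[qi : qi + params.seed_len], ()):
                diags.setdefault(qi - ti, []).append(qi)
        blocks: list[LocalAlignment] = []
        for diag, qpos in diags.items():
            qpos.sort()
            # split seed positions on one diagonal into well-separated runs
            runs: list[tuple[int, int]] = []
            lo = hi = qpos[0]
            for qi in qpos[1:]:
                if qi - hi <= params.chain_max_gap + params.seed_len:
                    hi = qi
                else:
                    runs.append((lo, hi + params.seed_len))
                    lo = hi = qi
            runs.append((lo, hi + params.seed_len))
            for lo, hi in runs:
                qs, qe, m = _extend_diagonal(qb, tb, diag, lo, hi, params)
                if qe > qs:
                    blocks.append(
                        LocalAlignment(target_id, strand, qs, qe, qs - diag, qe - diag,
                                       m, qe - qs)
                    )
        blocks = _chain_blocks(blocks, params)
        for b in blocks:
            if b.aligned_bp >= min_span and b.identity >= min_identity:
                if strand == "-":
                    # report query span in forward-query coordinates
                    n = len(query)
                    b = LocalAlignment(
                        b.target_id, "-", n - b.q_end, n - b.q_start,
                        b.t_start, b.t_end, b.matches, b.columns,
                    )
                results.append(b)
    results.sort(key=lambda b: (-b.score, -b.aligned_bp, b.t_start))
    return results


def _chain_blocks(blocks: list[LocalAlignment], params: AlignParams) -> list[LocalAlignment]:
    """Greedy chaining of collinear blocks across nearby diagonals."""
    if len(blocks) <= 1:
        return blocks
    blocks.sort(key=lambda b: (b.q_start, b.t_start))
    chained: list[LocalAlignment] = []
    cur = blocks[0]
    for nxt in blocks[1:]:
        gap_q = nxt.q_start - cur.q_end
        gap_t = nxt.t_start - cur.t_end
        dshift = abs((nxt.q_start - nxt.t_start) - (cur.q_start - cur.t_start))
        if (
            -params.seed_len <= gap_q <= params.chain_max_gap
            and -params.seed_len <= gap_t <= params.chain_max_gap
            and dshift <= params.chain_diag_band
            and nxt.q_end > cur.q_end
            and nxt.t_end > cur.t_end
        ):
            overlap = max(0, -min(gap_q, gap_t))
            extra_cols = max(gap_q, gap_t, 0) + max(nxt.columns - overlap, 0)
            # approximate: matches in the overlap region are counted once
            extra_matches = max(nxt.matches - overlap, 0)
            cur = LocalAlignment(
                cur.target_id, cur.strand, cur.q_start, nxt.q_end,
                cur.t_start, nxt.t_end, cur.matches + extra_matches,
                cur.columns + extra_cols,
            )
        else:
            chained.append(cur)
            cur = nxt
    chained.append(cur)
    return chained
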