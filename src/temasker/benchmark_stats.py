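"""Statistics for evaluating a masking strategy.

How much of the gene, exon, flanking and NLR space does a set of repeat
calls cover; is NLR (disease-resistance) space masked more densely than the
genome at large (an odds ratio); and are particular protein domains enriched
among genes overlapping repeats (Fisher exact tests with Benjamini-Hochberg
correction over domains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kmer_detector import count_kmers
from .sequence_io import GeneFeature, GenomeSequence, GenomicInterval, RepeatInterval


@dataclass(frozen=True)
class NLRMaskingStats:
    """The four space measures (bp) of the NLR-masking odds ratio."""

    nlr_masked: int
    gen_masked: int
    nlr: int
    gen: int

    @property
    def odds_ratio(self) -> float:
        return (self.nlr_masked / self.gen_masked) / (self.nlr / self.gen)


@dataclass
class EnrichmentResult:
    """Per-domain 2x2 Fisher test of overlap-gene enrichment.

    a = foreground genes with the domain, b = background-only genes with it,
    c = foreground genes without it, d = background-only genes without it.
    """

    domain: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    fdr: float = 1.0
    enriched: bool = False


def _merged_starts_ends(intervals: Iterable[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _overlap_with_merged(iv: GenomicInterval, starts: np.ndarray, ends: np.ndarray) -> int:
    if len(starts) == 0:
        return 0
    lo = int(np.searchsorted(ends, iv.start, side="right"))
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if hi <= lo:
        return 0
    return int(
        np.sum(np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start))
    )


def _check_sorted(intervals: Sequence[GenomicInterval], what: str) -> None:
    last: dict[str, int] = {}
    for iv in intervals:
        if iv.start < last.get(iv.seq_id, -1):
            raise ValueError(f"{what} are not sorted by start within {iv.seq_id}")
        last[iv.seq_id] = iv.start


def intersect_overlap(
    features: Sequence[GenomicInterval],
    repeats: Sequence[RepeatInterval],
    min_overlap: int = 1,
) -> tuple[list[int], float]:
    """Per-feature repeat overlap (bp) and the overlapped fraction of feature space.

    Overlap is the union of a feature's intersections with the (merged)
    repeat intervals; features below min_overlap report 0. Inputs must be
    sorted by start within each sequence.
    """
    _check_sorted(features, "features")
    _check_sorted([r.interval for r in repeats], "repeats")
    by_seq: dict[str, list[GenomicInterval]] = {}
    for r in repeats:
        by_seq.setdefault(r.interval.seq_id, []).append(r.interval)
    merged = {sid: _merged_starts_ends(ivs) for sid, ivs in by_seq.items()}
    overlaps: list[int] = []
    for feat in features:
        starts, ends = merged.get(feat.seq_id, (np.empty(0), np.empty(0)))
        ov = _overlap_with_merged(feat, starts, ends)
        overlaps.append(ov if ov >= min_overlap else 0)
    feat_bp = sum(f.length for f in features)
    frac = sum(overlaps) / feat_bp if feat_bp else 0.0
    return overlaps, frac


def flanking_windows(
    genes: Sequence[GeneFeature],
    size: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Strand-aware upstream/downstream windows with neighbor-gene subtraction.

    Upstream of a '-' gene lies to its right. Windows are clipped at
    chromosome bounds, any bp covered by ANY gene interval is removed (to
    exclude coding sequence of neighbors), and empty windows are dropped.
    """
    chrom_lengths = chrom_lengths or {}
    gene_ivs_by_seq: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        gene_ivs_by_seq.setdefault(g.gene_interval.seq_id, []).append(g.gene_interval)
    merged = {sid: _merged_starts_ends(ivs) for sid, ivs in gene_ivs_by_seq.items()}

    def subtract(seq_id: str, lo: int, hi: int) -> list[GenomicInterval]:
        lo = max(lo, 0)
        if seq_id in chrom_lengths:
            hi = min(hi, chrom_lengths[seq_id])
        if hi <= lo:
            return []
        starts, ends = merged[seq_id]
        pieces: list[GenomicInterval] = []
        cur = lo
        i = int(np.searchsorted(ends, lo, side="right"))
        while i < len(starts) and starts[i] < hi:
            if starts[i] > cur:
                pieces.append(GenomicInterval(seq_id, cur, int(starts[i])))
            cur = max(cur, int(ends[i]))
            i += 1
        if cur < hi:
            pieces.append(GenomicInterval(seq_id, cur, hi))
        return pieces

    upstream: list[GenomicInterval] = []
    downstream: list[GenomicInterval] = []
    for g in genes:
        iv = g.gene_interval
        left = (iv.start - size, iv.start)
        right = (iv.end, iv.end + size)
        if g.strand == "-":
            up_rng, down_rng = right, left
        else:
            up_rng, down_rng = left, right
        upstream.extend(subtract(iv.seq_id, *up_rng))
        downstream.extend(subtract(iv.seq_id, *down_rng))
    return upstream, downstream


def nlr_masking_odds_ratio(
    nlr_loci: Sequence[GenomicInterval],
    repeats: Sequence[RepeatInterval],
    genomes: Sequence[GenomeSequence],
    min_overlap: int = 50,
) -> NLRMaskingStats:
    """Odds ratio of NLR masking: masked density in NLR space vs genome-wide.

    OR = (NLRmasked / Genmasked) / (NLR / Gen). Loci overlapping repeats by
    no more than min_overlap bp (default: strictly more than 50 bp required)
    contribute nothing to the masked NLR space.
    """
    overlaps, _ = intersect_overlap(sorted(nlr_loci), sorted(repeats, key=lambda r: (r.interval.seq_id, r.interval.start)))
    nlr_masked = sum(ov for ov in overlaps if ov > min_overlap)
    by_seq: dict[str, list[GenomicInterval]] = {}
    for r in repeats:
        by_seq.setdefault(r.interval.seq_id, []).append(r.interval)
    gen_masked = sum(
        int(np.sum(e - s))
        for s, e in (_merged_starts_ends(ivs) for ivs in by_seq.values())
    )
    nlr_bp = sum(iv.length for iv in nlr_loci)
    gen_bp = sum(len(g) for g in genomes)
    if gen_masked == 0:
        raise ValueError("odds ratio undefined: no masked genome space")
    if nlr_bp == 0:
        raise ValueError("odds ratio undefined: no NLR space")
    return NLRMaskingStats(nlr_masked, gen_masked, nlr_bp, gen_bp)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's.
    Degenerate margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        warnings.warn("all-zero 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def domain_enrichment(
    gene_overlaps: Mapping[str, int],
    gene_domain_table: Mapping[str, Iterable[str]],
    min_overlap: int = 50,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Domain enrichment among genes overlapping repeats.

    Foreground = genes whose repeat overlap is strictly greater than
    min_overlap bp; background = all other genes in the domain table (the
    whole-proteome expectation). Each domain is tested gene-level
    (presence/absence) with a two-sided Fisher exact test; BH-FDR is applied
    across all tested domains and only enrichment (odds ratio > 1) at
    fdr < alpha is flagged.
    """
    genes = sorted(gene_domain_table)
    fg = {g for g in genes if gene_overlaps.get(g, 0) > min_overlap}
    if not fg:
        warnings.warn("no foreground genes exceed the overlap threshold")
        return []
    bg = [g for g in genes if g not in fg]
    domains = sorted({d for ds in gene_domain_table.values() for d in ds})
    results: list[EnrichmentResult] = []
    for dom in domains:
        with_dom = {g for g in genes if dom in set(gene_domain_table[g])}
        a = len(fg & with_dom)
        b = sum(1 for g in bg if g in with_dom)
        c = len(fg) - a
        d = len(bg) - b
        if (c == 0 and d == 0) or (a == 0 and b == 0):
            odds = 1.0  # domain in every gene, or in none: no association
        elif b * c == 0:
            odds = float("inf") if a * d else 0.0
        else:
            odds = (a * d) / (b * c)
        results.append(EnrichmentResult(dom, a, b, c, d, odds, fisher_exact_2x2(a, b, c, d)))
    fdrs = bh_fdr([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
        r.enriched = bool(f < alpha and r.odds_ratio > 1)
    return results


def kmer_census(
    sequences: Sequence[str], k: int, min_count: int = 20
) -> tuple[int, "KmerTable"]:
    """Number of canonical k-mers occurring at least min_count times.

    Mirrors a jellyfish count/dump -L workflow over extracted repeat
    sequences (typical k: 16, 21, 31). Returns the census and the table.
    """
    from .kmer_detector import KmerTable  # noqa: F401  (type for docstring/return)
    from .sequence_io import GenomeSequence

    table = count_kmers(
        [GenomeSequence(f"s{i}", s) for i, s in enumerate(sequences)], k
    )
    census = int(np.count_nonzero(table.counts >= min_count))
    return census, table
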