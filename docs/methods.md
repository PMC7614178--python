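# Methods

`temasker` implements a two-step protocol for annotating repetitive sequence
in plant-sized genomes — call repeats by k-mer counting, then classify the
called intervals against a curated transposable-element (TE) library — plus
the procedure for curating such a library from heterogeneous collections and
the statistics used to judge what a masking strategy covers.

## Repeat detection by k-mer counting

The detector builds a genome-wide table of canonical k-mer counts (canonical
= the lexicographically smaller of a word and its reverse complement, so both
strands and inverted copies share one key). Every position is scored by the
count of the word starting there; windows containing N score 0. Maximal runs
of positions with score ≥ `count_threshold` become intervals extended by the
full last word, runs separated by ≤ `merge_dist` bp are merged, and intervals
shorter than `min_repeat_len` bp are discarded. The interval score is the
mean position score over its run.

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `k` | auto = ⌊log₄ L⌋ clamped to [13, 16] | word size; with this choice a random unique k-mer has expected genome count of order 1, so repeated words stand out. The clamp covers genomes from ~0.1 to ~10 Gbp; the CLI accepts small explicit k for toy inputs. |
| `count_threshold` | 3 | minimum genome-wide count for a repetitive word; at k ≈ log₄ L the background count is 1–4, so 3 separates interspersed repeat families (tens of copies) from chance doubles. |
| `merge_dist` | k | a single substitution inside a repeat copy invalidates up to k word starts, creating gaps of ≤ k bp between runs; merging at k bridges isolated mutations without joining distinct copies across unique sequence. |
| `min_repeat_len` | max(2k, 30) | drops calls supported by fewer than ~k repetitive word starts. |

The detector is a transparent count-threshold caller; it does not reproduce
the smoothing/HMM internals of any particular published k-mer masker, and it
is validated by planted-repeat recovery (base-level recall/precision against
simulation truth), not by bitwise agreement with an external tool. Low
complexity and tandem-repeat calling (dust/trf-style) are out of scope.

Counting packs words into 64-bit integers (k ≤ 31) and uses vectorised
numpy throughout; a 1 Mbp genome masks in about a second on one CPU.
Soft-masking lowercases the called residues and never changes lengths.

## Repeat classification

Repeats strictly longer than 90 bp are extracted and aligned to the library.
Classification terms are parsed from library FASTA headers after the first
`#` (e.g. `RLG_43695:mipsREdat_9.3p_ALL#LTR/Gypsy`); headers without a hash
are UNCLASSIFIED. Each repeat takes the class of its best hit — maximal
alignment score, ties broken by larger aligned span, then lexicographically
smallest library id — which makes annotation deterministic and invariant to
library order. Repeats spanning two families still receive a single best-hit
class; per-base mosaic annotation is deliberately not attempted.

The internal aligner seeds with exact shared 11-mers on both strands, groups
seeds by diagonal, extends each run gaplessly with an X-drop criterion
(match +1, mismatch −2, drop 12), and chains blocks across nearby diagonals
(shift ≤ 12, gap ≤ 40 bp) so occasional 1-bp indels do not split alignments.
Identity = matches / aligned columns, with diagonal shifts counted as gap
columns. Hits need identity ≥ 0.70 and span ≥ 90 bp. On substitution-diverged
pairs ≤ 300 bp the identity agrees with a Smith–Waterman oracle within 0.03
(tested); at divergence well above ~15% the seed density collapses and hits
are missed, which matches the intended operating range (library entries are
≥ 85% similar to the copies they annotate, or they should not classify them).
A PAF adapter accepts alignments from an external long-read mapper for users
who prefer the original tooling; published comparisons show the choice of
aligner moves annotated fractions only slightly.

## Library curation

Sources (TE collections and transcript sets) are merged with inclusive
length bounds 90–55,000 bp and tag-prefixed ids. Pairs are connected when
identity ≥ 95% and coverage of the shorter sequence ≥ 75%, where coverage is
the union of local alignment blocks projected on the shorter sequence and
identity is matches over aligned columns across those blocks. Clusters are
the connected components of this graph. Components are used instead of a
Markov-clustering step: at 95%/75% stringency the graph is already close to
transitively closed, components are parameter-free and deterministic, and a
different partitioner can be plugged in where the component step sits. A
shared-15-mer prefilter skips pairs that cannot reach 95% identity; the
resulting partition is independent of input order (tested by permutation).

The longest member of each cluster is its representative (ties:
lexicographically smallest id). TE-only clusters are kept; transcript-only
clusters are dropped; mixed clusters survive only with members from at least
6 distinct TE collections and a potential-host-gene fraction of exactly zero
("below 0.00" is read as 0.00 after rounding — a fraction strictly below
zero is impossible).

The benchmark translates library sequences in six frames and asks which
control Pfam domains are found: TP/FN over a positive list of TE-associated
domains, TN/FP over a negative list of disease-resistance (R/NLR) gene
domains. Sensitivity and specificity are reported at two decimals. Domain
finding itself is consumed from an external HMM-search table (domtblout
dialect, accession versions stripped); a literal-peptide motif scanner is
provided so the benchmark path runs without external tools on fixtures. The
two control lists may overlap (zf-BED-like domains occur in both transposases
and R genes); overlap is reported with a warning rather than silently
resolved, since such domains legitimately count on both sides.

## Masking-strategy statistics

Interval work is half-open bp arithmetic throughout. Per-feature repeat
overlap is the union of intersections with merged repeat intervals
(equivalent to a per-base set intersection; tested against that oracle).
Flanking windows (default 500 bp) are strand-aware — upstream of a minus
gene lies to its right — clipped at chromosome ends, and any bp belonging to
any gene is subtracted so neighbor coding sequence never counts as flank.

The NLR masking odds ratio is

    OR = (NLRmasked / Genmasked) / (NLR / Gen)

with all four quantities in bp ("space" is read as base pairs, not locus
counts); NLR loci must overlap repeats by strictly more than 50 bp to
contribute to NLRmasked. OR = 1 means NLR space is masked at genome-average
density; OR > 1 means immune-receptor loci are preferentially masked — the
failure mode homology libraries are prone to. Whether masking is
significantly *depleted* in NLR space is not tested; only enrichment is
flagged, mirroring how the statistic is used.

Domain enrichment among repeat-overlapping genes uses gene-level
presence/absence: foreground = genes with > 50 bp repeat overlap, background
= the rest of the proteome; each domain gets a two-sided Fisher exact test
(scipy, minimum-likelihood two-sided convention, matching the R `fisher.test`
default) and Benjamini–Hochberg FDR across all tested domains; only odds
ratio > 1 at FDR < 0.05 is flagged. A domain present in every gene is
reported with odds ratio 1 (no association). The k-mer census (canonical
k-mers with ≥ 20 copies, k ∈ {16, 21, 31}) reuses the detector's counting
and mirrors a jellyfish count/dump workflow.

## Synthetic data generator

`synthetic_fixtures.simulate_genome` emulates the repeat structure the
protocol assumes: an i.i.d. background at a set GC content carrying
interspersed, non-overlapping copies of a few TE family consensus sequences,
each copy independently substituted (and optionally hit by single-bp indels)
and inserted on a random strand; a gene annotation in which a configurable
subset of genes overlaps repeat copies and carries a TE-associated domain
accession (creating a detectable enrichment signal); NLR-like loci placed in
repeat-free background (so a k-mer masker should yield OR < 1); and the
truth library with `famN#Class` headers. Defaults — 1 Mbp, 5 families × 20
copies of 300–3,000 bp, 2% substitutions, no indels, 40% GC, 200 genes of
which 20 overlap repeats, 10 NLR loci, seed 42 — define the study conditions
used by the tests and the acceptance script; identical seeds give
byte-identical outputs.

What the simulation does **not** model: nested insertions, solo-LTR
formation, target-site duplications, realistic TE age/divergence
distributions, satellite and low-complexity repeats, and GC heterogeneity.
Passing the planted-recovery tests therefore demonstrates that the detector
recovers interspersed, moderately diverged repeat families on a neutral
background; it does not bound performance on tandem arrays, highly diverged
relics, or compositionally biased genomes.

## Numerical and edge-case conventions

- All interval containers reject `start >= end`; zero-length features cannot
  exist, and empty BED files round-trip to empty lists.
- `masked_fraction` refuses overlapping intervals rather than silently
  double-counting; callers merge first.
- Empty repeat space reports annotated fractions of 0 with a warning; empty
  called sets report precision 1 by convention (no called base is wrong) with
  recall 0.
- Degenerate 2×2 margins give Fisher p = 1; an all-zero table additionally
  warns.
- BED scores are written with `repr` so float scores round-trip exactly.
- Problem sizes in the test and acceptance runs (1 Mbp default genome,
  200 kb annotation fixtures, ≤ 50-sequence clustering oracles) were chosen
  so every oracle can be brute-forced and the whole pipeline re-runs from
  scratch in seconds.
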