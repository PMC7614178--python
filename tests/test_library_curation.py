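import itertools

import numpy as np
import pytest
from Bio import Align

from temasker.library_curation import (
    Cluster,
    ClusteringParams,
    LibrarySource,
    build_library,
    cluster_sequences,
    evaluate_controls,
    filter_clusters,
    merge_libraries,
    pairwise_similarity,
    pick_representative,
    read_domain_hits,
    scan_motifs,
    six_frame_translate,
)
from temasker.repeat_annotator import LibrarySequence

from conftest import mutate_subs, random_dna


def write_fasta_text(path, entries):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))


def sw_similarity(a: str, b: str) -> tuple[float, float]:
    """Oracle (identity %, coverage % of shorter) from one best local alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    best = None
    for s2 in (longer, _revcomp(longer)):
        aln = aligner.align(shorter, s2)[0]
        if best is None or aln.score > best.score:
            best = aln
    matches = sum(
        1 for x, y in zip(str(best[0]), str(best[1])) if x == y and x != "-"
    )
    q_cov = best.aligned[0][-1][1] - best.aligned[0][0][0]
    return 100 * matches / best.length, 100 * q_cov / len(shorter)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestMergeLibraries:
    def test_inclusive_length_bounds(self, tmp_path):
        p = tmp_path / "lib.fa"
        write_fasta_text(
            p,
            [
                ("too_short#X", "A" * 89),
                ("at_min#X", "A" * 90),
                ("at_max#X", "C" * 55_000),
                ("too_long#X", "C" * 55_001),
            ],
        )
        merged = merge_libraries([LibrarySource(str(p), "t1")])
        assert {e.lib_id for e in merged} == {"t1:at_min", "t1:at_max"}

    def test_two_sources_tagged(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta_text(p1, [(f"s{i}#LTR/Gypsy", "ACGT" * 50) for i in range(3)])
        write_fasta_text(p2, [(f"s{i}", "TTAA" * 50) for i in range(2)])
        merged = merge_libraries(
            [LibrarySource(str(p1), "A"), LibrarySource(str(p2), "B", "transcript")]
        )
        assert len(merged) == 5
        assert {e.source_library for e in merged} == {"A", "B"}
        assert all(e.lib_id.startswith(("A:", "B:")) for e in merged)

    def test_tag_collision_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        write_fasta_text(p, [("s1", "ACGT" * 50)])
        with pytest.raises(ValueError, match="duplicate"):
            merge_libraries([LibrarySource(str(p), "X"), LibrarySource(str(p), "X")])

    def test_host_gene_flags_read(self, tmp_path):
        p = tmp_path / "a.fa"
        write_fasta_text(p, [("s1", "ACGT" * 50), ("s2", "TTGG" * 50)])
        flags = tmp_path / "host.list"
        flags.write_text("s2\n")
        merged = merge_libraries([LibrarySource(str(p), "A", "TE", str(flags))])
        by_id = {e.lib_id: e for e in merged}
        assert not by_id["A:s1"].host_gene_flag
        assert by_id["A:s2"].host_gene_flag


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(20)
        s = random_dna(rng, 200)
        a, b = LibrarySequence("a", s), LibrarySequence("b", s)
        assert pairwise_similarity(a, b) == (100.0, 100.0)

    def test_substring_covers_shorter_fully(self):
        rng = np.random.default_rng(21)
        long = random_dna(rng, 200)
        a = LibrarySequence("a", long)
        b = LibrarySequence("b", long[25:175])
        ident, cov = pairwise_similarity(a, b)
        assert ident == 100.0
        assert cov == 100.0

    def test_ten_substitutions_vs_oracle(self):
        rng = np.random.default_rng(22)
        s = random_dna(rng, 200)
        m = mutate_subs(rng, s, 10, margin=5)
        ident, cov = pairwise_similarity(LibrarySequence("a", s), LibrarySequence("b", m))
        assert abs(ident - 95.0) <= 0.5
        o_ident, o_cov = sw_similarity(s, m)
        assert abs(ident - o_ident) <= 1.0
        assert cov >= o_cov - 2.0


def make_family_fixture(seed=23, n_families=5, copies=4, rate=0.02):
    rng = np.random.default_rng(seed)
    seqs = []
    for f in range(n_families):
        cons = random_dna(rng, int(rng.integers(500, 1500)))
        for c in range(copies):
            n_subs = int(round(rate * len(cons)))
            seqs.append(
                LibrarySequence(
                    f"f{f}c{c}", mutate_subs(rng, cons, n_subs, margin=3),
                    source_library=f"lib{c}",
                )
            )
    return seqs


def brute_force_components(seqs, params):
    """Oracle: all-pairs SW graph -> connected components (union-find)."""
    parent = {s.lib_id: s.lib_id for s in seqs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(seqs, 2):
        ident, cov = sw_similarity(a.residues, b.residues)
        if ident >= params.min_identity and cov >= params.min_coverage:
            parent[find(a.lib_id)] = find(b.lib_id)
    groups = {}
    for s in seqs:
        groups.setdefault(find(s.lib_id), set()).add(s.lib_id)
    return sorted(groups.values(), key=min)


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        seqs = [LibrarySequence(f"s{i}", "ACGTTGCA" * 40) for i in range(3)]
        clusters = cluster_sequences(seqs)
        assert len(clusters) == 1
        assert clusters[0].member_ids == {"s0", "s1", "s2"}

    def test_ninety_percent_identity_stays_apart(self):
        rng = np.random.default_rng(24)
        s = random_dna(rng, 500)
        m = mutate_subs(rng, s, 50, margin=3)  # 10% divergence
        clusters = cluster_sequences(
            [LibrarySequence("a", s), LibrarySequence("b", m)]
        )
        assert len(clusters) == 2

    def test_five_families_give_five_clusters_matching_oracle(self):
        seqs = make_family_fixture()
        params = ClusteringParams()
        clusters = cluster_sequences(seqs, params)
        assert len(clusters) == 5
        partition = sorted((c.member_ids for c in clusters), key=min)
        assert partition == brute_force_components(seqs, params)

    def test_input_permutation_invariance(self):
        seqs = make_family_fixture(seed=25, n_families=3)
        fwd = cluster_sequences(seqs)
        rev = cluster_sequences(seqs[::-1])
        assert [c.member_ids for c in fwd] == [c.member_ids for c in rev]
        assert [c.representative for c in fwd] == [c.representative for c in rev]


class TestRepresentative:
    def test_longest_wins(self):
        seqs = [
            LibrarySequence("x", "A" * 100),
            LibrarySequence("y", "A" * 300),
            LibrarySequence("z", "A" * 200),
        ]
        assert pick_representative({"x", "y", "z"}, seqs) == "y"

    def test_singleton(self):
        seqs = [LibrarySequence("only", "ACGT" * 30)]
        assert pick_representative({"only"}, seqs) == "only"

    def test_length_tie_lexicographic(self):
        seqs = [LibrarySequence("z", "A" * 100), LibrarySequence("a", "C" * 100)]
        assert pick_representative({"z", "a"}, seqs) == "a"


class TestFilterClusters:
    def mixed(self, n_libs, host_frac):
        return Cluster(
            member_ids={f"m{i}" for i in range(8)},
            te_libraries_present={f"lib{i}" for i in range(n_libs)},
            has_transcripts=True,
            host_gene_fraction=host_frac,
            representative="m0",
        )

    def test_mixed_cluster_boundaries(self):
        assert filter_clusters([self.mixed(6, 0.0)]) == [self.mixed(6, 0.0)]
        assert filter_clusters([self.mixed(5, 0.0)]) == []
        assert filter_clusters([self.mixed(6, 0.1)]) == []

    def test_te_only_kept_transcript_only_dropped(self):
        te_only = Cluster({"a"}, {"lib1"}, False, 0.0, "a")
        tx_only = Cluster({"b"}, set(), True, 0.0, "b")
        assert filter_clusters([te_only, tx_only]) == [te_only]

    def test_monotone_in_min_libraries(self):
        clusters = [self.mixed(n, 0.0) for n in range(1, 9)]
        kept_by_cutoff = [set(
            frozenset(c.te_libraries_present) for c in filter_clusters(clusters, min_libraries=m)
        ) for m in range(1, 9)]
        for lo, hi in zip(kept_by_cutoff, kept_by_cutoff[1:]):
            assert hi <= lo


class TestSixFrameTranslate:
    def test_forward_frame_with_stop(self):
        frames = six_frame_translate("ATGAAATAG")
        assert frames[0] == "MK*"

    def test_reverse_frame(self):
        assert six_frame_translate("TTA")[3] == "*"  # revcomp TAA

    def test_too_short_gives_six_empty(self):
        assert six_frame_translate("AC") == [""] * 6

    def test_frame_length_closed_form(self):
        rng = np.random.default_rng(26)
        for L in (3, 7, 10, 23, 60):
            seq = random_dna(rng, L)
            frames = six_frame_translate(seq)
            assert len(frames) == 6
            for f in range(3):
                expected = (L - f) // 3
                assert len(frames[f]) == expected
                assert len(frames[3 + f]) == expected


class TestEvaluateControls:
    def test_reported_confusion_counts(self):
        """The control benchmark arithmetic on the reported counts."""
        pos = [f"PFP{i:04d}" for i in range(22)]
        neg = [f"PFN{i:04d}" for i in range(38)]
        found = set(pos[:20]) | set(neg[:2])
        cm = evaluate_controls(found, pos, neg)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (20, 2, 36, 2)
        assert cm.rounded() == (0.91, 0.95)

    def test_perfect_classification(self):
        pos, neg = ["P1", "P2"], ["N1", "N2"]
        cm = evaluate_controls({"P1", "P2"}, pos, neg)
        assert cm.rounded() == (1.00, 1.00)

    def test_totals_invariant(self):
        rng = np.random.default_rng(27)
        pos = [f"P{i}" for i in range(15)]
        neg = [f"N{i}" for i in range(20)]
        found = {x for x in pos + neg if rng.random() < 0.4}
        cm = evaluate_controls(found, pos, neg)
        assert cm.tp + cm.fn == len(pos)
        assert cm.tn + cm.fp == len(neg)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate_controls(set(), [], ["N1"])

    def test_overlapping_lists_warn(self):
        with pytest.warns(UserWarning, match="both control lists"):
            evaluate_controls({"X"}, ["X", "P"], ["X", "N"])

    def test_motif_scan_fixture(self):
        """A planted transposase motif is found (TP); a planted kinase motif in
        the library is also found (FP)."""
        # codons spelling literal peptides in frame +1
        transposase = "ATG" + "GGTGTTCAACGTACTCGT" * 3  # GVQRTR...
        kinase = "ATG" + "CACCGTGACTTAAAACCT" * 3       # HRDLKP...
        seqs = [
            LibrarySequence("te1", transposase + "ACGT" * 20),
            LibrarySequence("host1", kinase + "TGCA" * 20),
        ]
        motifs = {"PFTRANS": "GVQRTRGVQRTR", "PFKIN": "HRDLKPHRDLKP"}
        found = {acc for _, acc in scan_motifs(seqs, motifs)}
        cm = evaluate_controls(found, ["PFTRANS"], ["PFKIN"])
        assert (cm.tp, cm.fp) == (1, 1)


class TestReadDomainHits:
    def test_version_suffix_stripped(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text(
            "# comment\n"
            "zf-BED  PF02892.12  60  seqA  100  1e-10\n"
        )
        assert read_domain_hits(p) == {("seqA", "PF02892")}

    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text("# a\n# b\n")
        assert read_domain_hits(p) == set()

    def test_five_hits(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        lines = [
            f"dom{i}\tPF{i:05d}.{i}\t50\tseq{i}\t10\t1e-5\n" for i in range(5)
        ]
        p.write_text("#h\n" + "".join(lines))
        hits = read_domain_hits(p)
        assert hits == {(f"seq{i}", f"PF{i:05d}") for i in range(5)}

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text("domA PF00001.1 50 seqA\nbroken line\n")
        with pytest.raises(ValueError, match="line 2"):
            read_domain_hits(p)


class TestEndToEndCuration:
    def test_five_families_two_host_genes_seven_sources(self, tmp_path):
        """Curation keeps all 5 family representatives and drops the host
        genes that contaminate a minority of TE collections."""
        rng = np.random.default_rng(28)
        families = [random_dna(rng, int(rng.integers(500, 1200))) for _ in range(5)]
        host_genes = [random_dna(rng, 800) for _ in range(2)]
        te_tags = [f"lib{i}" for i in range(6)]
        sources = []
        for t, tag in enumerate(te_tags):
            entries = []
            for f, cons in enumerate(families):
                n = int(round(0.01 * len(cons)))
                entries.append((f"fam{f}_{tag}#LTR/Gypsy", mutate_subs(rng, cons, n, 3)))
            host_ids = []
            if t < 3:  # host genes contaminate only 3 of 6 TE collections
                for h, hg in enumerate(host_genes):
                    entries.append((f"host{h}_{tag}#DNA/Unknown", hg))
                    host_ids.append(f"host{h}_{tag}")
            p = tmp_path / f"{tag}.fa"
            write_fasta_text(p, entries)
            flag_path = None
            if host_ids and t == 0:  # one collection annotates potential host genes
                flag_path = tmp_path / f"{tag}.host.list"
                flag_path.write_text("".join(f"{i}\n" for i in host_ids))
            sources.append(LibrarySource(str(p), tag, "TE",
                                         str(flag_path) if flag_path else None))
        # transcript source: the host genes plus unrelated transcripts
        tx_entries = [(f"tx_host{h}", hg) for h, hg in enumerate(host_genes)]
        tx_entries += [(f"tx{i}", random_dna(rng, 600)) for i in range(3)]
        ptx = tmp_path / "cdna.fa"
        write_fasta_text(ptx, tx_entries)
        sources.append(LibrarySource(str(ptx), "cdna", "transcript"))

        seqs = merge_libraries(sources)
        clusters = cluster_sequences(seqs)
        kept = filter_clusters(clusters, min_libraries=6, max_host_fraction=0.0)
        library = build_library(kept, seqs)
        # exactly the 5 family representatives survive
        assert len(library) == 5
        fams = {e.lib_id.split(":")[1].split("_")[0] for e in library}
        assert fams == {f"fam{f}" for f in range(5)}
        assert not any("host" in e.lib_id for e in library)
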