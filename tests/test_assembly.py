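"""String graph: filters with bitmap oracles, transitive reduction vs
brute force, pruning, cleaning, and contig splicing."""

import numpy as np
import pytest

from lorcas import _align, assembly as asm
from lorcas.assembly import (
    Contig,
    OverlapRecord,
    StringGraph,
    adaptive_overlap_filter,
    best_edge_prune,
    build_string_graph,
    clean_graph,
    coverage_filter,
    coverage_stats,
    extract_contigs,
    transitive_reduction,
)
from lorcas.io_core import RawRead


def _ovl(a, b, a_iv, b_iv, a_len, b_len, identity=0.99, strand="+"):
    return OverlapRecord(a, b, strand, a_iv, b_iv, a_len, b_len, identity,
                         a_iv[1] - a_iv[0])


class TestCoverageFilter:
    def test_uncovered_tip_removed(self):
        reads = [RawRead("a", "A" * 3000), RawRead("b", "A" * 3000)]
        # only half of read a covered -> interior c_min = 0
        ovl = [_ovl("a", "b", (0, 1500), (1500, 3000), 3000, 3000)]
        kept, kept_ovl = coverage_filter(reads, ovl, min_coverage=2,
                                         max_coverage=100, max_diff_coverage=50,
                                         end_clip=0)
        assert kept == [] and kept_ovl == []

    def test_high_coverage_repeat_removed(self):
        reads = [RawRead("r", "A" * 2000)] + [
            RawRead(f"x{i}", "A" * 2000) for i in range(5)
        ]
        ovl = [
            _ovl("r", f"x{i}", (0, 2000), (0, 2000), 2000, 2000)
            for i in range(5)
        ]
        kept, _ = coverage_filter(reads, ovl, 1, 3, 100, end_clip=0)
        assert "r" not in {r.id for r in kept}

    def test_stats_match_bitmap_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = 3000
            ovls = []
            bitmap = np.zeros(n, np.int32)
            for j in range(int(rng.integers(1, 12))):
                s = int(rng.integers(0, n - 100))
                e = int(rng.integers(s + 50, n))
                ovls.append(_ovl("r", f"x{j}", (s, e), (0, e - s), n, n))
                bitmap[s:e] += 1
            st = coverage_stats("r", n, ovls)
            assert st.c_min == bitmap.min()
            assert st.c_max == bitmap.max()
            assert st.c_diff == bitmap.max() - bitmap.min()


class TestAdaptiveFilter:
    def test_local_cutoff_drops_outlier(self):
        # one read with nine 0.99 dovetails and one 0.92: local cutoff kills it
        ovls = [
            _ovl("hq", f"n{i}", (4000, 5000), (0, 1000), 5000, 5000, 0.99)
            for i in range(9)
        ]
        ovls.append(_ovl("hq", "bad", (4000, 5000), (0, 1000), 5000, 5000, 0.92))
        kept = adaptive_overlap_filter(ovls, 0.90, 500, alpha=2.0)
        assert all(o.b_id != "bad" for o in kept)
        assert len(kept) == 9

    def test_global_floor_binds_for_noisy_read(self):
        ovls = [
            _ovl("lq", f"n{i}", (4000, 5000), (0, 1000), 5000, 5000,
                 0.91 + 0.001 * i)
            for i in range(8)
        ]
        kept = adaptive_overlap_filter(ovls, 0.90, 500, alpha=2.0)
        assert len(kept) == 8

    def test_overhang_rule(self):
        # inner overhang 600 on both sides of the dovetail: dropped
        ovls = [
            _ovl("a", "b", (600, 4000), (600, 4000), 5000, 5000, 0.99),
            _ovl("a", "c", (1000, 5000), (0, 4000), 5000, 5000, 0.99),
        ]
        kept = adaptive_overlap_filter(ovls, 0.90, 500, alpha=2.0)
        assert [o.b_id for o in kept] == ["c"]


def _graph_from_edges(edges):
    g = StringGraph()
    for u, v, ext, ovl in edges:
        g.add_edge(u, v, ext, ovl)
    return g


class TestBuildStringGraph:
    def _reads(self):
        rng = np.random.default_rng(2)
        genome = rng.integers(0, 4, 10_000).astype(np.uint8)
        a = RawRead("a", _align.decode(genome[0:5000]))
        b = RawRead("b", _align.decode(genome[3000:8000]))
        return genome, a, b

    def test_dovetail_creates_dual_edges(self):
        genome, a, b = self._reads()
        ovl = _ovl("a", "b", (3000, 5000), (0, 2000), 5000, 5000)
        g = build_string_graph([a, b], [ovl])
        assert g.n_edges() == 2
        e = g.out[("a", "+")][("b", "+")]
        assert e.ext_len == 3000  # read b appends 5000 - 2000
        dual_e = g.out[("b", "-")][("a", "-")]
        assert dual_e.ext_len == 3000  # a's left overhang
        assert e.ovl_len == 2000

    def test_contained_read_absent(self):
        genome, a, b = self._reads()
        c = RawRead("c", _align.decode(genome[3500:4500]))
        ovl_ab = _ovl("a", "b", (3000, 5000), (0, 2000), 5000, 5000)
        ovl_ac = _ovl("a", "c", (3500, 4500), (0, 1000), 5000, 1000)
        g = build_string_graph([a, b, c], [ovl_ab, ovl_ac])
        assert "c" not in g.reads

    def test_clean_tiling_gives_simple_path(self, clean_readset, small_genome):
        from lorcas.io_core import PipelineConfig
        from lorcas import trimming as trm

        reads, truths = clean_readset
        cfg = PipelineConfig()
        overlaps = trm.pairwise_overlaps(reads, cfg)
        g = build_string_graph(reads, overlaps, min_overlap=500)
        # after reduction each orientation should be close to a simple path
        transitive_reduction(g, 100)
        out_degs = [len(g.out[v]) for v in g.nodes() if g.out[v]]
        assert max(out_degs, default=0) <= 2

    def test_reverse_strand_dovetail(self):
        rng = np.random.default_rng(3)
        genome = rng.integers(0, 4, 8000).astype(np.uint8)
        a = RawRead("a", _align.decode(genome[0:5000]))
        b = RawRead("b", _align.revcomp(_align.decode(genome[3000:8000])))
        # b reversed: its forward interval for genome[3000:5000] is [3000,5000)
        ovl = _ovl("a", "b", (3000, 5000), (3000, 5000), 5000, 5000,
                   strand="-")
        g = build_string_graph([a, b], [ovl])
        assert ("b", "-") in g.out[("a", "+")]


class TestTransitiveReduction:
    def test_triangle_removed(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 900),
            (("b", "+"), ("c", "+"), 150, 850),
            (("a", "+"), ("c", "+"), 250, 750),
        ])
        transitive_reduction(g, fuzz=10)
        assert ("c", "+") not in g.out[("a", "+")]
        assert ("b", "+") in g.out[("a", "+")]

    def test_out_of_tolerance_kept(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 900),
            (("b", "+"), ("c", "+"), 150, 850),
            (("a", "+"), ("c", "+"), 400, 750),
        ])
        transitive_reduction(g, fuzz=10)
        assert ("c", "+") in g.out[("a", "+")]

    def test_matches_bruteforce_on_random_dags(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            nodes = [(f"n{i}", "+") for i in range(n)]
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        edges[(nodes[i], nodes[j])] = int(rng.integers(50, 500))
            g = StringGraph()
            for (u, v), ext in edges.items():
                g.add_edge(u, v, ext, 1000 - ext, with_dual=False)
            fuzz = 30
            # oracle: test all 2-paths
            expected_removed = set()
            for (u, v), ext in edges.items():
                for (x, w), e1 in edges.items():
                    if x != u:
                        continue
                    e2 = edges.get((w, v))
                    if e2 is None or w == v:
                        continue
                    if abs(ext - (e1 + e2)) <= fuzz:
                        expected_removed.add((u, v))
            transitive_reduction(g, fuzz)
            remaining = {(u, v) for u, v, _ in g.edges()}
            assert remaining == set(edges) - expected_removed

    def test_reachability_preserved(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 900),
            (("b", "+"), ("c", "+"), 150, 850),
            (("a", "+"), ("c", "+"), 250, 750),
            (("c", "+"), ("d", "+"), 100, 700),
        ])
        transitive_reduction(g, fuzz=10)

        def reachable(src):
            seen, stack = set(), [src]
            while stack:
                v = stack.pop()
                for w in g.out.get(v, {}):
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            return seen

        assert ("d", "+") in reachable(("a", "+"))


class TestBestEdgePrune:
    def test_weaker_out_edge_removed(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 3000),
            (("a", "+"), ("c", "+"), 100, 1200),
            (("d", "+"), ("c", "+"), 100, 2000),
        ])
        best_edge_prune(g)
        # a->c is neither a's best out nor c's best in
        assert ("c", "+") not in g.out[("a", "+")]
        assert ("b", "+") in g.out[("a", "+")]
        assert ("c", "+") in g.out[("d", "+")]

    def test_simple_path_unchanged(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 900),
            (("b", "+"), ("c", "+"), 100, 900),
        ])
        n_before = g.n_edges()
        best_edge_prune(g)
        assert g.n_edges() == n_before

    def test_kept_if_best_in_elsewhere(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 3000),
            (("a", "+"), ("c", "+"), 100, 1200),
        ])
        best_edge_prune(g)
        # a->c is c's only (hence best) in-edge: kept
        assert ("c", "+") in g.out[("a", "+")]


class TestCleanGraph:
    def test_tip_removed(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 900),
            (("b", "+"), ("c", "+"), 100, 900),
            (("c", "+"), ("d", "+"), 100, 900),
            (("t", "+"), ("b", "+"), 100, 400),  # 1-node spur into b
        ])
        clean_graph(g, tip_len=3, bubble_depth=5)
        assert ("t", "+") not in g.out

    def test_bubble_collapsed(self):
        g = _graph_from_edges([
            (("s", "+"), ("a1", "+"), 100, 900),
            (("a1", "+"), ("a2", "+"), 100, 900),
            (("a2", "+"), ("e", "+"), 100, 900),
            (("s", "+"), ("b1", "+"), 100, 500),
            (("b1", "+"), ("b2", "+"), 100, 500),
            (("b2", "+"), ("e", "+"), 100, 500),
        ])
        clean_graph(g, tip_len=0, bubble_depth=5)
        outs = list(g.out[("s", "+")])
        assert len(outs) == 1  # one branch removed
        assert outs[0] == ("a1", "+")  # stronger branch survives

    def test_clean_linear_noop(self):
        g = _graph_from_edges([
            (("a", "+"), ("b", "+"), 100, 900),
            (("b", "+"), ("c", "+"), 100, 900),
        ])
        n = g.n_edges()
        clean_graph(g)
        assert g.n_edges() == n


class TestExtractContigs:
    def test_perfect_tiling_reconstructs_genome(self, small_genome):
        from lorcas import simulate as sim
        from lorcas import trimming as trm
        from lorcas.io_core import PipelineConfig

        glen = 50_000
        genome = sim.make_genome(glen, seed=21)
        model = sim.ErrorModel.noiseless()
        reads, truths = sim.sample_reads(genome, 10, (8_000, 4_000, 12_000),
                                         model, seed=23)
        cfg = PipelineConfig(genome_size=glen)
        overlaps = trm.pairwise_overlaps(reads, cfg)
        contigs, g = asm.assemble(reads, overlaps, cfg)
        assert contigs
        total = sum(c.length for c in contigs)
        assert total <= 1.1 * glen
        # the longest contig must be an exact substring of the genome
        longest = max(contigs, key=lambda c: c.length)
        assert (
            longest.sequence in genome.sequence
            or _align.revcomp(longest.sequence) in genome.sequence
        )
        assert longest.length >= 0.8 * glen

    def test_y_branch_breaks_paths(self):
        g = StringGraph({x: "A" * 1000 for x in "abcd"})
        g.add_edge(("a", "+"), ("b", "+"), 100, 900)
        g.add_edge(("b", "+"), ("c", "+"), 100, 900)
        g.add_edge(("b", "+"), ("d", "+"), 100, 900)
        contigs = extract_contigs(g)
        # no contig contains the branch node b plus both branches
        for c in contigs:
            ids = [rid for rid, _, _ in c.layout]
            assert not ({"c", "d"} <= set(ids))
        assert len(contigs) == 3

    def test_singleton_node(self):
        g = StringGraph({"solo": "ACGTACGT"})
        g.add_node(("solo", "+"))
        g.add_node(("solo", "-"))
        contigs = extract_contigs(g)
        assert len(contigs) == 1
        assert contigs[0].sequence in ("ACGTACGT", _align.revcomp("ACGTACGT"))

    def test_layout_conservation(self):
        # re-splicing the layout reproduces the contig byte for byte
        rng = np.random.default_rng(6)
        genome = rng.integers(0, 4, 9000).astype(np.uint8)
        seqs = {
            "a": _align.decode(genome[0:4000]),
            "b": _align.decode(genome[2500:6500]),
            "c": _align.decode(genome[5000:9000]),
        }
        g = StringGraph(seqs)
        g.add_edge(("a", "+"), ("b", "+"), 2500, 1500, dual_ext_len=2500)
        g.add_edge(("b", "+"), ("c", "+"), 2500, 1500, dual_ext_len=2500)
        contigs = extract_contigs(g)
        main = max(contigs, key=lambda c: c.length)
        assert main.sequence == _align.decode(genome)
        rebuilt = ""
        for rid, orient, offset in main.layout:
            seq = seqs[rid] if orient == "+" else _align.revcomp(seqs[rid])
            rebuilt = rebuilt[:offset] + seq
        assert rebuilt == main.sequence

    def test_empty_graph(self):
        assert extract_contigs(StringGraph()) == []
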