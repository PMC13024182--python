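"""Graph parsing, depth, bubble detection, voting, and contig merging."""

import networkx as nx
import numpy as np
import pytest

from bovidy.pangraph import (GFAError, MergeError, detect_bubbles, merge_overlap,
                             parse_gfa, parse_walks, segment_depth, vote_path,
                             write_gfa)
from bovidy.simulate import simulate_pangraph, walks_to_tsv
from bovidy._util import revcomp


def exhaustive_best_path(graph, depth):
    """Oracle: enumerate every simple source-to-sink path and return the
    maximal summed-depth score plus all argmax paths."""
    g = graph.digraph()
    src, snk = graph.backbone[0][0], graph.backbone[-1][0]
    best, argmax = None, []
    for path in nx.all_simple_paths(g, src, snk):
        score = sum(depth.get(s, 0) for s in path)
        if best is None or score > best:
            best, argmax = score, [path]
        elif score == best:
            argmax.append(path)
    return best, argmax


class TestParse:
    def test_single_segment(self):
        g = parse_gfa("S\ts1\tACGT\n")
        assert g.segments == {"s1": "ACGT"} and g.links == []

    def test_star_sequence_rejected(self):
        with pytest.raises(GFAError, match="sequence required"):
            parse_gfa("S\ts1\t*\n")

    def test_unknown_link_names_line(self):
        with pytest.raises(GFAError, match="line 2.*unknown segment s9"):
            parse_gfa("S\ts1\tACGT\nL\ts1\t+\ts9\t+\t0M\n")

    def test_roundtrip_preserves_graph(self):
        gfa, _, _ = simulate_pangraph(6, 3, bubble_spec=[(2, 3)], seed=5)
        g1 = parse_gfa(gfa)
        g2 = parse_gfa(write_gfa(g1))
        assert g1.segments == g2.segments
        assert sorted(g1.links) == sorted(g2.links)
        assert g1.backbone == g2.backbone

    def test_generator_segment_ledger(self):
        gfa, _, _ = simulate_pangraph(7, 4, bubble_spec=[(1, 2), (4, 3)], seed=2)
        g = parse_gfa(gfa)
        # 7 backbone + 1 alt (2-branch) + 2 alts (3-branch)
        assert len(g.segments) == 10


class TestDepth:
    def test_zero_walks(self):
        g = parse_gfa(simulate_pangraph(5, 2, seed=0)[0])
        assert set(segment_depth(g, []).values()) == {0}

    def test_identical_walks_full_depth(self):
        gfa, walks, _ = simulate_pangraph(5, 6, bubble_spec=0, seed=0)
        g = parse_gfa(gfa)
        depth = segment_depth(g, walks)
        assert all(depth[s] == 6 for s, _ in g.backbone)

    def test_depth_matches_generator_support(self):
        gfa, walks, truth = simulate_pangraph(9, 6, bubble_spec=[(2, 2), (5, 3)], seed=1)
        g = parse_gfa(gfa)
        depth = segment_depth(g, walks)
        support = {}
        for _, w in walks:
            for s in w:
                support[s] = support.get(s, 0) + 1
        for s, n in support.items():
            assert depth[s] == n
        assert all(depth[s] == 0 for s in g.segments if s not in support)

    def test_walk_tsv_roundtrip(self):
        gfa, walks, _ = simulate_pangraph(6, 4, bubble_spec=[(3, 2)], seed=3)
        parsed = parse_walks(walks_to_tsv(walks))
        assert parsed == [(n, list(p)) for n, p in walks]

    def test_unknown_segment_in_walk(self):
        g = parse_gfa(simulate_pangraph(5, 2, seed=0)[0])
        with pytest.raises(GFAError, match="nope"):
            segment_depth(g, [("s1", ["b0", "nope"])])


class TestBubbles:
    def test_linear_graph_no_bubbles(self):
        g = parse_gfa(simulate_pangraph(6, 2, bubble_spec=0, seed=0)[0])
        assert detect_bubbles(g) == []

    def test_single_insertion_two_branches(self):
        g = parse_gfa(simulate_pangraph(5, 2, bubble_spec=[(2, 2)], seed=0)[0])
        bubbles = detect_bubbles(g)
        assert len(bubbles) == 1
        b = bubbles[0]
        assert b.source == ("b1", "+") and b.sink == ("b3", "+")
        assert sorted(len(br) for br in b.branches) == [1, 1]
        assert not b.complex

    @pytest.mark.parametrize("seed", range(20))
    def test_bubble_set_matches_brute_force(self, seed):
        """Oracle: a bubble anchor pair is any (i < j) of adjacent backbone
        anchors joined by an off-backbone path."""
        rng = np.random.default_rng(seed)
        nb = int(rng.integers(6, 10))
        gfa, _, _ = simulate_pangraph(nb, 3, bubble_spec=int(rng.integers(1, 4)),
                                      seed=seed)
        g = parse_gfa(gfa)
        got = {(b.source[0], b.sink[0]) for b in detect_bubbles(g)}
        dg = g.digraph()
        bb = [s for s, _ in g.backbone]
        expected = set()
        for i, s in enumerate(bb):
            for j in range(i + 1, len(bb)):
                t = bb[j]
                for path in nx.all_simple_paths(dg, s, t):
                    if len(path) > 2 and all(n not in bb for n in path[1:-1]):
                        expected.add((s, t))
                        break
        assert got == expected

    def test_cyclic_region_flagged_complex(self):
        gfa = ("S\tb0\tAA\nS\tb1\tCC\nS\tb2\tGG\nS\tu1\tTT\nS\tu2\tAT\n"
               "L\tb0\t+\tb1\t+\t0M\nL\tb1\t+\tb2\t+\t0M\n"
               "L\tb0\t+\tu1\t+\t0M\nL\tu1\t+\tu2\t+\t0M\n"
               "L\tu2\t+\tu1\t+\t0M\nL\tu2\t+\tb2\t+\t0M\n"
               "P\tbackbone\tb0+,b1+,b2+\t*\n")
        bubbles = detect_bubbles(parse_gfa(gfa))
        assert len(bubbles) == 1 and bubbles[0].complex


class TestVote:
    def test_no_bubbles_backbone_concatenation(self):
        gfa, walks, _ = simulate_pangraph(5, 3, bubble_spec=0, seed=0)
        g = parse_gfa(gfa)
        cons = vote_path(g, segment_depth(g, walks), detect_bubbles(g))
        assert cons.sequence == "".join(g.segments[s] for s, _ in g.backbone)

    def test_deeper_branch_chosen(self):
        gfa, walks, truth = simulate_pangraph(5, 6, bubble_spec=[(2, 2)], seed=7)
        g = parse_gfa(gfa)
        depth = segment_depth(g, walks)
        cons = vote_path(g, depth, detect_bubbles(g))
        assert [s for s, _ in cons.path] == truth

    @pytest.mark.parametrize("seed", range(30))
    def test_vote_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        nb = int(rng.integers(5, 10))
        gfa, walks, truth = simulate_pangraph(
            nb, int(rng.integers(2, 7)), bubble_spec=int(rng.integers(0, 4)), seed=seed)
        g = parse_gfa(gfa)
        assert len(g.segments) <= 15
        depth = segment_depth(g, walks)
        cons = vote_path(g, depth, detect_bubbles(g))
        got_score = sum(depth[s] for s, _ in cons.path)
        best, argmax = exhaustive_best_path(g, depth)
        assert got_score == best
        if len(argmax) == 1:
            assert [s for s, _ in cons.path] == argmax[0] == truth

    def test_length_conservation(self):
        gfa, walks, _ = simulate_pangraph(8, 5, bubble_spec=2, seed=4)
        g = parse_gfa(gfa)
        cons = vote_path(g, segment_depth(g, walks), detect_bubbles(g))
        assert len(cons.sequence) == sum(len(g.segments[s]) for s, _ in cons.path)

    def test_depth_monotonicity(self):
        """Raising a chosen branch's depth never un-chooses it."""
        gfa, walks, _ = simulate_pangraph(6, 5, bubble_spec=[(2, 2)], seed=9)
        g = parse_gfa(gfa)
        depth = segment_depth(g, walks)
        bubbles = detect_bubbles(g)
        cons = vote_path(g, depth, bubbles)
        chosen = set(s for s, _ in cons.path)
        bumped = {s: d + (5 if s in chosen else 0) for s, d in depth.items()}
        cons2 = vote_path(g, bumped, bubbles)
        assert cons2.path == cons.path

    def test_complex_bubble_resolves_to_backbone_and_flags(self):
        gfa = ("S\tb0\tAA\nS\tb1\tCC\nS\tb2\tGG\nS\tu1\tTT\nS\tu2\tAT\n"
               "L\tb0\t+\tb1\t+\t0M\nL\tb1\t+\tb2\t+\t0M\n"
               "L\tb0\t+\tu1\t+\t0M\nL\tu1\t+\tu2\t+\t0M\n"
               "L\tu2\t+\tu1\t+\t0M\nL\tu2\t+\tb2\t+\t0M\n"
               "P\tbackbone\tb0+,b1+,b2+\t*\n")
        g = parse_gfa(gfa)
        cons = vote_path(g, {s: 1 for s in g.segments}, detect_bubbles(g))
        assert [s for s, _ in cons.path] == ["b0", "b1", "b2"]
        assert cons.flags == [0]


class TestMerge:
    def test_hand_verified_overlap(self):
        merged, rep = merge_overlap("ACGTACGT", "ACGTTTTT", min_overlap=4,
                                    min_identity=1.0)
        assert merged == "ACGTACGTTTTT"
        assert rep["overlap_len"] == 4 and rep["identity"] == 1.0

    def test_containment(self):
        a = "ACGTACGTACGTAAATTTCCC"
        merged, rep = merge_overlap(a, a[8:16], min_overlap=4, min_identity=1.0)
        assert merged == a and rep["containment"]

    def test_reverse_complement_overlap(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 300))
        tail = a[-60:]
        b = revcomp(tail + "".join(rng.choice(list("ACGT"), 100)))
        merged, rep = merge_overlap(a, b, min_overlap=50, min_identity=1.0)
        assert rep["orientation"] == "-"
        assert len(merged) == 300 + len(b) - rep["overlap_len"]

    def test_disjoint_raises(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        with pytest.raises(MergeError, match="no merge anchor"):
            merge_overlap(a, b, min_overlap=50, min_identity=0.99)

    @pytest.mark.parametrize("seed", range(10))
    def test_length_conservation_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(200, 500))))
        ov = int(rng.integers(40, 120))
        b = a[-ov:] + "".join(rng.choice(list("ACGT"), int(rng.integers(50, 300))))
        merged, rep = merge_overlap(a, b, min_overlap=30, min_identity=0.95)
        assert rep["merged_len"] == rep["len_a"] + rep["len_b"] - rep["overlap_len"]
        assert rep["overlap_len"] >= ov  # at least the planted anchor
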