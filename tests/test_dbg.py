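import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepnexus.dbg import (
    DbgParams,
    PathContig,
    Scaffold,
    assemble_dbg,
    build_graph,
    extract_unitigs,
    filter_edges,
    olc_refine,
    rank_scaffolds,
    score_scaffold,
)
from pepnexus.simulate import random_protein


class TestBuildGraph:
    def test_two_peptide_path_with_shared_kmer(self):
        kg = build_graph(["ACDEFGH", "DEFGHIK"], k=4)
        path = ["ACDE", "CDEF", "DEFG", "EFGH", "FGHI", "GHIK"]
        weights = [kg.edge_weight(u, v) for u, v in zip(path, path[1:])]
        assert weights == [1, 1, 2, 1, 1]  # DEFGH spans both peptides

    def test_single_kmer_peptide_has_no_edges(self):
        kg = build_graph(["ACDEFGH"], k=7)
        assert kg.nodes == {"ACDEFGH"} and kg.graph.number_of_edges() == 0

    def test_duplicate_peptides_double_weights(self):
        once = build_graph(["ACDEFGH"], k=4)
        twice = build_graph(["ACDEFGH", "ACDEFGH"], k=4)
        for u, v, w in once.graph.edges.data("weight"):
            assert twice.edge_weight(u, v) == 2 * w

    def test_short_peptides_skipped(self):
        kg = build_graph(["ACD"], k=4)
        assert kg.nodes == set()

    @given(st.integers(0, 300))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_weight_conservation(self, seed):
        rng = np.random.default_rng(seed)
        peps = [random_protein(int(rng.integers(4, 15)), rng) for _ in range(10)]
        k = 4
        kg = build_graph(peps, k)
        n_spanning = sum(max(len(p) - k, 0) for p in peps)
        assert kg.total_weight() == n_spanning


class TestExtractUnitigs:
    def test_linear_path_spelled(self):
        kg = build_graph(["ACDEFGH", "DEFGHIK"], k=4)
        contigs = extract_unitigs(kg)
        assert len(contigs) == 1
        c = contigs[0]
        assert c.sequence == "ACDEFGHIK"
        assert sum(c.weights) / len(c.weights) == pytest.approx(1.2)
        assert min(c.weights) == 1

    def test_branch_node_splits_paths(self):
        # two peptides share prefix ACDE, diverge afterwards: branch at CDE*
        kg = build_graph(["ACDEF", "ACDEG"], k=3)
        contigs = extract_unitigs(kg)
        assert all(
            "F" not in c.sequence or "G" not in c.sequence for c in contigs
        ), "no contig may span the branch"

    def test_empty_graph(self):
        assert extract_unitigs(build_graph([], k=4)) == []

    def test_size_threshold_drops_short(self):
        kg = build_graph(["ACDEFGH"], k=4)
        assert extract_unitigs(kg, size_threshold=8) == []
        assert len(extract_unitigs(kg, size_threshold=7)) == 1

    def test_cycle_terminates_at_revisit(self):
        # repeat-induced cycle: AAAB...AAAB
        kg = build_graph(["AAABCAAABC"], k=3)
        contigs = extract_unitigs(kg)
        assert contigs  # traversal terminates and yields sequence


class TestOlcRefine:
    def test_two_contigs_merge(self):
        a = PathContig("ACDEFGHIK", [1, 1, 2, 1, 1])
        b = PathContig("FGHIKLMNP", [3, 1, 1, 1, 1])
        (s,) = olc_refine([a, b], olc_min_overlap=5)
        assert s.sequence == "ACDEFGHIKLMNP"
        assert s.weights == [1, 1, 2, 1, 1, 3, 1, 1, 1, 1]

    def test_no_overlap_identity(self):
        a = PathContig("ACDEFGH", [1, 1])
        b = PathContig("KLMNPQR", [2, 2])
        out = olc_refine([a, b], olc_min_overlap=5)
        assert sorted(s.sequence for s in out) == ["ACDEFGH", "KLMNPQR"]

    def test_three_chained_w_min(self):
        a = PathContig("ACDEFGHIK", [5, 5])
        b = PathContig("EFGHIKLMN", [4, 1])
        c = PathContig("IKLMNPQRS", [9, 9])
        out = olc_refine([a, b, c], olc_min_overlap=5)
        assert len(out) == 1
        assert out[0].w_min == 1
        assert out[0].sequence == "ACDEFGHIKLMNPQRS"


class TestScoring:
    def test_worked_example(self):
        assert score_scaffold(1, 2, 1, alpha=1, beta=1) == pytest.approx(2.2)

    def test_w_min_unit_difference_scores_point_two(self):
        s1 = score_scaffold(50, 4.0, 3, alpha=1.3, beta=0.7)
        s2 = score_scaffold(50, 4.0, 2, alpha=1.3, beta=0.7)
        assert s1 - s2 == pytest.approx(0.2)

    def test_coefficient_isolation(self):
        assert score_scaffold(123, 9.0, 5, alpha=0, beta=0) == pytest.approx(1.0)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            score_scaffold(0, 1, 1)

    @given(
        L=st.integers(2, 500),
        w_mean=st.floats(1, 50),
        w_min=st.floats(1, 50),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_increasing_in_each_argument(self, L, w_mean, w_min):
        base = score_scaffold(L, w_mean, w_min)
        assert score_scaffold(L + 1, w_mean, w_min) > base
        assert score_scaffold(L, w_mean + 0.5, w_min) > base
        assert score_scaffold(L, w_mean, w_min + 0.5) > base


class TestRanking:
    def test_descending_by_score(self):
        scaffolds = [
            Scaffold("A" * 5, [1], score=2.2),
            Scaffold("C" * 5, [1], score=5.0),
            Scaffold("D" * 5, [1], score=0.3),
        ]
        assert [s.score for s in rank_scaffolds(scaffolds)] == [5.0, 2.2, 0.3]

    def test_tie_broken_by_length(self):
        scaffolds = [Scaffold("A" * 8, score=1.0), Scaffold("C" * 10, score=1.0)]
        assert rank_scaffolds(scaffolds)[0].L == 10

    def test_empty(self):
        assert rank_scaffolds([]) == []


def tiling_windows(reference: str, width: int = 12, step: int = 4) -> list[str]:
    return [
        reference[i : min(i + width, len(reference))]
        for i in range(0, len(reference) - 4, step)
    ]


class TestReconstruction:
    @pytest.mark.parametrize("k", [6, 7])
    def test_tiling_digest_reconstructs_reference(self, k):
        for seed in range(5):
            ref = random_protein(np.random.default_rng(seed).integers(100, 301), seed, unique_kmer=k)
            peps = tiling_windows(ref)
            scaffolds = assemble_dbg(peps, DbgParams(k=k, size_threshold=15))
            assert scaffolds[0].sequence == ref

    def test_raising_edge_weight_never_extends_assembly(self, noiseless_peptides):
        totals = []
        for mew in (1, 2, 3, 5):
            scaffolds = assemble_dbg(noiseless_peptides, DbgParams(min_edge_weight=mew))
            totals.append(sum(s.L for s in scaffolds))
        assert all(a >= b for a, b in zip(totals, totals[1:]))


def test_filter_edges_removes_low_weight():
    kg = build_graph(["ACDEFGH", "DEFGHIK"], k=4)
    filtered = filter_edges(kg, min_edge_weight=2)
    assert filtered.graph.number_of_edges() == 1
    assert filtered.nodes == kg.nodes
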