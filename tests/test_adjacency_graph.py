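"""Adjacency graph construction, decomposition, run counting, classification."""

import random

import pytest

from dcjdist import (
    Adjacency,
    SignedMarker,
    build_graph,
    classify_component,
    count_runs,
    decompose,
    marker_partition,
    adjacencies_of,
)
from dcjdist.adjacency_graph import (
    AB_PATH,
    BB_PATH,
    CYCLE,
    LINEAR_SINGLETON_A,
    Component,
)
from .conftest import genome, random_tiny_pair


def sm(token: str) -> SignedMarker:
    return SignedMarker(token.lstrip("-"), token.startswith("-"))


class TestAdjacencies:
    def test_running_example_genome_a(self, fig_a, fig_b):
        part = marker_partition(fig_a, fig_b)
        adj = adjacencies_of(fig_a, part, "A")
        expected = {
            Adjacency(None, (), ("b", "t"), "A"),
            Adjacency(("b", "h"), (sm("s"), sm("u")), ("c", "h"), "A"),
            Adjacency(("c", "t"), (), ("a", "t"), "A"),
            Adjacency(("a", "h"), (sm("v"),), ("d", "h"), "A"),
            Adjacency(("d", "t"), (), ("e", "t"), "A"),
            Adjacency(("e", "h"), (), None, "A"),
        }
        assert set(adj) == expected

    def test_running_example_genome_b(self, fig_a, fig_b):
        part = marker_partition(fig_a, fig_b)
        adj = adjacencies_of(fig_b, part, "B")
        expected = {
            Adjacency(None, (), ("a", "t"), "B"),
            Adjacency(("a", "h"), (sm("w"),), ("b", "t"), "B"),
            Adjacency(("b", "h"), (sm("-x"),), ("c", "t"), "B"),
            Adjacency(("c", "h"), (), None, "B"),
            Adjacency(None, (sm("y"),), ("d", "t"), "B"),
            Adjacency(("d", "h"), (sm("z"),), ("e", "t"), "B"),
            Adjacency(("e", "h"), (), None, "B"),
        }
        assert set(adj) == expected

    def test_clean_circular_self_pair(self):
        g = genome(">G\na b @\n")
        part = marker_partition(g, g)
        adj = adjacencies_of(g, part, "A")
        assert set(adj) == {
            Adjacency(("a", "h"), (), ("b", "t"), "A"),
            Adjacency(("b", "h"), (), ("a", "t"), "A"),
        }

    def test_canonical_orientation_equality(self):
        left = Adjacency(("b", "h"), (sm("s"), sm("u")), ("c", "h"), "A")
        right = Adjacency(("c", "h"), (sm("-u"), sm("-s")), ("b", "h"), "A")
        assert left == right
        assert hash(left) == hash(right)

    def test_singleton_adjacencies(self):
        a = genome(">A\nx y $\np @\na $\n")
        b = genome(">B\na $\n")
        part = marker_partition(a, b)
        adj = adjacencies_of(a, part, "A")
        singles = [v for v in adj if v.labeled and v.gamma1 is None and v.gamma2 is None]
        assert sorted(v.circular for v in singles) == [False, True]


class TestDecomposition:
    def test_running_example_components(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        kinds = sorted((c.kind, c.size) for c in graph.components)
        assert kinds == [(AB_PATH, 2), (AB_PATH, 6), (BB_PATH, 5)]
        assert graph.n_cycles == 0
        assert graph.n_ab_paths == 2

    def test_ab_path_starts_at_a_endpoint(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        for comp in graph.components:
            if comp.kind == AB_PATH:
                assert comp.vertices[0].origin == "A"
                assert comp.vertices[-1].origin == "B"

    def test_identical_genomes_all_two_vertex(self, fig_a):
        graph = build_graph(fig_a, fig_a)
        assert all(c.size == 2 for c in graph.components)
        n = len(fig_a.chromosomes[0].markers)
        assert len(graph.components) == graph.n_common + 1

    def test_triangle_pair_two_vertex_cycle(self):
        a = genome(">A\na b c d e $\n")
        c = genome(">C\na e $\n")
        graph = build_graph(a, c)
        kinds = sorted((k.kind, k.size) for k in graph.components)
        assert kinds == [(AB_PATH, 2), (AB_PATH, 2), (CYCLE, 2)]
        cyc = next(k for k in graph.components if k.kind == CYCLE)
        assert count_runs(cyc) == 1

    def test_genome_vs_empty_all_singletons(self, fig_a):
        from dcjdist import Genome

        graph = build_graph(fig_a, Genome("E", ()))
        assert [c.kind for c in graph.components] == [LINEAR_SINGLETON_A]
        assert graph.components[0].size == 1

    def test_vertex_count_conservation(self):
        rng = random.Random(5)
        for _ in range(30):
            a, b = random_tiny_pair(rng)
            graph = build_graph(a, b)
            comps = decompose(graph)
            assert sum(c.size for c in comps) == len(
                graph.adjacencies_a
            ) + len(graph.adjacencies_b)

    def test_ab_path_count_always_even(self):
        rng = random.Random(6)
        for _ in range(40):
            a, b = random_tiny_pair(rng)
            assert build_graph(a, b).n_ab_paths % 2 == 0


class TestRuns:
    def test_figure_path_has_three_runs(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        path = next(c for c in graph.components if c.kind == AB_PATH and c.size == 6)
        assert path.vertices[0] == Adjacency(None, (), ("b", "t"), "A")
        assert count_runs(path) == 3

    def test_bb_path_has_two_runs(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        bb = next(c for c in graph.components if c.kind == BB_PATH)
        assert count_runs(bb) == 2

    def test_all_clean_component_zero_runs(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        small = next(c for c in graph.components if c.size == 2)
        assert count_runs(small) == 0

    def test_one_sided_cycle_single_wrapping_run(self):
        a = genome(">A\na x b y @\n")
        b = genome(">B\na b @\n")
        graph = build_graph(a, b)
        cyc = next(c for c in graph.components if c.kind == CYCLE)
        # labels x and y sit in different A-adjacencies of one cycle but in
        # the same genome, so they wrap into a single run
        assert count_runs(cyc) == 1

    def test_cycles_never_have_odd_runs_above_one(self):
        rng = random.Random(7)
        for _ in range(60):
            a, b = random_tiny_pair(rng)
            for comp in build_graph(a, b).components:
                if comp.kind == CYCLE:
                    lam = count_runs(comp)
                    assert lam in (0, 1) or lam % 2 == 0


def _fake_path(kind: str, sides: list[tuple[str, bool]]) -> Component:
    verts = [
        Adjacency(None, (SignedMarker(f"m{i}"),) if lab else (), None, side)
        for i, (side, lab) in enumerate(sides)
    ]
    return Component(kind, verts)


class TestClassification:
    @pytest.mark.parametrize(
        "lam,first,indel_code,sub_code",
        [
            (1, "A", "A", "A"),
            (1, "B", "B", "B"),
            (2, "A", "AB", "AB"),
            (3, "A", "A", "ABA"),
            (3, "B", "B", "BAB"),
            (4, "A", "AB", "ABAB"),
            (5, "B", "B", "B"),
            (6, "B", "BA", "BA"),
            (7, "A", "A", "ABA"),
            (8, "B", "BA", "BABA"),
        ],
    )
    def test_ab_path_structures(self, lam, first, indel_code, sub_code):
        sides = []
        side = first
        for _ in range(lam):
            sides.append((side, True))
            side = "B" if side == "A" else "A"
        comp = _fake_path(AB_PATH, sides)
        assert classify_component(comp, "indel").structure == indel_code
        assert classify_component(comp, "substitution").structure == sub_code

    def test_even_run_bb_path_canonicalized(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        bb = next(c for c in graph.components if c.kind == BB_PATH)
        assert classify_component(bb, "indel").code == "BBAB"

    def test_figure_path_class_is_never_source(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        path = next(c for c in graph.components if c.size == 6)
        assert classify_component(path, "indel").code == "ABB"
        assert classify_component(path, "substitution").code == "ABBAB"

    def test_zero_runs_epsilon(self, fig_a, fig_b):
        graph = build_graph(fig_a, fig_b)
        small = next(c for c in graph.components if c.size == 2)
        for model in ("indel", "substitution"):
            assert classify_component(small, model).structure == "e"

    def test_cycles_not_classified(self):
        a = genome(">A\na b c d e $\n")
        c = genome(">C\na e $\n")
        cyc = next(k for k in build_graph(a, c).components if k.kind == CYCLE)
        assert classify_component(cyc, "indel") is None

    def test_swap_mirrors_classification(self):
        rng = random.Random(8)
        for _ in range(30):
            a, b = random_tiny_pair(rng)
            for model in ("indel", "substitution"):
                fwd = sorted(
                    rc.code
                    for c in build_graph(a, b).components
                    if (rc := classify_component(c, model)) is not None
                )
                mirrored = sorted(
                    rc.mirrored().code
                    for c in build_graph(b, a).components
                    if (rc := classify_component(c, model)) is not None
                )
                assert fwd == mirrored
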