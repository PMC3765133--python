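"""Top-level distances, corrected metrics, diameter bounds and triangle checks."""

import random
from fractions import Fraction as F

import pytest

from dcjdist import (
    Genome,
    build_graph,
    corrected_metric,
    dcj_distance,
    diameter_bound,
    genome_stats,
    minimal_correction_constant,
    triple_check,
    triple_partition,
    upper_bound,
    weighted_distance,
    worst_case_pair,
)
from .conftest import genome, random_tiny_pair

W_GRID = [F(k, 10) for k in range(1, 11)]


class TestDcjDistance:
    def test_inversion_sorting_needs_three(self, tri):
        a, b, _ = tri
        assert dcj_distance(a, b) == 3

    def test_identity(self, fig_a):
        assert dcj_distance(fig_a, fig_a) == 0

    def test_running_example(self, fig_a, fig_b):
        assert dcj_distance(fig_a, fig_b) == 4  # 5 - 0 - 2/2


class TestWeightedDistance:
    @pytest.mark.parametrize("model", ["indel", "substitution"])
    @pytest.mark.parametrize("w", [F(1), F(1, 2), F(1, 5)])
    def test_equal_content_pair_costs_three(self, tri, model, w):
        a, b, _ = tri
        assert weighted_distance(a, b, w, model).total == 3

    @pytest.mark.parametrize("w", [F(1), F(1, 2), F(1, 5)])
    def test_nested_deletion_costs_w(self, tri, w):
        a, _, c = tri
        bd = weighted_distance(a, c, w, "indel")
        assert bd.total == w
        assert bd.dcj == 0
        assert bd.sum_potential == 1

    def test_identity_zero(self, fig_a):
        for model in ("indel", "substitution"):
            assert weighted_distance(fig_a, fig_a, F(1, 2), model).total == 0

    def test_distance_zero_iff_equivalent(self):
        g1 = genome(">G\na b -c $\n")
        g2 = genome(">G\nc -b -a $\n")  # same molecule, reversed reading
        assert weighted_distance(g1, g2, F(1), "indel").total == 0
        g3 = genome(">G\na c -b $\n")
        assert weighted_distance(g1, g3, F(1), "indel").total > 0

    def test_empty_genome_costs_w_per_chromosome(self, fig_b):
        empty = Genome("E", ())
        for model in ("indel", "substitution"):
            for w in (F(1), F(2, 5)):
                assert weighted_distance(fig_b, empty, w, model).total == 2 * w
                assert weighted_distance(empty, fig_b, w, model).total == 2 * w
        assert weighted_distance(empty, Genome("E2", ()), F(1), "indel").total == 0

    def test_rejects_bad_w(self, tri):
        a, b, _ = tri
        for w in (F(0), F(-1, 2), F(3, 2)):
            with pytest.raises(ValueError):
                weighted_distance(a, b, w, "indel")

    def test_symmetry(self):
        rng = random.Random(31)
        for _ in range(25):
            a, b = random_tiny_pair(rng)
            for model in ("indel", "substitution"):
                for w in (F(1), F(1, 2), F(3, 5)):
                    assert (
                        weighted_distance(a, b, w, model).total
                        == weighted_distance(b, a, w, model).total
                    )

    def test_substitution_never_exceeds_indel(self):
        rng = random.Random(32)
        for _ in range(30):
            a, b = random_tiny_pair(rng, max_common=4, max_unique=3)
            for w in (F(1), F(1, 2), F(1, 4)):
                assert (
                    weighted_distance(a, b, w, "substitution").total
                    <= weighted_distance(a, b, w, "indel").total
                )

    def test_monotone_in_w(self):
        rng = random.Random(33)
        for _ in range(15):
            a, b = random_tiny_pair(rng, max_common=4, max_unique=3)
            for model in ("indel", "substitution"):
                vals = [weighted_distance(a, b, w, model).total for w in W_GRID]
                assert vals == sorted(vals)

    def test_sandwich_bounds(self):
        """d_DCJ <= weighted distance <= component bound <= diameter bound."""
        rng = random.Random(34)
        for _ in range(25):
            a, b = random_tiny_pair(rng, max_common=4, max_unique=3)
            graph = build_graph(a, b)
            n = graph.n_common
            sa, sb = genome_stats(a, b), genome_stats(b, a)
            for model in ("indel", "substitution"):
                for w in (F(1), F(3, 5), F(1, 4)):
                    d = weighted_distance(a, b, w, model).total
                    ub = upper_bound(graph.components, w, model)
                    db = diameter_bound(n, sa, sb, w, model)
                    assert dcj_distance(a, b) <= d <= ub <= db


class TestCorrection:
    @pytest.mark.parametrize(
        "w,model,expected",
        [
            (F(1), "indel", F(1)),
            (F(1, 2), "indel", F(3, 4)),
            (F(1), "substitution", F(3, 4)),
            (F(1, 2), "substitution", F(5, 8)),
        ],
    )
    def test_minimal_constants(self, w, model, expected):
        assert minimal_correction_constant(w, model) == expected

    def test_corrected_metric_adds_k_u(self, tri):
        a, _, c = tri
        assert corrected_metric(a, c, F(1), "indel", F(1)) == 1 + 3  # d=1, u=3
        assert corrected_metric(a, a, F(1), "indel", F(1)) == 0

    def test_low_k_warns(self, tri, caplog):
        import logging

        a, _, c = tri
        with caplog.at_level(logging.WARNING, logger="dcjdist.distances"):
            corrected_metric(a, c, F(1), "indel", F(1, 10))
        assert any("minimal" in r.message for r in caplog.records)


class TestDiameterAndWorstCase:
    def test_zero_markers_zero_bound(self):
        empty = Genome("E", ())
        s = genome_stats(empty, empty)
        assert diameter_bound(0, s, s, F(1), "indel") == 0

    def test_running_example_bound(self, fig_a, fig_b):
        sa, sb = genome_stats(fig_a, fig_b), genome_stats(fig_b, fig_a)
        assert diameter_bound(5, sa, sb, F(1), "indel") == 13  # 2*5 + (1+2)
        assert weighted_distance(fig_a, fig_b, F(1), "indel").total <= 13

    @pytest.mark.parametrize("n", range(1, 11))
    def test_worst_case_family_indel_closed_form(self, n):
        """Fully labeled 2n-cycle: distance (w+1) n + (w-1), touching Lemma's bound."""
        a, b = worst_case_pair(n)
        graph = build_graph(a, b)
        assert [c.kind for c in graph.components] == ["cycle"]
        assert graph.components[0].size == 2 * n
        assert graph.components[0].Lambda == 2 * n
        for w in (F(1), F(2, 3), F(1, 3)):
            d = weighted_distance(a, b, w, "indel").total
            assert d == (w + 1) * n + (w - 1)
            sa, sb = genome_stats(a, b), genome_stats(b, a)
            assert d <= diameter_bound(n, sa, sb, w, "indel")

    @pytest.mark.parametrize("n", [2, 4, 6, 8, 10])
    def test_worst_case_family_substitution_closed_form(self, n):
        a, b = worst_case_pair(n)
        for w in (F(1), F(1, 2)):
            d = weighted_distance(a, b, w, "substitution").total
            assert d == F(w + 2, 2) * n + (w - 1)


class TestTriple:
    def test_counterexample_uncorrected_fails(self, tri):
        a, b, c = tri
        rep = triple_check(a, b, c, F(1), "indel", k=F(0))
        assert not rep.holds
        assert rep.slack == -1
        assert not rep.reduced_holds

    def test_counterexample_fixed_by_k_one(self, tri):
        a, b, c = tri
        rep = triple_check(a, b, c, F(1), "indel", k=F(1))
        assert rep.holds
        assert rep.metrics == {"AB": F(3), "AC": F(4), "BC": F(4)}

    def test_minimal_k_restores_inequality(self, tri):
        a, b, c = tri
        for model in ("indel", "substitution"):
            for w in (F(1), F(1, 2), F(1, 5)):
                rep = triple_check(a, b, c, w, model)  # default minimal k
                assert rep.holds
                assert rep.reduced_holds

    def test_degenerate_triple_with_repeated_genome(self, tri):
        a, b, _ = tri
        rep = triple_check(a, b, a, F(1), "indel", k=F(1))
        assert rep.holds
        assert rep.slack >= 0

    def test_partition_sets(self, tri):
        a, b, c = tri
        part = triple_partition(a, b, c)
        assert part.common == frozenset("ae")
        assert part.ab == frozenset("bcd")
        assert part.only_a == part.only_b == part.only_c == frozenset()

    @pytest.mark.parametrize("model", ["indel", "substitution"])
    def test_worst_case_family_violates_below_minimal_k(self, model):
        """With k strictly below the minimal constant, large fully-labeled
        cycles against an empty genome break the corrected inequality."""
        empty = Genome("C", ())
        for w in (F(1), F(1, 2)):
            k_min = minimal_correction_constant(w, model)
            k = k_min * F(2, 3)
            violated = False
            for n in range(2, 11, 2):
                rep = triple_check(*worst_case_pair(n), empty, w, model, k=k)
                if not rep.holds:
                    violated = True
            assert violated
            for n in range(2, 11, 2):
                assert triple_check(*worst_case_pair(n), empty, w, model, k=k_min).holds
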