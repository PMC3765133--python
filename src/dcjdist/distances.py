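"""Genomic distances under the weighted DCJ-indel and DCJ-substitution models.

The DCJ distance of two duplication-free genomes is ``|G| - c - b/2`` where G
is the common marker set and c, b count the cycles and AB-paths of the
adjacency graph.  With content-modifying operations (indels, or the more
general substitutions) priced at ``0 < w <= 1`` against DCJ cost 1, the exact
weighted distance is the component-wise bound minus the recombination-group
deductions:

    d = d_DCJ + w * sum(potential) - deductions[w]

Both distances may violate the triangular inequality.  Adding a surcharge
``k * u(A, B)`` on the number of unique markers restores it; the minimal
constants are ``k = (w+1)/2`` (indel) and ``k = (w+2)/4`` (substitution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Optional

from .adjacency_graph import AdjacencyGraph, Model, build_graph, count_runs
from .genome_io import Genome, GenomeStats, genome_stats, marker_partition
from .potentials import (
    check_w,
    component_potential,
    dcj_sorting_cost,
    indel_potential,
    substitution_potential,
    upper_bound,
)
from .recombination import GroupCounts, deduction, maximize_groups, path_census

__all__ = [
    "DistanceBreakdown",
    "TriplePartition",
    "TripleReport",
    "dcj_distance",
    "weighted_distance",
    "corrected_metric",
    "minimal_correction_constant",
    "diameter_bound",
    "triple_partition",
    "triple_check",
]


@dataclass
class DistanceBreakdown:
    """Full accounting of one weighted distance computation."""

    model: str
    w: Fraction
    n_common: int
    n_cycles: int
    n_ab_paths: int
    dcj: int
    sum_potential: int
    group_counts: Optional[GroupCounts]
    total: Fraction
    graph: AdjacencyGraph = field(repr=False)

    @property
    def singleton_pairs(self) -> int:
        if self.group_counts is None:
            return 0
        return self.group_counts.pair_ls + self.group_counts.pair_cs

    @property
    def deduction(self) -> Fraction:
        if self.group_counts is None:
            return Fraction(0)
        return self.group_counts.total_deduction

    def as_dict(self) -> dict:
        d = {
            "model": self.model,
            "w": str(self.w),
            "n_common": self.n_common,
            "n_cycles": self.n_cycles,
            "n_ab_paths": self.n_ab_paths,
            "d_dcj": self.dcj,
            "sum_potential": self.sum_potential,
            "deduction": str(self.deduction),
            "distance": str(self.total),
            "distance_float": float(self.total),
        }
        if self.group_counts is not None:
            d["groups"] = dict(self.group_counts.per_group)
            d["singleton_pairs"] = {
                "linear": self.group_counts.pair_ls,
                "circular": self.group_counts.pair_cs,
            }
        return d


def dcj_distance(a: Genome, b: Genome) -> int:
    """Minimum number of DCJs sorting the common content: |G| - c - b/2."""
    graph = build_graph(a, b)
    return graph.n_common - graph.n_cycles - graph.n_ab_paths // 2


def weighted_distance(
    a: Genome, b: Genome, w: Fraction, model: Model
) -> DistanceBreakdown:
    """Exact weighted DCJ-indel or DCJ-substitution distance with breakdown."""
    w = check_w(w)
    if model not in ("indel", "substitution"):
        raise ValueError(f"unknown model {model!r}")
    part = marker_partition(a, b)
    graph = build_graph(a, b, part)
    comps = graph.components
    d_dcj = graph.n_common - graph.n_cycles - graph.n_ab_paths // 2

    pot = 0
    for comp in comps:
        lam = count_runs(comp)
        pot += indel_potential(lam) if model == "indel" else substitution_potential(lam)

    census = path_census(comps, model)
    groups = maximize_groups(census, w)
    total = d_dcj + w * pot - deduction(groups, w, model)
    assert total >= 0
    return DistanceBreakdown(
        model=model,
        w=w,
        n_common=graph.n_common,
        n_cycles=graph.n_cycles,
        n_ab_paths=graph.n_ab_paths,
        dcj=d_dcj,
        sum_potential=pot,
        group_counts=groups,
        total=total,
        graph=graph,
    )


def minimal_correction_constant(w: Fraction, model: Model) -> Fraction:
    """Smallest surcharge constant restoring the triangular inequality.

    ``(w+1)/2`` for the indel model and ``(w+2)/4`` for the substitution
    model; any smaller constant admits violating triples.
    """
    w = check_w(w)
    if model == "indel":
        return (w + 1) / 2
    if model == "substitution":
        return (w + 2) / 4
    raise ValueError(f"unknown model {model!r}")


def corrected_metric(
    a: Genome,
    b: Genome,
    w: Fraction,
    model: Model,
    k: Fraction | None = None,
) -> Fraction:
    """Corrected distance ``d(A,B) + k * u(A,B)``.

    With ``k`` at least the minimal correction constant the result is a
    metric on duplication-free genomes; smaller k only logs a warning because
    sub-metric surcharges remain useful for exploratory comparisons.
    """
    import logging

    w = check_w(w)
    k_min = minimal_correction_constant(w, model)
    if k is None:
        k = k_min
    k = Fraction(k)
    if k < k_min:
        logging.getLogger(__name__).warning(
            "correction constant %s below the minimal %s; triangular inequality "
            "is not guaranteed", k, k_min,
        )
    part = marker_partition(a, b)
    return weighted_distance(a, b, w, model).total + k * part.u


def diameter_bound(
    n: int, stats_a: GenomeStats, stats_b: GenomeStats, w: Fraction, model: Model
) -> Fraction:
    """Upper bound on the weighted distance of any two genomes.

    ``(w+1) n + w (L_A + S_A + L_B + S_B)`` for the indel model and
    ``(w+2)/2 n + w (L_A + S_A + L_B + S_B)`` for the substitution model,
    where n counts common markers, L the linear chromosomes and S the
    circular singletons.
    """
    w = check_w(w)
    chrom_term = w * (
        stats_a.n_linear
        + stats_a.n_circular_singleton
        + stats_b.n_linear
        + stats_b.n_circular_singleton
    )
    if model == "indel":
        return (w + 1) * n + chrom_term
    if model == "substitution":
        return Fraction(w + 2, 2) * n + chrom_term
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class TriplePartition:
    """The seven disjoint marker sets of three genomes.

    ``only_a/b/c`` are exclusive markers; ``ab`` (the critical set for the
    triangular inequality), ``bc`` and ``ac`` are shared by exactly two
    genomes; ``common`` by all three.
    """

    only_a: frozenset[str]
    only_b: frozenset[str]
    only_c: frozenset[str]
    ab: frozenset[str]
    bc: frozenset[str]
    ac: frozenset[str]
    common: frozenset[str]


@dataclass
class TripleReport:
    holds: bool
    slack: Fraction  # minimal m(X,Z) + m(Y,Z) - m(X,Y) over the three roles
    partition: TriplePartition
    distances: dict[str, Fraction]
    metrics: dict[str, Fraction]
    reduced_holds: bool  # d(A,B) <= d(A,C) + d(B,C) + 2k |ab|


def triple_partition(a: Genome, b: Genome, c: Genome) -> TriplePartition:
    ma, mb, mc = a.marker_names(), b.marker_names(), c.marker_names()
    return TriplePartition(
        only_a=frozenset(ma - mb - mc),
        only_b=frozenset(mb - ma - mc),
        only_c=frozenset(mc - ma - mb),
        ab=frozenset((ma & mb) - mc),
        bc=frozenset((mb & mc) - ma),
        ac=frozenset((ma & mc) - mb),
        common=frozenset(ma & mb & mc),
    )


def triple_check(
    a: Genome,
    b: Genome,
    c: Genome,
    w: Fraction,
    model: Model,
    k: Fraction | None = None,
) -> TripleReport:
    """Evaluate the three corrected triangle inequalities on a genome triple.

    ``k = 0`` checks the raw distances.  Also reports the reduced inequality
    ``d(A,B) <= d(A,C) + d(B,C) + 2 k |D|`` over the markers D common to A
    and B only, which is equivalent to the corrected inequality for the
    AB role.
    """
    w = check_w(w)
    if k is None:
        k = minimal_correction_constant(w, model)
    k = Fraction(k)
    part = triple_partition(a, b, c)

    genomes = {"A": a, "B": b, "C": c}
    dist: dict[str, Fraction] = {}
    metr: dict[str, Fraction] = {}
    for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
        d = weighted_distance(genomes[x], genomes[y], w, model).total
        u = marker_partition(genomes[x], genomes[y]).u
        dist[x + y] = d
        metr[x + y] = d + k * u

    slacks = [
        metr["AC"] + metr["BC"] - metr["AB"],
        metr["AB"] + metr["BC"] - metr["AC"],
        metr["AB"] + metr["AC"] - metr["BC"],
    ]
    slack = min(slacks)
    reduced = dist["AB"] <= dist["AC"] + dist["BC"] + 2 * k * len(part.ab)
    return TripleReport(
        holds=slack >= 0,
        slack=slack,
        partition=part,
        distances=dist,
        metrics=metr,
        reduced_holds=reduced,
    )
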