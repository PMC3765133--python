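"""Per-component DCJ sorting costs and content-modification potentials.

A component P of the adjacency graph is DCJ-sorted separately with
``floor((|P|-1)/2)`` DCJ operations.  Its indel-potential ``lambda(P)`` is
the minimum number of indels achievable while DCJ-sorting P with optimal
DCJs, ``ceil((Lambda+1)/2)`` for ``Lambda >= 1``; the substitution-potential
``sigma(P)`` is the analogous minimum number of substitutions,
``ceil((Lambda+1)/4)``.  Summing per-component costs yields upper bounds on
the weighted distances (tight up to the recombination-group deductions).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .adjacency_graph import (
    CIRCULAR_SINGLETON_A,
    CIRCULAR_SINGLETON_B,
    LINEAR_SINGLETON_A,
    LINEAR_SINGLETON_B,
    Component,
    Model,
    count_runs,
)

__all__ = [
    "ComponentPotential",
    "dcj_sorting_cost",
    "indel_potential",
    "substitution_potential",
    "component_potential",
    "component_distance",
    "upper_bound",
    "check_w",
]


def check_w(w: Fraction) -> Fraction:
    w = Fraction(w)
    if not 0 < w <= 1:
        raise ValueError(f"content-modifying cost w must satisfy 0 < w <= 1, got {w}")
    return w


@dataclass(frozen=True)
class ComponentPotential:
    dcj_cost: int
    lambda_p: int
    sigma_p: int


def dcj_sorting_cost(comp: Component) -> int:
    """DCJs needed to sort one component separately: floor((|P|-1)/2).

    Covers paths (size s needs floor((s-1)/2)), cycles (size 2k needs k-1)
    and singletons (0) uniformly; summed over all components this equals the
    DCJ distance |G| - c - b/2.
    """
    return (comp.size - 1) // 2


def indel_potential(lam: int) -> int:
    """Minimum indels for a component with ``lam`` runs: ceil((lam+1)/2)."""
    if lam < 0:
        raise ValueError("run count must be non-negative")
    return 0 if lam == 0 else -((lam + 1) // -2)


def substitution_potential(lam: int) -> int:
    """Minimum substitutions for a component with ``lam`` runs: ceil((lam+1)/4)."""
    if lam < 0:
        raise ValueError("run count must be non-negative")
    return 0 if lam == 0 else -((lam + 1) // -4)


def component_potential(comp: Component) -> ComponentPotential:
    lam = count_runs(comp)
    return ComponentPotential(
        dcj_cost=dcj_sorting_cost(comp),
        lambda_p=indel_potential(lam),
        sigma_p=substitution_potential(lam),
    )


def component_distance(comp: Component, w: Fraction, model: Model) -> Fraction:
    """Weighted cost of sorting one component separately.

    ``d_DCJ(P) + w*lambda(P)`` in the indel model, ``d_DCJ(P) + w*sigma(P)``
    in the substitution model; a singleton costs ``w`` (one indel or
    substitution of the whole chromosome).
    """
    w = check_w(w)
    pot = component_potential(comp)
    content = pot.lambda_p if model == "indel" else pot.sigma_p
    return pot.dcj_cost + w * content


def _singleton_counts(components: Iterable[Component]) -> dict[str, int]:
    counts = {LINEAR_SINGLETON_A: 0, LINEAR_SINGLETON_B: 0,
              CIRCULAR_SINGLETON_A: 0, CIRCULAR_SINGLETON_B: 0}
    for c in components:
        if c.kind in counts:
            counts[c.kind] += 1
    return counts


def singleton_pairs(components: Iterable[Component]) -> tuple[int, int]:
    """Maximum disjoint pairs of (linear, circular) singletons across genomes.

    A pair (one singleton per genome, same topology) can be sorted by a
    single substitution; a linear chromosome may not be substituted by a
    circular one.
    """
    n = _singleton_counts(components)
    return (
        min(n[LINEAR_SINGLETON_A], n[LINEAR_SINGLETON_B]),
        min(n[CIRCULAR_SINGLETON_A], n[CIRCULAR_SINGLETON_B]),
    )


def upper_bound(components: Sequence[Component], w: Fraction, model: Model) -> Fraction:
    """Component-wise upper bound on the weighted distance.

    Indel model: ``d_DCJ + w * sum(lambda)``.  Substitution model:
    ``d_DCJ + w * sum(sigma) - w * (P_LS + P_CS)`` where the last term counts
    the disjoint singleton pairs sorted by a single substitution each.
    """
    w = check_w(w)
    total = Fraction(0)
    for comp in components:
        total += component_distance(comp, w, model)
    if model == "substitution":
        p_ls, p_cs = singleton_pairs(components)
        total -= w * (p_ls + p_cs)
    return total
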