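# Methods

This note records the model implemented by `dcjdist`, the choices made where
the design was genuinely open, and what the validation harness does and does
not show.

## Model and assumptions

Genomes are multisets of linear and/or circular chromosomes over signed
markers (genes or synteny blocks). Three assumptions are structural:

* **No duplicated markers.** Every marker name occurs at most once per
  genome. Orthology assignment happens upstream.
* **Unit DCJ cost, content cost `0 < w <= 1`.** A DCJ cuts two adjacencies
  and rejoins the four open ends; an indel inserts or deletes one contiguous
  block inside one adjacency's label (at most one whole chromosome at a
  time); a substitution replaces one contiguous block by another in a single
  adjacency, with linear-for-circular chromosome swaps disallowed. Costs
  above 1 for content operations are rejected: the theory requires the
  content cost to be bounded by the DCJ cost.
* **Chromosomes are unoriented molecules.** A linear chromosome equals its
  reverse complement; a circular one equals any rotation or reflected
  rotation. Genome equality, the search oracle's state space and the
  distance identity axiom all use this canonicalization.

The distance pipeline is: marker partition -> adjacency graph -> component
decomposition -> run counts `Λ` -> potentials `λ = ⌈(Λ+1)/2⌉`,
`σ = ⌈(Λ+1)/4⌉` -> component-wise bound -> recombination-group deductions ->
exact distance. The corrected metrics add `k·u(A,B)` with minimal constants
`(w+1)/2` (indel) and `(w+2)/4` (substitution).

## Exact arithmetic

`w`, `k` and every distance are `fractions.Fraction`s. The deduction groups
switch on and off at `w = 1/2` and `w = 2/3`; a float `w` of `0.5` would sit
on the wrong side of the boundary after rounding, so the CLI converts
decimal input to exact rationals before any comparison (`0.5` is `1/2`
exactly, not the binary float). The skip rule uses strict `w <= 1/2` /
`w <= 2/3`, which matches the behaviour of the deductions at the boundary:
at `w = 1/2` the neutral-closing groups tie with the plain `-w` groups they
would cannibalize, so skipping them loses nothing.

## Deduction groups and their maximization

Each group (P, Q, T, S1, S2, M, N1, N2 for indels; U through Z2 for
substitutions) is a set of alternative source multisets of labeled-path run
classes, with a fixed per-occurrence saving. The prescribed computation is
greedy by group, in the order listed. Within and across groups the lines
compete for the same components, and no per-group algorithm is forced by the
theory, so the implementation solves the greedy prescription exactly as a
lexicographic sequence of tiny integer programs (scipy's HiGHS backend): the
occurrence count of group 1 is maximized first, then group 2 subject to
group 1 staying maximal, and so on. Problems have at most a few dozen
variables; instances without competing lines bypass the solver. A final
tie-break pass prefers explicit singleton pairings over equal-value
recombinations so that the reported disjoint-pair counts `P_LS`/`P_CS`
follow their definition.

### Singletons as path classes

A linear chromosome without common markers is the degenerate one-vertex case
of an AA/BB-path and participates in the deduction groups through its run
class (`AAA`/`BBB`): a DCJ can gather its doomed content with another
component's run so that one content operation disposes of both. Circular
singletons cannot be recombined without a wasted DCJ and only contribute the
substitution-model pairing saving. These choices are validated against the
search oracle rather than assumed: the oracle battery includes
singleton-rich instances.

### A completion of the substitution-model recombination tables

The run-merge algebra implies that merging two odd-run paths whose runs lie
in *opposite* genomes (classes `AAA + BBB`, and `AAB + BBA`) saves one
substitution: the merged component has two runs and `σ(2) = 1`, while the
sources cost `σ(1) + σ(1) = 2`, and the AA+BB recombination that merges them
is optimal (no DCJ overhead). The analogous merge saves nothing in the indel
model (`λ(2) = 2`), which is why these two pairs do not appear among the
indel deductions. `dcjdist` includes them as members of the `-w` group
(X1). The completion was found, and is continuously re-verified, by the
exhaustive-search oracle: without these two lines the formula overestimates
the substitution distance of, e.g., a 3-common-marker instance with one
A-run path and one B-run path by exactly `w`. A systematic enumeration of
all AA x BB class pairs under the merge algebra shows these are the only
such additions, and their resultants are never-source AB-paths, so no
further multi-recombination groups arise.

## The search oracle

The oracle is an A* search over canonicalized genome states, with move set:
all DCJs whose cuts do not fall between two markers that are both absent
from the target (inversions, translocations, fissions, fusions, excisions,
circularizations); deletions of maximal target-absent blocks; insertions of
any arrangement of still-missing target markers at any position or as a new
chromosome; and, in the substitution model, in-place block replacements.
Two reductions keep it honest but tractable:

* **Whole-block content moves.** A deletion that removes only part of a
  label strands an adjacent remnant that remains target-absent forever;
  extending the deletion to the whole maximal block and dropping the
  remnant's later removal never costs more. The exhaustive sub-block move
  set remains available (`maximal_content=False`) and is tested to yield
  identical optima.
* **Admissible pruning.** The priority adds a lower bound on the remaining
  cost: the DCJ distance restricted to the markers shared by the current
  state and the target (content operations never decrease it — deletions do
  not touch the common-marker graph and insertions only extend it), plus
  block-counting bounds on the content operations still needed (one
  operation removes or introduces at most one contiguous block; one DCJ
  merges or splits at most two). Both bounds are proved admissible by the
  projection/monotonicity arguments above, so optimality is preserved; the
  search reopens states, so even where the combined bound is inconsistent
  the popped goal cost is minimal.

Costs are carried as integers in units of `1/denominator(w)`, making the
priority queue exact without rational arithmetic. The oracle returns `None`
when it has proven the distance exceeds the cost cap and raises when the
state budget runs out — it never returns a wrong number. Because the model
is symmetric (reversing a scenario swaps insertions and deletions), the
search runs toward the genome with fewer unique markers.

## Simulator

The simulator provides the study conditions for validation, not realistic
evolution (no rate matrices or length distributions):

* `random_genome(n, chromosomes, topology, seed)` — uniform signed order,
  uniform split points.
* `evolve(genome, n_dcj, n_content, model, seed)` — requested numbers of
  uniformly random DCJs and content operations, insertions drawing fresh
  names from a disjoint namespace so partitions stay unambiguous; the
  returned log replays deterministically and its cost at any `w` upper-
  bounds the computed distance of the pair.
* `make_triple(n_common, n_shared_ab, ...)` — triples with an exact number
  of markers shared by A and B only (the set that drives triangle
  violations), built by evolving B and C from A with insertions only.
* `worst_case_pair(n)` — the extremal family: two circular genomes whose
  adjacency graph is a single fully labeled cycle with `2n` vertices and
  `2n` runs, attaining `(w+1)n + (w-1)` (indel) and, for even `n`,
  `(w+2)n/2 + (w-1)` (substitution). Genome B visits the common markers
  with stride two; for even `n` that closes into two circular chromosomes,
  which leaves the graph and the distance unchanged.

## Validation scales

The test suite checks the worked example exactly; the oracle battery runs
200 random instances (up to 4 common and 2 unique markers per genome, mixed
topologies, singletons included) against the search oracle at
`w ∈ {1/4, 1/2, 3/5, 2/3, 1}` in both models — 2 000 exact equalities; the
property suite covers the component-cost identity, potential formulas for
`Λ ≤ 50`, model dominance, monotonicity in `w`, the bound chain, metric
axioms, 1 000 random triples under the minimal correction constants, and the
extremal family for `n ≤ 10` symbolically. Instance sizes for the oracle
battery were chosen so the exhaustive search stays exact (no capped or
skipped searches); passing these tests demonstrates correctness of the
combinatorics, not biological realism of the simulator.

## Known limitations

* Duplicated markers are rejected, not resolved; no orthology inference.
* The distance is a point estimate of parsimony cost; no scenario sampling
  or uncertainty quantification.
* The oracle is exponential and practical only below roughly ten markers.
* Mixed linear/circular genomes are accepted (the formulas are per
  component) with a logged warning, since the classical setting assumes
  uniform topology per genome.
* The group maximization solves small integer programs; on adversarial
  inputs with thousands of labeled paths of many interacting classes the
  lexicographic solves, while still polynomial in practice via HiGHS, are
  not the letter of a linear-time scan. For real genome pairs the number of
  interacting labeled paths is small.
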