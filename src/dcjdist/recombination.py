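"""Path-recombination census and deduction-group maximization.

A recombination is a DCJ whose two cuts fall in different components of the
adjacency graph.  Certain path recombinations lower the combined
DCJ-plus-content cost below the component-wise upper bound.  They organize
into groups with a fixed per-occurrence saving (a linear function of the
content-modifying cost w), and the exact distance is obtained by greedily
maximizing the number of occurrences group by group, in a fixed order:

* indel model:        P, Q, T, S1, S2, M, N1, N2
* substitution model: U, V, W, X1, X2, Y, Z1, Z2

Groups whose closing DCJ is neutral stop paying off for small w and are
skipped: Q, T, S2, M, N1 (V, W, X2, Y, Z1) for ``w <= 1/2`` and N2 (Z2) for
``w <= 2/3``.

Linear singletons are the degenerate one-vertex AA/BB-paths and take part in
the maximization through their run class (AAA or BBB).  In the substitution
model a pair of same-topology singletons, one per genome, can instead be
sorted by a single substitution; these pairings compete with the
recombination groups for the same components and are resolved jointly at the
X1 priority level, which carries the same per-occurrence saving w.

The greedy order is realized exactly as a lexicographic integer program:
each group's occurrence count is maximized subject to the component counts
and to all previous groups keeping their maximal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .adjacency_graph import (
    CIRCULAR_SINGLETON_A,
    CIRCULAR_SINGLETON_B,
    LINEAR_SINGLETON_A,
    LINEAR_SINGLETON_B,
    Component,
    Model,
    classify_component,
)
from .potentials import check_w

__all__ = [
    "RecombinationLine",
    "Group",
    "PathCensus",
    "GroupCounts",
    "TABLE_LINES",
    "GROUPS",
    "GROUP_ORDER",
    "path_census",
    "maximize_groups",
    "deduction",
    "group_coefficient",
]

# Pseudo-classes for singleton bookkeeping.  LSA/LSB pool into AAA/BBB when
# consumed by recombination lines; CSA/CSB only ever pair with each other.
LSA, LSB, CSA, CSB = "LSA", "LSB", "CSA", "CSB"
NEVER_SOURCE = "."  # labeled AB-paths that never source a recombination

# Affine coefficients (const, slope): value = const + slope * w.
Affine = tuple[int, int]


def _affine(w: Fraction, a: Affine) -> Fraction:
    return a[0] + a[1] * w


@dataclass(frozen=True)
class RecombinationLine:
    """One recombination: sources, best resultants and its cost variation."""

    op: str  # operation type tag, e.g. "o-1", "n-2"
    sources: tuple[str, ...]
    resultants: tuple[str, ...]
    delta_potential: int  # change of the summed potential (delta-lambda/sigma)
    delta_dcj: int  # 0 optimal, 1 neutral, 2 counter-optimal

    def delta_cost(self, w: Fraction) -> Fraction:
        """Combined variation delta_DCJ + w * delta_potential."""
        return self.delta_dcj + Fraction(w) * self.delta_potential


def _line(op: str, sources: str, resultants: str, dpot: int, ddcj: int) -> RecombinationLine:
    return RecombinationLine(
        op, tuple(sources.split("+")), tuple(resultants.split("+")), dpot, ddcj
    )


# All individually useful path recombinations per model (sources, best
# resultants, potential variation, DCJ variation).  "." marks never-source
# AB-paths among the resultants.
TABLE_LINES: dict[str, tuple[RecombinationLine, ...]] = {
    "indel": (
        _line("o-2", "AAAB+BBAB", ".+.", -2, 0),
        _line("o-1", "AAA+BBAB", ".+ABAB", -1, 0),
        _line("o-1", "BBA+AAAB", ".+ABBA", -1, 0),
        _line("o-1", "AAB+BBAB", ".+ABBA", -1, 0),
        _line("o-1", "BBB+AAAB", ".+ABAB", -1, 0),
        _line("o-1", "AAA+BBA", ".+.", -1, 0),
        _line("o-1", "AAB+BBB", ".+.", -1, 0),
        _line("n-2", "AAAB+AAAB", "AAA+AAB", -2, 1),
        _line("n-2", "BBAB+BBAB", "BBA+BBB", -2, 1),
        _line("n-2", "AAAB+ABAB", ".+AAA", -2, 1),
        _line("n-2", "AAAB+ABBA", ".+AAB", -2, 1),
        _line("n-2", "BBAB+ABAB", ".+BBB", -2, 1),
        _line("n-2", "BBAB+ABBA", ".+BBA", -2, 1),
        _line("n-2", "ABAB+ABBA", ".+.", -2, 1),
        _line("n-1", "AAA+ABBA", ".+AAAB", -1, 1),
        _line("n-1", "AAB+ABAB", ".+AAAB", -1, 1),
        _line("n-1", "BBA+ABAB", ".+BBAB", -1, 1),
        _line("n-1", "BBB+ABBA", ".+BBAB", -1, 1),
    ),
    "substitution": (
        _line("o-2", "AAABAB+BBABAB", ".+.", -2, 0),
        _line("o-1", "AAA+BBABA", ".+.", -1, 0),
        _line("o-1", "AAB+BBBAB", ".+.", -1, 0),
        _line("o-1", "AAABA+BBA", ".+.", -1, 0),
        _line("o-1", "AABAB+BBB", ".+.", -1, 0),
        _line("o-1", "AAAB+BBABAB", ".+.", -1, 0),
        _line("o-1", "AAABAB+BBAB", ".+.", -1, 0),
        _line("o-1", "AAAB+BBAB", ".+.", -1, 0),
        _line("o-1", "AAABA+BBABAB", ".+.", -1, 0),
        _line("o-1", "AABAB+BBABAB", ".+.", -1, 0),
        _line("o-1", "AAABAB+BBABA", ".+.", -1, 0),
        _line("o-1", "AAABAB+BBBAB", ".+.", -1, 0),
        _line("o-1", "AAA+BBA", ".+.", -1, 0),
        _line("o-1", "AAB+BBB", ".+.", -1, 0),
        # Opposite-side odd-run merges: sigma(1)+sigma(1)=2 but the combined
        # path has two runs and sigma(2)=1, so the optimal AA+BB
        # recombination still saves one substitution.  (In the indel model
        # the analogous merge saves nothing, lambda(2)=2, and these pairs are
        # rightly absent there.)  Verified against the search oracle.
        _line("o-1", "AAA+BBB", ".+.", -1, 0),
        _line("o-1", "AAB+BBA", ".+.", -1, 0),
        _line("o-1", "AAA+BBAB", ".+.", -1, 0),
        _line("o-1", "AAB+BBAB", ".+.", -1, 0),
        _line("o-1", "AAAB+BBA", ".+.", -1, 0),
        _line("o-1", "AAAB+BBB", ".+.", -1, 0),
        _line("o-1", "AAA+BBABAB", ".+ABABAB", -1, 0),
        _line("o-1", "AAB+BBABAB", ".+ABBABA", -1, 0),
        _line("o-1", "AAABAB+BBA", ".+ABBABA", -1, 0),
        _line("o-1", "AAABAB+BBB", ".+ABABAB", -1, 0),
        _line("n-2", "AAABAB+AAABAB", "AAABA+AABAB", -2, 1),
        _line("n-2", "BBABAB+BBABAB", "BBABA+BBBAB", -2, 1),
        _line("n-2", "AAABAB+ABABAB", ".+AAABA", -2, 1),
        _line("n-2", "AAABAB+ABBABA", ".+AABAB", -2, 1),
        _line("n-2", "BBABAB+ABABAB", ".+BBBAB", -2, 1),
        _line("n-2", "BBABAB+ABBABA", ".+BBABA", -2, 1),
        _line("n-2", "ABABAB+ABBABA", ".+.", -2, 1),
        _line("n-1", "AAA+ABBABA", ".+AAABAB", -1, 1),
        _line("n-1", "AAB+ABABAB", ".+AAABAB", -1, 1),
        _line("n-1", "BBA+ABABAB", ".+BBABAB", -1, 1),
        _line("n-1", "BBB+ABBABA", ".+BBABAB", -1, 1),
        _line("n-1", "AAAB+ABABAB", ".+AAA", -1, 1),
        _line("n-1", "AAAB+ABBABA", ".+AAB", -1, 1),
        _line("n-1", "BBAB+ABBABA", ".+BBA", -1, 1),
        _line("n-1", "BBAB+ABABAB", ".+BBB", -1, 1),
    ),
}


@dataclass(frozen=True)
class Group:
    """One deduction group: alternative source multisets sharing a saving."""

    gid: str
    saving: Affine  # per-occurrence deduction, as const + slope * w
    lines: tuple[dict, ...]  # each line: class code -> multiplicity
    skip_at_or_below: Fraction | None = None  # skip the group when w <= this
    dcj_sequence: str = ""

    def active(self, w: Fraction) -> bool:
        return self.skip_at_or_below is None or w > self.skip_at_or_below


def _g(gid, saving, lines, skip=None, seq=""):
    parsed = []
    for ln in lines:
        need: dict[str, int] = {}
        for tok in ln.split("+"):
            mult = 1
            if tok[0] == "2":
                mult, tok = 2, tok[1:]
            need[tok] = need.get(tok, 0) + mult
        parsed.append(need)
    return Group(gid, saving, tuple(parsed), skip, seq)


HALF = Fraction(1, 2)
TWO_THIRDS = Fraction(2, 3)

GROUPS: dict[str, tuple[Group, ...]] = {
    "indel": (
        _g("P", (0, 2), ["AAAB+BBAB"], seq="o-2"),
        _g("Q", (-1, 4), ["2AAAB+BBA+BBB", "2BBAB+AAA+AAB"], HALF, "2 o-1 < n-2"),
        _g("T", (-1, 3), [
            "AAAB+BBA+ABAB", "AAAB+BBB+ABBA", "BBAB+AAA+ABBA", "BBAB+AAB+ABAB",
            "2BBAB+AAA", "2BBAB+AAB", "2AAAB+BBA", "2AAAB+BBB",
        ], HALF, "o-1 < n-2"),
        _g("S1", (0, 1), [
            "AAA+BBA", "AAB+BBB", "AAAB+BBA", "AAAB+BBB", "BBAB+AAA", "BBAB+AAB",
        ], seq="o-1"),
        _g("S2", (-1, 2), [
            "ABAB+ABBA", "AAAB+ABAB", "AAAB+ABBA", "BBAB+ABAB", "BBAB+ABBA",
            "2AAAB", "2BBAB",
        ], HALF, "n-2"),
        _g("M", (-2, 4), ["2ABAB+AAB+BBA", "2ABBA+AAA+BBB"], HALF, "2 n-1 < o-2"),
        _g("N1", (-1, 2), ["ABAB+AAB+BBA", "ABBA+AAA+BBB"], HALF, "n-1 < o-1"),
        _g("N2", (-2, 3), [
            "2ABAB+AAB", "2ABAB+BBA", "2ABBA+AAA", "2ABBA+BBB",
        ], TWO_THIRDS, "n-1 < n-2"),
    ),
    "substitution": (
        _g("U", (0, 2), ["AAABAB+BBABAB"], seq="o-2"),
        _g("V", (-1, 4), ["2AAABAB+BBA+BBB", "2BBABAB+AAA+AAB"], HALF, "2 o-1 < n-2"),
        _g("W", (-1, 3), [
            "AAABAB+BBA+ABABAB", "AAABAB+BBB+ABBABA",
            "BBABAB+AAA+ABBABA", "BBABAB+AAB+ABABAB",
            "2AAABAB+BBA", "2AAABAB+BBB", "2BBABAB+AAA", "2BBABAB+AAB",
        ], HALF, "o-1 < n-2"),
        _g("X1", (0, 1), [
            "AAA+BBABAB", "AAB+BBABAB", "AAABAB+BBA", "AAABAB+BBB",
            "AAAB+BBABAB", "AAABAB+BBAB", "AAAB+BBAB",
            "AAABA+BBABAB", "AABAB+BBABAB", "AAABAB+BBABA", "AAABAB+BBBAB",
            "AAA+BBA", "AAB+BBB", "AAA+BBAB", "AAB+BBAB", "AAAB+BBA", "AAAB+BBB",
            "AAA+BBABA", "AAB+BBBAB", "AAABA+BBA", "AABAB+BBB",
            # Opposite-side odd-run merges (see TABLE_LINES): one
            # substitution covers both runs after an optimal recombination.
            "AAA+BBB", "AAB+BBA",
            # Singleton pairings: one substitution sorts a same-topology
            # singleton pair; same saving w, resolved jointly with X1.
            "LSA+LSB", "CSA+CSB",
        ], seq="o-1"),
        _g("X2", (-1, 2), [
            "2AAABAB", "2BBABAB", "AAABAB+ABABAB", "AAABAB+ABBABA",
            "BBABAB+ABABAB", "BBABAB+ABBABA", "ABABAB+ABBABA",
        ], HALF, "n-2"),
        _g("Y", (-2, 4), ["2ABABAB+AAB+BBA", "2ABBABA+AAA+BBB"], HALF, "2 n-1 < o-2"),
        _g("Z1", (-1, 2), [
            "ABABAB+AAAB+BBABA", "ABBABA+AAAB+BBBAB", "ABBABA+AAABA+BBAB",
            "ABABAB+AABAB+BBAB", "ABABAB+AAB+BBABA", "ABABAB+AABAB+BBA",
            "ABBABA+AAA+BBBAB", "ABBABA+AAABA+BBB",
            "ABABAB+AAB+BBA", "ABBABA+AAA+BBB",
        ], HALF, "n-1 < o-1"),
        _g("Z2", (-2, 3), [
            "2ABABAB+AAB", "2ABABAB+BBA", "2ABBABA+AAA", "2ABBABA+BBB",
        ], TWO_THIRDS, "n-1 < n-2"),
    ),
}

GROUP_ORDER = {m: tuple(g.gid for g in gs) for m, gs in GROUPS.items()}
_PAIR_LINES = ({LSA: 1, LSB: 1}, {CSA: 1, CSB: 1})


@dataclass
class PathCensus:
    """Occurrence counts of labeled-path run classes plus singleton tallies.

    ``counts`` maps class codes (``AAAB`` etc.) of non-singleton labeled
    paths; singletons are tallied under ``LSA``/``LSB``/``CSA``/``CSB`` and
    never-source labeled AB-paths under ``.``.
    """

    model: Model
    counts: dict[str, int] = field(default_factory=dict)

    def get(self, code: str) -> int:
        return self.counts.get(code, 0)

    def available(self, code: str) -> int:
        """Source pool for a class; linear singletons widen AAA/BBB."""
        n = self.get(code)
        if code == "AAA":
            n += self.get(LSA)
        elif code == "BBB":
            n += self.get(LSB)
        return n


@dataclass
class GroupCounts:
    """Occurrences per deduction group and the resulting total deduction."""

    model: Model
    w: Fraction
    per_group: dict[str, int]
    pair_ls: int = 0
    pair_cs: int = 0

    @property
    def total_deduction(self) -> Fraction:
        return deduction(self, self.w, self.model)


def path_census(components: Iterable[Component], model: Model) -> PathCensus:
    """Tally labeled paths by run class; cycles and clean paths are excluded."""
    counts: dict[str, int] = {}

    def bump(code):
        counts[code] = counts.get(code, 0) + 1

    singleton_keys = {
        LINEAR_SINGLETON_A: LSA,
        LINEAR_SINGLETON_B: LSB,
        CIRCULAR_SINGLETON_A: CSA,
        CIRCULAR_SINGLETON_B: CSB,
    }
    source_codes = {
        code for grp in GROUPS[model] for ln in grp.lines for code in ln
    }
    for comp in components:
        if comp.kind in singleton_keys:
            bump(singleton_keys[comp.kind])
            continue
        rc = classify_component(comp, model)
        if rc is None or rc.structure == "e":
            continue
        bump(rc.code if rc.code in source_codes else NEVER_SOURCE)
    return PathCensus(model, counts)


def group_coefficient(gid: str, w: Fraction, model: Model) -> Fraction:
    """Per-occurrence deduction of a group, e.g. 2w for P, 4w-1 for Q."""
    for grp in GROUPS[model]:
        if grp.gid == gid:
            return _affine(Fraction(w), grp.saving)
    raise KeyError(gid)


def _solve_lexicographic(
    stages: Sequence[tuple[str, Sequence[Mapping[str, int]]]],
    avail: Mapping[str, int],
) -> dict[str, list[int]]:
    """Maximize stage occurrence sums in order, sharing the resource pool.

    ``avail`` maps resource keys; needs on AAA/BBB may additionally draw from
    the LSA/LSB pools.  Returns per-stage line counts.
    """
    lines: list[tuple[int, Mapping[str, int]]] = []
    for si, (_, stage_lines) in enumerate(stages):
        for ln in stage_lines:
            lines.append((si, ln))

    def feasible(need: Mapping[str, int]) -> bool:
        for code, mult in need.items():
            pool = avail.get(code, 0)
            if code == "AAA":
                pool += avail.get(LSA, 0)
            elif code == "BBB":
                pool += avail.get(LSB, 0)
            if pool < mult:
                return False
        return True

    live = [(si, ln) for si, ln in lines if feasible(ln)]
    result: dict[str, list[int]] = {
        gid: [0] * len(stage_lines) for gid, stage_lines in stages
    }
    if not live:
        return result

    if len(live) == 1:
        si, ln = live[0]
        count = min(
            (avail.get(c, 0)
             + (avail.get(LSA, 0) if c == "AAA" else 0)
             + (avail.get(LSB, 0) if c == "BBB" else 0)) // m
            for c, m in ln.items()
        )
        gid, stage_lines = stages[si]
        result[gid][stage_lines.index(ln)] = count
        return result

    # Resource rows: plain classes capped directly; AAA/LSA and BBB/LSB get a
    # pooled cap plus an LSA/LSB-only cap so singleton pairings stay bounded.
    resources = sorted({c for _, ln in live for c in ln})
    rows: list[tuple[tuple[str, ...], int]] = []
    for code in resources:
        if code == "AAA":
            rows.append((("AAA", LSA), avail.get("AAA", 0) + avail.get(LSA, 0)))
        elif code == "BBB":
            rows.append((("BBB", LSB), avail.get("BBB", 0) + avail.get(LSB, 0)))
        else:
            rows.append(((code,), avail.get(code, 0)))

    n = len(live)
    a_res = np.zeros((len(rows), n))
    for j, (si, ln) in enumerate(live):
        for i, (codes, _) in enumerate(rows):
            a_res[i, j] = sum(ln.get(c, 0) for c in codes)
    ub_res = np.array([cap for _, cap in rows], dtype=float)
    bound = max(int(ub_res.max()), 0)

    fixed: list[tuple[np.ndarray, int]] = []
    stage_vec: dict[int, np.ndarray] = {}
    for si in range(len(stages)):
        vec = np.array([1.0 if s == si else 0.0 for s, _ in live])
        if vec.any():
            stage_vec[si] = vec

    from scipy.optimize import Bounds

    def solve(objective: np.ndarray):
        constraints = [LinearConstraint(a_res, -np.inf, ub_res)]
        for vec, val in fixed:
            constraints.append(LinearConstraint(vec[None, :], val, val))
        res = milp(
            c=-objective,
            constraints=constraints,
            integrality=np.ones(n),
            bounds=Bounds(0, bound),
        )
        if res.status != 0:  # pragma: no cover - tiny feasible systems
            raise RuntimeError(f"group maximization failed: {res.message}")
        return int(round(-res.fun)), res.x

    counts = np.zeros(n)
    for si in range(len(stages)):
        if si not in stage_vec:
            continue
        opt, counts = solve(stage_vec[si])
        fixed.append((stage_vec[si], opt))

    # Tie-break: among maximizing solutions prefer explicit singleton
    # pairings over recombination lines fed from the singleton pools, so the
    # reported disjoint-pair counts follow their definition.
    pair_pref = np.array(
        [1.0 if ln in _PAIR_LINES else 0.0 for _, ln in live]
    )
    if pair_pref.any():
        _, counts = solve(pair_pref)

    for j, (si, ln) in enumerate(live):
        gid, stage_lines = stages[si]
        result[gid][stage_lines.index(ln)] += int(round(counts[j]))
    return result


def maximize_groups(
    census: PathCensus | Mapping[str, int], w: Fraction, model: Model | None = None
) -> GroupCounts:
    """Greedy-in-order occurrence counts of the deduction groups.

    Accepts either a :class:`PathCensus` or a plain mapping of class codes to
    counts (``model`` then required).  Groups outside their w-regime are
    forced to zero before maximization.
    """
    w = check_w(w)
    if isinstance(census, PathCensus):
        counts = dict(census.counts)
        model = census.model
    else:
        if model is None:
            raise ValueError("model required when passing a plain census mapping")
        counts = dict(census)

    stages = [
        (grp.gid, list(grp.lines))
        for grp in GROUPS[model]
        if grp.active(w)
    ]
    per_line = _solve_lexicographic(stages, counts)

    per_group = {grp.gid: 0 for grp in GROUPS[model]}
    pair_ls = pair_cs = 0
    for gid, line_counts in per_line.items():
        grp = next(g for g in GROUPS[model] if g.gid == gid)
        for ln, cnt in zip(grp.lines, line_counts):
            if ln == _PAIR_LINES[0]:
                pair_ls += cnt
            elif ln == _PAIR_LINES[1]:
                pair_cs += cnt
            else:
                per_group[gid] += cnt
    return GroupCounts(model, w, per_group, pair_ls, pair_cs)


def deduction(group_counts: GroupCounts, w: Fraction, model: Model) -> Fraction:
    """Total deduction from the component-wise bound.

    Indel: ``2wP + (4w-1)Q + (3w-1)T + wS1 + (2w-1)(S2+2M+N1) + (3w-2)N2``;
    substitution: the same shape over U..Z2 plus ``w (P_LS + P_CS)`` for the
    singleton pairs.
    """
    w = check_w(w)
    total = Fraction(0)
    for grp in GROUPS[model]:
        total += _affine(w, grp.saving) * group_counts.per_group.get(grp.gid, 0)
    if model == "substitution":
        total += w * (group_counts.pair_ls + group_counts.pair_cs)
    return total
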