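"""Exact minimum-cost sorting by uniform-cost search, for tiny instances.

The oracle enumerates genome states reachable by DCJs (cost 1) and
content-modifying operations (cost w) and finds a cheapest sequence sorting
one genome into another.  It is exponential and only meant as ground truth
for validating the closed-form distances on small examples.

Operation semantics follow the weighted rearrangement model:

* a DCJ cuts two adjacencies and rejoins the four open ends differently
  (inversions, translocations, fusions, fissions, excisions,
  (de)circularizations); cuts may not fall between two markers of a label
  (markers absent from the target) unless the audit flag is set;
* a deletion removes a contiguous block of target-absent markers from a
  single adjacency's label; at most one chromosome vanishes at a time;
* an insertion adds a contiguous block of still-missing target markers at
  any single position, or as a whole new chromosome;
* in the substitution model one operation may replace a contiguous block by
  another within one adjacency (or substitute a whole chromosome's content,
  keeping its topology).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Literal, Optional

from .genome_io import Chromosome, Genome, SignedMarker

__all__ = [
    "Move",
    "SearchLimitExceeded",
    "exact_distance",
    "exact_scenario",
    "neighbors",
    "state_from_genome",
    "genome_from_state",
    "canonical_state",
    "apply_dcj_moves",
]

Marker = tuple[str, bool]  # (name, reverse)
Chrom = tuple[bool, tuple[Marker, ...]]  # (circular, markers)
State = tuple[Chrom, ...]
Model = Literal["indel", "substitution"]


class SearchLimitExceeded(RuntimeError):
    """The state cap was hit before the search could finish."""


@dataclass(frozen=True)
class Move:
    kind: Literal["dcj", "insertion", "deletion", "substitution"]
    cost: Fraction
    description: str


def state_from_genome(g: Genome) -> State:
    return tuple(
        (c.circular, tuple((m.name, m.reverse) for m in c.markers))
        for c in g.chromosomes
    )


def genome_from_state(state: State, name: str = "genome") -> Genome:
    return Genome(
        name,
        tuple(
            Chromosome(tuple(SignedMarker(n, r) for n, r in ms), circ)
            for circ, ms in state
            if ms
        ),
    )


def _revflip(ms: tuple[Marker, ...]) -> tuple[Marker, ...]:
    return tuple((n, not r) for n, r in reversed(ms))


def _canon_chrom(chrom: Chrom) -> Chrom:
    circ, ms = chrom
    rev = _revflip(ms)
    if not circ:
        return (circ, min(ms, rev))
    n = len(ms)
    best = min(
        min(ms[i:] + ms[:i] for i in range(n)),
        min(rev[i:] + rev[:i] for i in range(n)),
    )
    return (circ, best)


def canonical_state(state: State) -> State:
    return tuple(sorted(_canon_chrom(c) for c in state if c[1]))


def _chrom_str(chrom: Chrom) -> str:
    circ, ms = chrom
    body = " ".join(("-" if r else "") + n for n, r in ms)
    return f"({body})" if circ else f"o {body} o"


def _linear_cut_positions(ms: tuple[Marker, ...], free, allow_label_cuts: bool):
    for p in range(len(ms) + 1):
        if allow_label_cuts or p == 0 or p == len(ms):
            yield p
        elif not (free(ms[p - 1][0]) and free(ms[p][0])):
            yield p


def _circular_cut_positions(ms: tuple[Marker, ...], free, allow_label_cuts: bool):
    n = len(ms)
    for p in range(n):
        if allow_label_cuts or not (free(ms[p - 1][0]) and free(ms[p][0])):
            yield p


def _dcj_results(state: State, free, allow_label_cuts: bool) -> Iterator[State]:
    """All genomes one DCJ away (label-preserving cuts unless audited)."""
    chroms = list(state)

    def emit(replacing: tuple[int, ...], new_chroms: list[Chrom]) -> State:
        rest = [c for i, c in enumerate(chroms) if i not in replacing]
        return tuple(rest + [c for c in new_chroms if c[1]])

    n = len(chroms)
    cut_cache = []
    for circ, ms in chroms:
        if circ:
            cut_cache.append(list(_circular_cut_positions(ms, free, allow_label_cuts)))
        else:
            cut_cache.append(list(_linear_cut_positions(ms, free, allow_label_cuts)))

    # Two cuts within one chromosome.
    for i, (circ, ms) in enumerate(chroms):
        cuts = cut_cache[i]
        for p1, p2 in itertools.combinations(cuts, 2):
            if not circ:
                seg = ms[p1:p2]
                # inversion
                if seg:
                    yield emit((i,), [(False, ms[:p1] + _revflip(seg) + ms[p2:])])
                # excision of the segment as a circular chromosome
                if seg:
                    yield emit((i,), [(False, ms[:p1] + ms[p2:]), (True, seg)])
            else:
                s1 = ms[p1:p2]
                s2 = ms[p2:] + ms[:p1]
                if s1 and s2:
                    yield emit((i,), [(True, _revflip(s1) + s2)])  # inversion
                    yield emit((i,), [(True, s1), (True, s2)])  # fission
        # single-cut operations
        for p in cuts:
            if not circ and 0 < p < len(ms):
                yield emit((i,), [(False, ms[:p]), (False, ms[p:])])  # fission
            if circ:
                yield emit((i,), [(False, ms[p:] + ms[:p])])  # linearization

    # Cuts in two different chromosomes.
    for i, j in itertools.combinations(range(n), 2):
        ci, mi = chroms[i]
        cj, mj = chroms[j]
        for p in cut_cache[i]:
            for q in cut_cache[j]:
                if not ci and not cj:
                    x1, x2 = mi[:p], mi[p:]
                    y1, y2 = mj[:q], mj[q:]
                    yield emit((i, j), [(False, x1 + y2), (False, y1 + x2)])
                    yield emit(
                        (i, j),
                        [(False, x1 + _revflip(y1)), (False, _revflip(y2) + x2)],
                    )
                elif not ci and cj:
                    s = mj[q:] + mj[:q]
                    yield emit((i, j), [(False, mi[:p] + s + mi[p:])])
                    yield emit((i, j), [(False, mi[:p] + _revflip(s) + mi[p:])])
                elif ci and not cj:
                    s = mi[p:] + mi[:p]
                    yield emit((i, j), [(False, mj[:q] + s + mj[q:])])
                    yield emit((i, j), [(False, mj[:q] + _revflip(s) + mj[q:])])
                else:
                    s1 = mi[p:] + mi[:p]
                    s2 = mj[q:] + mj[:q]
                    yield emit((i, j), [(True, s1 + s2)])
                    yield emit((i, j), [(True, s1 + _revflip(s2))])


def _free_blocks(ms: tuple[Marker, ...], circ: bool, free) -> Iterator[tuple[int, int]]:
    """Maximal runs of target-absent markers, as (start, length)."""
    n = len(ms)
    flags = [free(m[0]) for m in ms]
    if all(flags):
        yield (0, n)
        return
    start = None
    idx = range(n) if not circ else range(n * 2)
    # For circular chromosomes scan twice so a wrapping block is found once.
    seen_wrap = False
    for k in idx:
        i = k % n
        if flags[i] and start is None:
            start = k
        if not flags[i] and start is not None:
            if start < n and not (circ and seen_wrap and start >= n):
                yield (start % n, k - start)
            start = None
        if circ and k >= n and not flags[i]:
            break
    if start is not None and not circ:
        yield (start, n - start)


def _sub_blocks(block: tuple[int, int], n: int) -> Iterator[tuple[int, int]]:
    start, length = block
    for off in range(length):
        for ln in range(1, length - off + 1):
            yield ((start + off) % n, ln)


def _delete(ms: tuple[Marker, ...], circ: bool, start: int, length: int) -> Chrom:
    n = len(ms)
    if start + length <= n:
        return (circ, ms[:start] + ms[start + length:])
    wrap = (start + length) % n
    return (circ, ms[wrap:start])


_INS_CACHE: dict[frozenset, list] = {}


def _insertion_sequences(missing: frozenset[str]) -> list[tuple[Marker, ...]]:
    cached = _INS_CACHE.get(missing)
    if cached is not None:
        return cached
    seqs: list[tuple[Marker, ...]] = []
    for k in range(1, len(missing) + 1):
        for combo in itertools.combinations(sorted(missing), k):
            for perm in itertools.permutations(combo):
                for signs in itertools.product((False, True), repeat=k):
                    seqs.append(tuple(zip(perm, signs)))
    if len(_INS_CACHE) > 4096:
        _INS_CACHE.clear()
    _INS_CACHE[missing] = seqs
    return seqs


def _content_results(
    state: State, target_names: frozenset[str], model: Model,
    maximal_only: bool = True,
) -> Iterator[tuple[State, str]]:
    """States one content-modifying operation away, tagged by kind.

    By default deletions (and the deleted part of substitutions) take whole
    maximal blocks of target-absent markers: a partial deletion leaves an
    adjacent remnant that stays target-absent forever, so extending the
    operation to the full block never costs more (the remnant's later removal
    is simply dropped).  ``maximal_only=False`` restores the exhaustive
    sub-block move set for audit runs.
    """
    free = lambda name: name not in target_names
    present = {n for _, ms in state for n, _ in ms}
    missing = frozenset(target_names - present)
    ins_seqs = _insertion_sequences(missing) if missing else []
    chroms = list(state)

    def emit(i: int, new: Chrom | None) -> State:
        rest = [c for j, c in enumerate(chroms) if j != i]
        if new is not None and new[1]:
            rest.append(new)
        return tuple(rest)

    for i, (circ, ms) in enumerate(chroms):
        blocks = list(_free_blocks(ms, circ, free))
        positions = range(len(ms) + 1) if not circ else range(len(ms))
        # pure insertions at every gap
        for seq in ins_seqs:
            for p in positions:
                yield emit(i, (circ, ms[:p] + seq + ms[p:])), "insertion"
        # deletions of label blocks
        for blk in blocks:
            spans = [blk] if maximal_only else list(_sub_blocks(blk, len(ms)))
            for start, ln in spans:
                base = _delete(ms, circ, start, ln)
                yield emit(i, base), "deletion"
                if model == "substitution":
                    # replace the block in place
                    bcirc, bms = base
                    pos = start if start + ln <= len(ms) else 0
                    for seq in ins_seqs:
                        yield emit(
                            i, (bcirc, bms[:pos] + seq + bms[pos:])
                        ), "substitution"

    # whole new chromosomes
    for seq in ins_seqs:
        yield state + ((False, seq),), "insertion"
        yield state + ((True, seq),), "insertion"


def neighbors(
    state: State,
    target: "Genome | frozenset[str]",
    model: Model,
    w: Fraction,
    allow_label_cuts: bool = False,
) -> Iterator[tuple[State, Move]]:
    """All states one operation away, with the move that reaches them.

    ``target`` may be the target genome or just its marker-name set; only
    the names matter for move legality.  The full sub-block content move set
    is enumerated here (the search itself uses the whole-block reduction).
    """
    if isinstance(target, Genome):
        target_names = frozenset(target.marker_names())
    else:
        target_names = frozenset(target)
    free = lambda name: name not in target_names
    for nxt in _dcj_results(state, free, allow_label_cuts):
        yield nxt, Move("dcj", Fraction(1), "dcj")
    for nxt, kind in _content_results(state, target_names, model, maximal_only=False):
        yield nxt, Move(kind, Fraction(w), kind)


def _count_blocks(chroms, is_hit) -> int:
    """Maximal runs of markers satisfying ``is_hit`` across chromosomes."""
    total = 0
    for circ, ms in chroms:
        flags = [is_hit(n) for n, _ in ms]
        if not any(flags):
            continue
        if all(flags):
            total += 1
            continue
        if circ:
            total += sum(
                1 for i, f in enumerate(flags) if f and not flags[i - 1]
            )
        else:
            total += sum(
                1 for i, f in enumerate(flags) if f and (i == 0 or not flags[i - 1])
            )
    return total


def _restricted_dcj_distance(state: State, target: State) -> int:
    """DCJ distance between the two genomes restricted to shared markers.

    This is |G'| - c - b/2 over the adjacency graph on the markers common to
    ``state`` and ``target``.  It lower-bounds the remaining sorting cost:
    a DCJ changes it by at most one, deletions leave the common-marker graph
    untouched, and insertions only grow it (the distance restricted to a
    marker subset never exceeds the full distance, by projection).
    """
    names_s = {n for _, ms in state for n, _ in ms}
    names_t = {n for _, ms in target for n, _ in ms}
    common = names_s & names_t
    if not common:
        return 0

    def matching(genome: State) -> dict:
        match: dict = {}
        for circ, ms in genome:
            kept = [(n, r) for n, r in ms if n in common]
            if not kept:
                continue
            exts = []
            for n, r in kept:
                left = (n, "h") if r else (n, "t")
                right = (n, "t") if r else (n, "h")
                exts.append((left, right))
            pairs = []
            for (l1, r1), (l2, r2) in zip(exts, exts[1:]):
                pairs.append((r1, l2))
            if circ:
                pairs.append((exts[-1][1], exts[0][0]))
            else:
                match[exts[0][0]] = None
                match[exts[-1][1]] = None
            for e1, e2 in pairs:
                match[e1] = e2
                match[e2] = e1
        return match

    match_s = matching(state)
    match_t = matching(target)

    visited: set = set()
    n_cycles = 0
    n_ab = 0

    def walk(start, first):
        """Follow alternating matchings from a telomeric end; return end side."""
        cur, side = start, first
        while True:
            visited.add(cur)
            nxt = (match_s if side == "s" else match_t)[cur]
            if nxt is None:
                return side
            cur = nxt
            visited.add(cur)
            side = "t" if side == "s" else "s"

    for ext, partner in match_s.items():
        if partner is None and ext not in visited:
            end = walk(ext, "t")  # leave through the other genome first
            if end == "t":
                n_ab += 1
    for ext, partner in match_t.items():
        if partner is None and ext not in visited:
            end = walk(ext, "s")
            if end == "s":
                n_ab += 1
    for ext in match_s:
        if ext not in visited:
            cur, side = ext, "s"
            while True:
                visited.add(cur)
                cur = (match_s if side == "s" else match_t)[cur]
                side = "t" if side == "s" else "s"
                if cur == ext and side == "s":
                    break
            n_cycles += 1

    return len(common) - n_cycles - n_ab // 2


def _remaining_cost_bound(
    state: State,
    target_chroms: State,
    target_names: frozenset[str],
    model: Model,
    p: int,
    q: int,
) -> int:
    """Admissible lower bound (in 1/q units) on the cost still to pay.

    With D maximal blocks of target-absent markers in the current genome and
    I maximal blocks of still-missing markers in the target, any scenario
    performs m_d deletions and m_i insertions (one contiguous block each) and
    enough DCJs to merge the D blocks down to m_d and to split what becomes
    the I blocks from m_i insertions; one DCJ merges (or splits) at most two
    blocks.  Substitutions may delete and insert at once.
    """
    present = {n for _, ms in state for n, _ in ms}
    d_blocks = _count_blocks(state, lambda n: n not in target_names)
    i_blocks = _count_blocks(target_chroms, lambda n: n not in present)
    sorting = _restricted_dcj_distance(state, target_chroms)
    if d_blocks == 0 and i_blocks == 0:
        return q * sorting
    best = None
    md_range = range(1, d_blocks + 1) if d_blocks else (0,)
    mi_range = range(1, i_blocks + 1) if i_blocks else (0,)
    for md in md_range:
        for mi in mi_range:
            content = max(md, mi) if model == "substitution" else md + mi
            dcjs = max(-((d_blocks - md) // -2), -((i_blocks - mi) // -2))
            cost = p * content + q * dcjs
            if best is None or cost < best:
                best = cost
    # The sorting DCJs of the common-marker graph may coincide with the
    # merge/split DCJs counted above, so combine by max, not sum; the content
    # operations themselves can safely ride on top of the sorting bound.
    need_content = (
        max(int(d_blocks > 0), int(i_blocks > 0))
        if model == "substitution"
        else int(d_blocks > 0) + int(i_blocks > 0)
    )
    return max(best or 0, q * sorting + p * need_content)


def _search(
    a: Genome,
    b: Genome,
    w: Fraction,
    model: Model,
    max_cost: Fraction | None,
    max_states: int,
    allow_label_cuts: bool,
    keep_parents: bool,
    maximal_content: bool = True,
):
    w = Fraction(w)
    if not keep_parents:
        # The distance is symmetric (reverse a scenario, swapping deletions
        # with insertions); searching toward the genome with fewer unique
        # markers keeps the insertion branching small.
        na = a.marker_names()
        nb = b.marker_names()
        if len(nb - na) > len(na - nb):
            a, b = b, a
    target_names = frozenset(b.marker_names())
    goal_state = state_from_genome(b)
    start = canonical_state(state_from_genome(a))
    goal = canonical_state(goal_state)
    if start == goal:
        return Fraction(0), []

    # All scenario costs are integer combinations k*1 + m*w; carry them as
    # integers in units of 1/q (w = p/q) so the priority queue never touches
    # rational arithmetic.
    p, q = w.numerator, w.denominator
    limit = None
    if max_cost is not None:
        lf = Fraction(max_cost) * q
        limit = lf.numerator // lf.denominator

    free = lambda name: name not in target_names

    h_cache: dict[State, int] = {}

    def h(state: State) -> int:
        val = h_cache.get(state)
        if val is None:
            val = _remaining_cost_bound(state, goal_state, target_names, model, p, q)
            h_cache[state] = val
        return val

    best: dict[State, int] = {start: 0}
    parents: dict[State, tuple[State, Move]] = {}
    counter = itertools.count()
    heap: list[tuple[int, int, int, State]] = [(h(start), next(counter), 0, start)]
    expanded = 0
    dcj_move = Move("dcj", Fraction(1), "dcj")

    while heap:
        _, _, cost, state = heapq.heappop(heap)
        if cost > best.get(state, cost):
            continue
        if state == goal:
            if not keep_parents:
                return Fraction(cost, q), []
            moves = []
            cur = state
            while cur != start:
                cur, mv = parents[cur][0], parents[cur][1]
                moves.append(mv)
            return Fraction(cost, q), list(reversed(moves))
        expanded += 1
        if expanded > max_states:
            raise SearchLimitExceeded(
                f"expanded more than {max_states} states "
                f"(current frontier cost {Fraction(cost, q)})"
            )

        succ: list[tuple[State, int, Move | None]] = []
        seen_raw: set[State] = set()
        for nxt in _dcj_results(state, free, allow_label_cuts):
            if nxt not in seen_raw:
                seen_raw.add(nxt)
                succ.append((nxt, cost + q, dcj_move if keep_parents else None))
        for nxt, kind in _content_results(
            state, target_names, model, maximal_content
        ):
            if nxt not in seen_raw:
                seen_raw.add(nxt)
                mv = Move(kind, w, kind) if keep_parents else None
                succ.append((nxt, cost + p, mv))

        for nxt, ncost, move in succ:
            key = canonical_state(nxt)
            prio = ncost + h(key)
            if limit is not None and prio > limit:
                continue
            prev = best.get(key)
            if prev is None or ncost < prev:
                best[key] = ncost
                if keep_parents:
                    parents[key] = (state, move)
                heapq.heappush(heap, (prio, next(counter), ncost, key))
    return None, []


def exact_distance(
    a: Genome,
    b: Genome,
    w: Fraction,
    model: Model = "indel",
    max_cost: Fraction | None = None,
    max_states: int = 2_000_000,
    allow_label_cuts: bool = False,
    maximal_content: bool = True,
) -> Optional[Fraction]:
    """Minimum cost of a DCJ + content-modifying sequence sorting A into B.

    Returns ``None`` if no scenario exists within ``max_cost`` (a proof that
    the distance exceeds the cap); raises :class:`SearchLimitExceeded` when
    the state budget runs out, never a wrong number.

    ``maximal_content=False`` switches to the exhaustive sub-block content
    move set (audit mode; the default whole-block moves are cost-equivalent).
    """
    cost, _ = _search(
        a, b, w, model, max_cost, max_states, allow_label_cuts, False,
        maximal_content,
    )
    return cost


def exact_scenario(
    a: Genome,
    b: Genome,
    w: Fraction,
    model: Model = "indel",
    max_cost: Fraction | None = None,
    max_states: int = 2_000_000,
) -> tuple[Optional[Fraction], list[Move]]:
    """Like :func:`exact_distance` but also returns one optimal move list."""
    return _search(a, b, w, model, max_cost, max_states, False, True)


def apply_dcj_moves(state: State, rng, n_moves: int) -> State:
    """Apply ``n_moves`` uniformly random DCJs (used by the simulator).

    Cuts are unrestricted (no target, hence no labels to protect).
    """
    free = lambda name: False
    for _ in range(n_moves):
        options = list(_dcj_results(state, free, True))
        if not options:
            break
        state = options[rng.randrange(len(options))]
    return state
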