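"""Random genomes, evolved genome pairs and triples for validation.

The simulator is a test-fixture generator: it produces duplication-free
genomes, applies controlled numbers of DCJs and content-modifying operations
with fresh marker names, and builds genome triples with a tunable set of
markers shared by exactly two of the three genomes (the set that governs
triangular-inequality violations).  Every operation is logged so a scenario
replays deterministically from its seed and its total cost upper-bounds the
computed distance of the resulting pair.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

from .genome_io import Chromosome, Genome, SignedMarker
from .oracle import (
    Move,
    State,
    apply_dcj_moves,
    genome_from_state,
    state_from_genome,
)

__all__ = ["ScenarioLog", "random_genome", "evolve", "make_triple", "worst_case_pair"]


@dataclass
class ScenarioLog:
    """Replayable operation log; content-op costs are priced by total_cost(w)."""

    seed: int
    operations: list[Move] = field(default_factory=list)

    def total_cost(self, w: Fraction) -> Fraction:
        w = Fraction(w)
        return sum(
            (Fraction(1) if op.kind == "dcj" else w for op in self.operations),
            Fraction(0),
        )


def random_genome(
    n_markers: int,
    n_chromosomes: int,
    topology: str = "linear",
    seed: int = 0,
    names: list[str] | None = None,
    genome_name: str = "G",
) -> Genome:
    """Uniformly random signed marker order split into chromosomes."""
    if n_chromosomes > n_markers:
        raise ValueError("more chromosomes than markers")
    rng = random.Random(seed)
    names = list(names) if names is not None else [f"g{i+1}" for i in range(n_markers)]
    if len(names) != n_markers:
        raise ValueError("names length must match n_markers")
    rng.shuffle(names)
    signed = [SignedMarker(n, rng.random() < 0.5) for n in names]
    if n_chromosomes == 0:
        return Genome(genome_name, ())
    # split points
    cuts = sorted(rng.sample(range(1, n_markers), n_chromosomes - 1)) if n_chromosomes > 1 else []
    bounds = [0] + cuts + [n_markers]
    chroms = []
    for lo, hi in zip(bounds, bounds[1:]):
        if topology == "circular":
            circ = True
        elif topology == "linear":
            circ = False
        else:
            circ = rng.random() < 0.5
        chroms.append(Chromosome(tuple(signed[lo:hi]), circ))
    return Genome(genome_name, tuple(chroms))


def _apply_content_op(
    state: State,
    rng: random.Random,
    model: str,
    fresh: "_NameSource",
    allowed: tuple[str, ...] | None = None,
) -> tuple[State, Move]:
    """One random deletion, insertion or substitution with fresh names."""
    chroms = list(state)
    kinds = ["insertion"]
    if chroms:
        kinds.append("deletion")
        if model == "substitution":
            kinds.append("substitution")
    if allowed is not None:
        kinds = [k for k in kinds if k in allowed] or ["insertion"]
    kind = rng.choice(kinds)

    def random_block(k: int) -> tuple:
        return tuple((fresh.next(), rng.random() < 0.5) for _ in range(k))

    if kind == "insertion" or not chroms:
        block = random_block(rng.randint(1, 2))
        if not chroms or rng.random() < 0.25:
            chroms.append((rng.random() < 0.5, block))
        else:
            i = rng.randrange(len(chroms))
            circ, ms = chroms[i]
            p = rng.randrange(len(ms) + (0 if circ else 1))
            chroms[i] = (circ, ms[:p] + block + ms[p:])
        return tuple(chroms), Move("insertion", Fraction(0), "random insertion")

    i = rng.randrange(len(chroms))
    circ, ms = chroms[i]
    start = rng.randrange(len(ms))
    length = min(rng.randint(1, 2), len(ms) - start)
    rest = ms[:start] + ms[start + length:]
    if kind == "deletion":
        chroms[i] = (circ, rest)
    else:
        block = random_block(rng.randint(1, 2))
        chroms[i] = (circ, rest[:start] + block + rest[start:])
    if not chroms[i][1]:
        del chroms[i]
    return tuple(chroms), Move(kind, Fraction(0), f"random {kind}")


class _NameSource:
    def __init__(self, prefix: str, taken: set[str]):
        self.prefix = prefix
        self.taken = taken
        self.n = 0

    def next(self) -> str:
        while True:
            self.n += 1
            name = f"{self.prefix}{self.n}"
            if name not in self.taken:
                self.taken.add(name)
                return name


def evolve(
    genome: Genome,
    n_dcj: int,
    n_content: int,
    model: str = "indel",
    seed: int = 0,
    unique_prefix: str = "u",
    name: str | None = None,
    content_kinds: tuple[str, ...] | None = None,
) -> tuple[Genome, ScenarioLog]:
    """Apply random DCJs and content-modifying operations to a genome.

    Insertions draw fresh marker names from ``unique_prefix`` so the result
    stays duplication-free and marker partitions are unambiguous.  The log
    records one entry per operation; its cost at weight w bounds the
    weighted distance between input and output from above.
    """
    rng = random.Random(seed)
    log = ScenarioLog(seed=seed)
    state = state_from_genome(genome)
    fresh = _NameSource(unique_prefix, set(genome.marker_names()))

    ops = ["dcj"] * n_dcj + ["content"] * n_content
    rng.shuffle(ops)
    for op in ops:
        if op == "dcj":
            if not state:
                raise ValueError("no valid DCJ on an empty genome")
            state = apply_dcj_moves(state, rng, 1)
            log.operations.append(Move("dcj", Fraction(1), "random dcj"))
        else:
            state, mv = _apply_content_op(state, rng, model, fresh, content_kinds)
            log.operations.append(Move(mv.kind, Fraction(1), mv.description))
    out_name = name if name is not None else genome.name + "'"
    return genome_from_state(state, out_name), log


def make_triple(
    n_common: int = 6,
    n_shared_ab: int = 2,
    n_dcj: int = 2,
    model: str = "indel",
    seed: int = 0,
) -> tuple[Genome, Genome, Genome]:
    """A genome triple with ``n_shared_ab`` markers common to A and B only.

    A is random; B evolves from A without deletions (so it keeps all of A's
    markers) plus rearrangements and insertions; C evolves from A after the
    markers destined to be A/B-exclusive are deleted.  With
    ``n_shared_ab = 0`` every marker shared by A and B also occurs in C, the
    regime where the uncorrected triangular inequality provably holds.
    """
    rng = random.Random(seed)
    total = n_common + n_shared_ab
    n_chrom = max(1, 1 + total // 5) if total else 0
    a = random_genome(total, n_chrom, "linear", seed=rng.randrange(2**30),
                      genome_name="A")
    b, _ = evolve(a, n_dcj if a.chromosomes else 0, 1, model,
                  seed=rng.randrange(2**30),
                  unique_prefix="ub", name="B", content_kinds=("insertion",))
    shared_ab = set(sorted(a.marker_names())[:n_shared_ab])
    kept = [
        Chromosome(tuple(m for m in c.markers if m.name not in shared_ab), c.circular)
        for c in a.chromosomes
        if any(m.name not in shared_ab for m in c.markers)
    ]
    c0 = Genome("C0", tuple(kept))
    c, _ = evolve(c0, n_dcj if c0.chromosomes else 0, 1, model,
                  seed=rng.randrange(2**30), unique_prefix="uc", name="C",
                  content_kinds=("insertion",))
    return a, b, c


def worst_case_pair(n: int, prefix: str = "g") -> tuple[Genome, Genome]:
    """The extremal family showing the correction constants are minimal.

    Two circular genomes over n common markers whose adjacency graph is a
    single fully-labeled cycle with 2n vertices (2n runs), so that the
    weighted indel distance equals ``(w+1) n + (w-1)`` and, for n even, the
    substitution distance equals ``(w+2) n/2 + (w-1)``.  Genome A carries the
    common markers in order with one unique marker per adjacency; genome B
    visits them with stride two, which chains all adjacencies into one cycle.
    """
    if n < 1:
        raise ValueError("n must be positive")
    common = [f"{prefix}{i+1}" for i in range(n)]
    a_markers = []
    for i, g in enumerate(common):
        a_markers.append(SignedMarker(g))
        a_markers.append(SignedMarker(f"x{i+1}"))
    a = Genome("A", (Chromosome(tuple(a_markers), circular=True),))

    order = [common[i % n] for i in range(0, 2 * n, 2)]
    # stride 2 visits every marker once for odd n; for even n it yields the
    # two interleaved halves, forming two circular chromosomes.
    chroms: list[Chromosome] = []
    if n % 2 == 1:
        seqs = [order[:n]]
    else:
        seqs = [common[0::2], common[1::2]]
    label = 0
    for seq in seqs:
        ms = []
        for g in seq:
            label += 1
            ms.append(SignedMarker(g))
            ms.append(SignedMarker(f"y{label}"))
        chroms.append(Chromosome(tuple(ms), circular=True))
    b = Genome("B", tuple(chroms))
    return a, b
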