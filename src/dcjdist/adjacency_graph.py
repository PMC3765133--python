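"""Adjacency graph construction, component decomposition and run counting.

For two duplication-free genomes A and B with common marker set G, every
common marker g contributes two extremities, the tail ``g^t`` and the head
``g^h``.  An adjacency of one genome is a pair of consecutive extremities
(or a telomere ``o``) together with the *label*: the possibly-empty block of
unique markers lying between them.  The adjacency graph AG(A, B) is the
bipartite multigraph with one vertex per adjacency and one edge per common
extremity; its connected components are cycles, AA-, BB- and AB-paths, plus
isolated singleton vertices for chromosomes that carry no common marker.

A *run* of a component is a maximal subpath whose labeled vertices all lie in
the same genome; the number of runs Lambda drives the indel- and
substitution-potentials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .genome_io import Genome, MarkerPartition, SignedMarker

__all__ = [
    "Extremity",
    "Adjacency",
    "Component",
    "RunClass",
    "AdjacencyGraph",
    "adjacencies_of",
    "build_graph",
    "decompose",
    "count_runs",
    "classify_component",
]

# An extremity is (marker_name, "t"|"h"); None stands for a telomere.
Extremity = Optional[tuple[str, str]]

Side = Literal["A", "B"]
Model = Literal["indel", "substitution"]

# Component kinds.
CYCLE = "cycle"
AA_PATH = "AA-path"
BB_PATH = "BB-path"
AB_PATH = "AB-path"
LINEAR_SINGLETON_A = "linear-singleton-A"
LINEAR_SINGLETON_B = "linear-singleton-B"
CIRCULAR_SINGLETON_A = "circular-singleton-A"
CIRCULAR_SINGLETON_B = "circular-singleton-B"


def _ext_str(ext: Extremity) -> str:
    return "o" if ext is None else f"{ext[0]}^{ext[1]}"


@dataclass(frozen=True)
class Adjacency:
    """One adjacency vertex: two extremities/telomeres plus its label.

    ``gamma1 l gamma2`` and ``gamma2 l-bar gamma1`` denote the same adjacency;
    equality and hashing go through a canonical orientation.  ``circular`` is
    true only for the single adjacency of a circular singleton chromosome.
    """

    gamma1: Extremity
    label: tuple[SignedMarker, ...]
    gamma2: Extremity
    origin: Side
    circular: bool = False

    @property
    def labeled(self) -> bool:
        return bool(self.label)

    def _key(self) -> tuple:
        fwd = (
            self.gamma1,
            tuple((m.name, m.reverse) for m in self.label),
            self.gamma2,
        )
        rev = (
            self.gamma2,
            tuple((m.name, not m.reverse) for m in reversed(self.label)),
            self.gamma1,
        )

        def order(k):
            g1, lab, g2 = k
            return (g1 is None, g1 or ("", ""), lab, g2 is None, g2 or ("", ""))

        return min((fwd, rev), key=order) + (self.origin, self.circular)

    def __eq__(self, other) -> bool:
        return isinstance(other, Adjacency) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def extremities(self) -> tuple[Extremity, Extremity]:
        return (self.gamma1, self.gamma2)

    def __str__(self) -> str:
        lab = " ".join(str(m) for m in self.label)
        if self.circular:
            return f"({lab})"
        mid = f" {lab} " if lab else " "
        return f"{_ext_str(self.gamma1)}{mid}{_ext_str(self.gamma2)}".replace("  ", " ")


@dataclass
class Component:
    """A connected component of the adjacency graph with an ordered walk.

    ``vertices`` alternate between A- and B-adjacencies.  AB-paths are stored
    from the A endpoint to the B endpoint; AA/BB-paths in the reading
    direction that makes their run structure start with an A-run whenever the
    run count is even (realizing the reading-direction equivalences).
    """

    kind: str
    vertices: list[Adjacency]

    @property
    def size(self) -> int:
        return len(self.vertices)

    @property
    def Lambda(self) -> int:
        return count_runs(self)

    @property
    def is_path(self) -> bool:
        return self.kind in (AA_PATH, BB_PATH, AB_PATH)

    @property
    def is_singleton(self) -> bool:
        return self.kind in (
            LINEAR_SINGLETON_A,
            LINEAR_SINGLETON_B,
            CIRCULAR_SINGLETON_A,
            CIRCULAR_SINGLETON_B,
        )

    def labeled_sides(self) -> list[Side]:
        return [v.origin for v in self.vertices if v.labeled]

    def first_run_side(self) -> Optional[Side]:
        sides = self.labeled_sides()
        return sides[0] if sides else None


@dataclass(frozen=True)
class RunClass:
    """Run-structure class of a path component for one model.

    ``structure`` encodes the alternating run pattern: ``e`` (no run), ``A``,
    ``B``, ``AB``, ``BA`` and, for the substitution model (which reduces the
    run count modulo four), also ``ABA``, ``BAB``, ``ABAB``, ``BABA``.  The
    conventional class name concatenates path kind and structure, e.g. an
    AA-path with even runs starting in A is ``AAAB``.
    """

    path_kind: Literal["AA", "BB", "AB"]
    structure: str

    @property
    def code(self) -> str:
        return self.path_kind + self.structure

    def mirrored(self) -> "RunClass":
        """Class obtained by swapping the roles of genomes A and B."""
        swap = {"A": "B", "B": "A"}
        kind = {"AA": "BB", "BB": "AA", "AB": "AB"}[self.path_kind]
        if self.structure == "e":
            return RunClass(kind, "e")
        if self.path_kind == "AB":
            # An AB-path read A->B becomes, after the swap, the reversed walk.
            seq = "".join(swap[c] for c in reversed(self.structure))
        else:
            seq = "".join(swap[c] for c in self.structure)
            # AA/BB reading-direction canonicalization: even-run structures
            # may be read in either direction.
            rev = seq[::-1]
            seq = min(seq, rev)
        return RunClass(kind, seq)


class AdjacencyGraph:
    """The bipartite multigraph AG(A, B) plus its decomposition."""

    def __init__(self, adj_a: list[Adjacency], adj_b: list[Adjacency], n_common: int):
        self.adjacencies_a = adj_a
        self.adjacencies_b = adj_b
        self.n_common = n_common
        self.components: list[Component] = _decompose(adj_a, adj_b)

    @property
    def n_cycles(self) -> int:
        return sum(1 for c in self.components if c.kind == CYCLE)

    @property
    def n_ab_paths(self) -> int:
        return sum(1 for c in self.components if c.kind == AB_PATH)


def _extremity(marker: SignedMarker, end: Literal["left", "right"]) -> Extremity:
    """Extremity found at the given end of a signed marker occurrence."""
    if end == "left":
        return (marker.name, "h" if marker.reverse else "t")
    return (marker.name, "t" if marker.reverse else "h")


def adjacencies_of(
    genome: Genome, partition: MarkerPartition, side: Side
) -> list[Adjacency]:
    """All adjacencies of one genome relative to the common marker set.

    Chromosomes without any common marker become singleton adjacencies
    (``o l o`` if linear, a circular label otherwise).
    """
    common = partition.common
    out: list[Adjacency] = []
    for chrom in genome.chromosomes:
        idx = [i for i, m in enumerate(chrom.markers) if m.name in common]
        if not idx:
            out.append(
                Adjacency(None, chrom.markers, None, side, circular=chrom.circular)
            )
            continue
        ms = chrom.markers
        if chrom.circular:
            # Rotate so a common marker leads; the wrap segment becomes the
            # label between the last and first common markers.
            rot = ms[idx[0]:] + ms[: idx[0]]
            idx = [i for i, m in enumerate(rot) if m.name in common]
            ms = rot
            for j, i in enumerate(idx):
                nxt = idx[(j + 1) % len(idx)]
                seg = ms[i + 1 : nxt] if j + 1 < len(idx) else ms[i + 1 :]
                out.append(
                    Adjacency(
                        _extremity(ms[i], "right"),
                        tuple(seg),
                        _extremity(ms[nxt], "left"),
                        side,
                    )
                )
        else:
            prev_ext: Extremity = None
            prev_pos = -1
            for i in idx:
                out.append(
                    Adjacency(
                        prev_ext,
                        tuple(ms[prev_pos + 1 : i]),
                        _extremity(ms[i], "left"),
                        side,
                    )
                )
                prev_ext = _extremity(ms[i], "right")
                prev_pos = i
            out.append(Adjacency(prev_ext, tuple(ms[prev_pos + 1 :]), None, side))
    return out


def build_graph(a: Genome, b: Genome, partition: MarkerPartition | None = None) -> AdjacencyGraph:
    """Build AG(A, B); one edge per common extremity shared by an A- and a B-adjacency."""
    from .genome_io import marker_partition

    part = partition if partition is not None else marker_partition(a, b)
    adj_a = adjacencies_of(a, part, "A")
    adj_b = adjacencies_of(b, part, "B")
    return AdjacencyGraph(adj_a, adj_b, len(part.common))


def decompose(graph: "AdjacencyGraph") -> list[Component]:
    """The graph's connected components, classified and ordered.

    AB-paths run from their A endpoint, the number of AB-paths is even, and
    every vertex belongs to exactly one component.
    """
    return list(graph.components)


def _decompose(adj_a: list[Adjacency], adj_b: list[Adjacency]) -> list[Component]:
    """Walk the multigraph into ordered components.

    Traversal tracks (side, vertex index, slot) triples so that parallel
    edges (two-vertex cycles) are followed correctly.
    """
    verts = {"A": adj_a, "B": adj_b}
    # extremity -> (side, index, slot)
    slot_of: dict[tuple[str, str, str], tuple[str, int, int]] = {}
    for side in ("A", "B"):
        for i, v in enumerate(verts[side]):
            for s, ext in enumerate(v.extremities()):
                if ext is not None and not v.circular:
                    slot_of[(side, ext[0], ext[1])] = (side, i, s)

    other = {"A": "B", "B": "A"}

    def partner(side: str, ext: Extremity) -> tuple[str, int, int] | None:
        if ext is None:
            return None
        return slot_of.get((other[side], ext[0], ext[1]))

    visited: set[tuple[str, int]] = set()
    components: list[Component] = []

    def walk(side: str, i: int, enter_slot: int) -> tuple[list[tuple[str, int]], bool]:
        """Follow the walk leaving through the slot opposite ``enter_slot``.

        Returns the vertex sequence and whether it closed into a cycle.
        """
        seq = []
        start = (side, i)
        cur_side, cur_i, cur_in = side, i, enter_slot
        while True:
            seq.append((cur_side, cur_i))
            visited.add((cur_side, cur_i))
            out_slot = 1 - cur_in
            ext = verts[cur_side][cur_i].extremities()[out_slot]
            nxt = partner(cur_side, ext)
            if nxt is None:
                return seq, False
            n_side, n_i, n_slot = nxt
            if (n_side, n_i) == start and len(seq) > 1:
                return seq, True
            cur_side, cur_i, cur_in = n_side, n_i, n_slot

    # Singletons and path endpoints first.
    endpoint_slots: list[tuple[str, int, int]] = []
    for side in ("A", "B"):
        for i, v in enumerate(verts[side]):
            if v.circular:
                visited.add((side, i))
                kind = CIRCULAR_SINGLETON_A if side == "A" else CIRCULAR_SINGLETON_B
                components.append(Component(kind, [v]))
            elif v.gamma1 is None and v.gamma2 is None:
                visited.add((side, i))
                kind = LINEAR_SINGLETON_A if side == "A" else LINEAR_SINGLETON_B
                components.append(Component(kind, [v]))
            else:
                for s, ext in enumerate(v.extremities()):
                    if ext is None:
                        endpoint_slots.append((side, i, s))

    for side, i, s in endpoint_slots:
        if (side, i) in visited:
            continue
        seq, _ = walk(side, i, s)
        first, last = seq[0][0], seq[-1][0]
        if first == last:
            kind = AA_PATH if first == "A" else BB_PATH
        else:
            kind = AB_PATH
            if first == "B":
                seq.reverse()
        comp = Component(kind, [verts[s_][i_] for s_, i_ in seq])
        if kind in (AA_PATH, BB_PATH):
            _canonicalize_direction(comp)
        components.append(comp)

    # Remaining vertices lie on cycles.
    for side in ("A", "B"):
        for i in range(len(verts[side])):
            if (side, i) not in visited:
                seq, closed = walk(side, i, 0)
                assert closed, "non-cycle component left after path traversal"
                components.append(Component(CYCLE, [verts[s_][i_] for s_, i_ in seq]))

    return components


def _canonicalize_direction(comp: Component) -> None:
    """Orient AA/BB-paths so that even run structures start with an A-run.

    Odd-run paths start and end with the same-genome run, so their structure
    is direction-invariant and the stored direction is immaterial.
    """
    sides = comp.labeled_sides()
    if sides and len(_blocks(sides)) % 2 == 0 and sides[0] == "B":
        comp.vertices.reverse()


def _blocks(sides: list[Side]) -> list[Side]:
    out: list[Side] = []
    for s in sides:
        if not out or out[-1] != s:
            out.append(s)
    return out


def count_runs(comp: Component) -> int:
    """Number of runs Lambda of a component.

    Clean vertices are transparent: a run extends over them as long as no
    labeled vertex of the other genome intervenes.  For cycles the count is
    circular, so a run may wrap around the arbitrary starting vertex; a cycle
    whose labels all lie in one genome has exactly one run.
    """
    sides = comp.labeled_sides()
    if not sides:
        return 0
    if comp.is_singleton:
        return 1
    blocks = _blocks(sides)
    if comp.kind == CYCLE and len(blocks) > 1 and blocks[0] == blocks[-1]:
        return len(blocks) - 1  # first and last block wrap into one run
    return len(blocks)


def classify_component(comp: Component, model: Model) -> Optional[RunClass]:
    """Run-structure class of a path (or linear singleton) for one model.

    The indel model distinguishes run counts by parity, the substitution
    model modulo four.  Returns ``None`` for cycles and circular singletons,
    which never act as recombination sources.
    """
    kind_map = {
        AA_PATH: "AA",
        BB_PATH: "BB",
        AB_PATH: "AB",
        LINEAR_SINGLETON_A: "AA",
        LINEAR_SINGLETON_B: "BB",
    }
    if comp.kind not in kind_map:
        return None
    pk = kind_map[comp.kind]
    lam = count_runs(comp)
    if lam == 0:
        return RunClass(pk, "e")
    first = comp.first_run_side()
    swap = {"A": "B", "B": "A"}
    if model == "indel":
        if lam % 2 == 1:
            structure = first
        else:
            structure = first + swap[first]
    else:
        r = lam % 4
        if r == 1:
            structure = first
        elif r == 2:
            structure = first + swap[first]
        elif r == 3:
            structure = first + swap[first] + first
        else:
            structure = (first + swap[first]) * 2
    return RunClass(pk, structure)
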