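"""Reading, writing and validating multichromosomal signed-marker genomes.

Genomes are written in a GRIMM-style plain-text dialect: a ``>name`` header
line starts each genome, and every following non-empty line is one chromosome
given as whitespace-separated signed markers (``-`` prefix for reverse
orientation), terminated by ``$`` (linear) or ``@`` (circular).

A genome is a set of chromosomes over named markers; no marker may occur twice
within one genome (duplication-free model).  Chromosomes are unoriented DNA
molecules: a linear chromosome equals its reverse complement, and a circular
chromosome equals any rotation or reflected rotation of itself.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_MARKER_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")

__all__ = [
    "SignedMarker",
    "Chromosome",
    "Genome",
    "MarkerPartition",
    "GenomeStats",
    "GenomeParseError",
    "parse_genomes",
    "write_genomes",
    "marker_partition",
    "genome_stats",
]


class GenomeParseError(ValueError):
    """Raised for malformed genome files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class SignedMarker:
    """A named marker read in forward (``+g``) or reverse (``-g``) orientation."""

    name: str
    reverse: bool = False

    def __post_init__(self):
        if not self.name or not _MARKER_RE.match(self.name) or self.name in ("$", "@"):
            raise ValueError(f"invalid marker name: {self.name!r}")

    def flipped(self) -> "SignedMarker":
        return SignedMarker(self.name, not self.reverse)

    def __str__(self) -> str:
        return ("-" if self.reverse else "") + self.name


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed markers with a linear/circular topology."""

    markers: tuple[SignedMarker, ...]
    circular: bool = False

    def __post_init__(self):
        if not self.markers:
            raise ValueError("empty chromosome")
        object.__setattr__(self, "markers", tuple(self.markers))

    def reversed_(self) -> "Chromosome":
        return Chromosome(tuple(m.flipped() for m in reversed(self.markers)), self.circular)

    def canonical(self) -> tuple:
        """Canonical key: reversal-invariant for linear chromosomes,
        rotation/reflection-invariant for circular ones."""
        fwd = tuple((m.name, m.reverse) for m in self.markers)
        rev = tuple((m.name, not m.reverse) for m in reversed(self.markers))
        if not self.circular:
            return ("L", min(fwd, rev))
        n = len(fwd)
        variants = [fwd[i:] + fwd[:i] for i in range(n)]
        variants += [rev[i:] + rev[:i] for i in range(n)]
        return ("C", min(variants))

    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def __str__(self) -> str:
        body = " ".join(str(m) for m in self.markers)
        return f"{body} {'@' if self.circular else '$'}"


@dataclass(frozen=True)
class Genome:
    """A named, duplication-free collection of chromosomes."""

    name: str
    chromosomes: tuple[Chromosome, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for nm in chrom.marker_names():
                if nm in seen:
                    raise ValueError(f"duplicate marker {nm!r} in genome {self.name!r}")
                seen.add(nm)
        topologies = {c.circular for c in self.chromosomes}
        if len(topologies) > 1:
            logger.warning(
                "genome %r mixes linear and circular chromosomes; "
                "distances are computed per component and remain well-defined",
                self.name,
            )

    def marker_names(self) -> set[str]:
        return {nm for c in self.chromosomes for nm in c.marker_names()}

    def canonical(self) -> tuple:
        """Order-, rotation- and reflection-invariant identity key."""
        return tuple(sorted(c.canonical() for c in self.chromosomes))

    def equivalent(self, other: "Genome") -> bool:
        return self.canonical() == other.canonical()

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class MarkerPartition:
    """Partition of two genomes' markers into common and genome-exclusive sets.

    ``common`` is the set G of shared markers; ``only_a``/``only_b`` hold the
    unique markers of each genome; ``u`` counts all unique markers.
    """

    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def u(self) -> int:
        return len(self.only_a) + len(self.only_b)

    def swapped(self) -> "MarkerPartition":
        return MarkerPartition(self.common, self.only_b, self.only_a)


@dataclass(frozen=True)
class GenomeStats:
    """Chromosome counts of one genome relative to a partner genome."""

    n_linear: int
    n_circular_singleton: int
    n_chromosomes: int


def _parse_marker(token: str, line_no: int) -> SignedMarker:
    reverse = token.startswith("-")
    name = token[1:] if reverse else token
    try:
        return SignedMarker(name, reverse)
    except ValueError as exc:
        raise GenomeParseError(str(exc), line_no) from None


def parse_genomes(text: str | Iterable[str]) -> list[Genome]:
    """Parse a genome file (string or iterable of lines) into Genomes.

    Raises :class:`GenomeParseError` for missing terminators, empty
    chromosomes or duplicated markers, naming the offending line.
    """
    if isinstance(text, str):
        lines: Iterator[tuple[int, str]] = iter(enumerate(text.splitlines(), 1))
    else:
        lines = iter(enumerate(text, 1))

    genomes: list[Genome] = []
    name: str | None = None
    chroms: list[Chromosome] = []
    header_line = 0

    def flush():
        nonlocal name, chroms
        if name is not None:
            try:
                genomes.append(Genome(name, tuple(chroms)))
            except ValueError as exc:
                raise GenomeParseError(str(exc), header_line) from None
        name, chroms = None, []

    for line_no, raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            header_line = line_no
            if not name:
                raise GenomeParseError("empty genome name", line_no)
            continue
        if name is None:
            raise GenomeParseError("chromosome data before any '>' header", line_no)
        tokens = line.split()
        if tokens[-1] not in ("$", "@"):
            raise GenomeParseError(
                f"chromosome line must end with '$' or '@', got {tokens[-1]!r}", line_no
            )
        circular = tokens[-1] == "@"
        body = tokens[:-1]
        if not body:
            raise GenomeParseError("empty chromosome", line_no)
        if any(t in ("$", "@") for t in body):
            raise GenomeParseError("terminator in the middle of a chromosome", line_no)
        chroms.append(Chromosome(tuple(_parse_marker(t, line_no) for t in body), circular))
    flush()
    return genomes


def write_genomes(genomes: Sequence[Genome]) -> str:
    """Serialize genomes to the dialect; inverse of :func:`parse_genomes`."""
    out = []
    for g in genomes:
        out.append(f">{g.name}\n")
        for chrom in g.chromosomes:
            out.append(str(chrom) + "\n")
    return "".join(out)


def marker_partition(a: Genome, b: Genome) -> MarkerPartition:
    """Split the markers of two genomes into G (common), A-only and B-only."""
    ma, mb = a.marker_names(), b.marker_names()
    return MarkerPartition(
        common=frozenset(ma & mb),
        only_a=frozenset(ma - mb),
        only_b=frozenset(mb - ma),
    )


def genome_stats(g: Genome, partner: Genome) -> GenomeStats:
    """Count linear chromosomes and circular singletons of ``g`` w.r.t. ``partner``.

    A circular singleton is a circular chromosome sharing no marker with the
    partner genome.  These counts (L, S, X) appear in the distance diameter
    bounds.
    """
    common = g.marker_names() & partner.marker_names()
    n_linear = sum(1 for c in g.chromosomes if not c.circular)
    n_cs = sum(
        1
        for c in g.chromosomes
        if c.circular and not (set(c.marker_names()) & common)
    )
    return GenomeStats(n_linear, n_cs, g.n_chromosomes)
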