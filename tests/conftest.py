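"""Shared fixtures: the running example, the triangle trio, random tiny pairs."""

from __future__ import annotations

import random

import pytest

from dcjdist import Chromosome, Genome, SignedMarker, parse_genomes

FIGURE_A = ">A\nb s u -c a v -d e $\n"
FIGURE_B = ">B\na w b -x c $\ny d z e $\n"

TRIANGLE_A = ">A\na b c d e $\n"
TRIANGLE_B = ">B\na c -d b e $\n"
TRIANGLE_C = ">C\na e $\n"


def genome(text: str) -> Genome:
    (g,) = parse_genomes(text)
    return g


@pytest.fixture
def fig_a() -> Genome:
    return genome(FIGURE_A)


@pytest.fixture
def fig_b() -> Genome:
    return genome(FIGURE_B)


@pytest.fixture
def tri() -> tuple[Genome, Genome, Genome]:
    return genome(TRIANGLE_A), genome(TRIANGLE_B), genome(TRIANGLE_C)


def random_tiny_pair(
    rng: random.Random,
    max_common: int = 4,
    max_unique: int = 2,
    allow_circular: bool = True,
) -> tuple[Genome, Genome]:
    """A random genome pair with few common and unique markers.

    Designed to exercise every component type: singletons, labeled paths of
    both parities, cycles, and mixed topologies.
    """
    n_common = rng.randint(0, max_common)
    common = [f"g{i}" for i in range(n_common)]

    def build(name: str, uniques: list[str]) -> Genome:
        markers = [SignedMarker(m, rng.random() < 0.5) for m in common + uniques]
        rng.shuffle(markers)
        if not markers:
            return Genome(name, ())
        n_chrom = rng.randint(1, min(2, len(markers)))
        cuts = sorted(rng.sample(range(1, len(markers)), n_chrom - 1))
        bounds = [0] + cuts + [len(markers)]
        chroms = []
        for lo, hi in zip(bounds, bounds[1:]):
            circ = allow_circular and rng.random() < 0.3
            chroms.append(Chromosome(tuple(markers[lo:hi]), circ))
        return Genome(name, tuple(chroms))

    ua = [f"a{i}" for i in range(rng.randint(0, max_unique))]
    ub = [f"b{i}" for i in range(rng.randint(0, max_unique))]
    return build("A", ua), build("B", ub)
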