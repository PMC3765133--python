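# dcjdist

Exact weighted genomic distances between multichromosomal genomes under the
double-cut-and-join (DCJ) model with content-modifying operations, plus the
a-posteriori surcharge that turns them into true metrics.

## The problem

Two genomes rarely carry the same gene content. Comparing them therefore
needs two kinds of events: *rearrangements* — inversions, translocations,
fusions and fissions, all expressible as a DCJ, which cuts two adjacencies
and rejoins the four open ends differently — and *content-modifying*
operations: insertions and deletions of contiguous marker blocks (*indels*),
or the more general *substitution* of one block by another, which models a
region under continuous turnover. In organisms undergoing reductive genome
evolution (obligate intracellular bacteria, endosymbionts), content changes
are believed to be more frequent than rearrangements and should cost less.
`dcjdist` assigns cost 1 to every DCJ and a cost `0 < w <= 1` to every
content-modifying operation and computes, in linear time in the genome size,
the exact minimum cost of transforming one duplication-free genome into
another:

* `d_id(A, B; w)` — the **DCJ-indel distance**,
* `d_sb(A, B; w)` — the **DCJ-substitution distance**.

## The method in brief

Let `G` be the markers common to `A` and `B`. The adjacency graph `AG(A, B)`
has one vertex per adjacency — a pair of consecutive marker extremities
(`g^t`/`g^h`) or telomeres, labeled by the unique markers between them — and
one edge per common extremity. It decomposes into cycles, `AA`-, `BB`- and
`AB`-paths, and singleton vertices for chromosomes with no common marker.
With `c` cycles and `b` AB-paths, the pure DCJ distance is
`d_DCJ = |G| - c - b/2`.

A *run* of a component is a maximal stretch of labeled vertices lying in one
genome; with `Λ` runs, a component can be DCJ-sorted while performing only
`λ = ⌈(Λ+1)/2⌉` indels or `σ = ⌈(Λ+1)/4⌉` substitutions. Summing gives the
component-wise upper bound `d_DCJ + w·Σλ` (resp. `d_DCJ + w·Σσ`, minus `w`
per disjoint pair of same-topology singletons, which one substitution sorts).
Certain *recombinations* — DCJs cutting two different components — beat the
bound; they group into families with fixed savings (`2w`, `4w-1`, `3w-1`,
`w`, `2w-1`, `3w-2`, some of which switch off for `w ≤ 1/2` or `w ≤ 2/3`),
and a greedy maximization of the groups in a fixed order yields the exact
distance. All arithmetic is exact (`fractions.Fraction`), so regime
boundaries at `w = 1/2` and `w = 2/3` are decided precisely.

Both distances can violate the triangular inequality (a genome that lost
most of its markers looks deceptively close to everything). Adding
`k · u(A, B)`, where `u` counts markers unique to either genome, restores it
exactly when `k ≥ (w+1)/2` (indel) or `k ≥ (w+2)/4` (substitution).

The package also contains a uniform-cost/A* search oracle that computes the
same minimum by brute force on tiny instances, and a simulator producing
random genomes, evolved pairs with logged scenarios, and extremal genome
families — the validation harness for the closed-form distances.

## Worked example

Genome files use a GRIMM-style dialect: `>name` headers, one chromosome per
line, `-` for reverse orientation, `$` linear / `@` circular terminators.

```sh
cat > pair.gen <<'EOF'
>A
b s u -c a v -d e $
>B
a w b -x c $
y d z e $
EOF
dcjdist distance -m indel -w 1/2 --json --correct pair.gen pair.gen
```

prints (abridged):

```json
{
  "model": "indel",
  "w": "1/2",
  "n_common": 5,
  "n_cycles": 0,
  "n_ab_paths": 2,
  "d_dcj": 4,
  "sum_potential": 4,
  "deduction": "0",
  "distance": "6",
  "distance_float": 6.0,
  "k": "3/4",
  "corrected": "45/4"
}
```

Reading it: the five shared markers `a..e` form one BB-path and two
AB-paths (`d_DCJ = 5 - 0 - 2/2 = 4`); the labeled paths carry 2 + 3 runs,
giving indel-potentials 2 + 2; no deduction group applies, so
`d_id = 4 + (1/2)·4 = 6`. With the seven unique markers
(`s,u,v` / `w,x,y,z`) and the minimal constant `k = (w+1)/2 = 3/4`, the
corrected metric is `6 + 7·(3/4) = 45/4`.

`dcjdist inspect` prints the per-component report (kind, size, runs, class),
`dcjdist matrix --correct` writes a PHYLIP matrix over many genomes,
`dcjdist triple` checks the triangle inequality on three genomes, and
`dcjdist oracle` runs the exhaustive search on small inputs.

## Layout

| module | contents |
| --- | --- |
| `genome_io` | dialect parser/writer, marker partitions, chromosome identity |
| `adjacency_graph` | adjacencies, graph decomposition, runs, run classes |
| `potentials` | per-component DCJ costs, λ/σ potentials, upper bounds |
| `recombination` | recombination tables, path census, group maximization |
| `distances` | distance formulas, corrected metrics, bounds, triple checks |
| `oracle` | exact search over genome states (ground truth on tiny inputs) |
| `simulate` | random genomes, evolved pairs, triples, extremal families |
| `cli` | `dcjdist` command-line front end |

See `docs/methods.md` for the model details, parameter semantics and known
limitations.
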