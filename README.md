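# dcjmetric

Genome rearrangement distances for genomes with **unequal gene content**,
and the weight correction that turns them into **metrics**.

Comparative genomics often summarises two genomes as sequences of signed
markers (genes or synteny blocks) and measures their divergence by the
minimum number of rearrangement operations transforming one into the other.
The double-cut-and-join (DCJ) operation — two cuts, one rejoin — subsumes
inversions, translocations, fusions and fissions, and the classical DCJ
distance for equal-content genomes is

    d_DCJ(A, B) = n − (c + b/2),

where *n* is the number of common markers and *c*, *b* are the cycles and
AB-paths of the adjacency graph AG(A, B).  When gene content differs, hybrid
models add content-modifying operations: **indels** (insertion/deletion of a
contiguous block) or the more parsimonious **substitutions** (replace one
contiguous block by another).  The resulting DCJ-indel and DCJ-substitution
distances, however, can violate the triangle inequality: two genomes with
identical content may look *further apart* than either is from a genome
missing most of their markers — a serious obstacle for median computations
and distance-based phylogenetics.

This package implements:

* the **genome model** and a plain-text dialect for signed multichromosomal
  genomes (linear `$` / circular `@` chromosomes, no duplicated markers);
* the **labeled adjacency graph** with its component classification
  (cycles, AB/AA/BB-paths, linear/circular singletons) and the
  vertex-count identity |AG(A,B)| = 2n + L_A + S_A + L_B + S_B;
* **runs and potentials**: the number of runs Λ(P) of unique markers per
  component and the closed forms λ(P) = ⌊Λ/2⌋ + 1 (indel potential) and
  σ(P) = ⌈(Λ+1)/4⌉ (substitution potential), giving the tight upper bounds

      d_DCJ-id(A,B) ≤ d_DCJ(A,B) + Σ_P λ(P),
      d_DCJ-sb(A,B) ≤ d_DCJ(A,B) + Σ_P σ(P);

* the **weight framework** w(ρ) = 1 for DCJs and w(ρ) = p + k·m(ρ) for a
  content operation touching m(ρ) markers, equivalent (for p = 1) to the
  a-posteriori correction

      m(A, B) = d(A, B) + k · u(A, B)

  with u(A,B) the number of unique markers — plus triangle-inequality
  **audits** of genome triples and a grid search for the smallest k that
  makes a family of triples metric;
* **brute-force oracles** validating everything at tiny scale: an exact
  weighted-distance search over whole genomes, an exhaustive optimal-DCJ
  sorting search inside single components (the authority behind λ and σ),
  and an exhaustive triple scan over tiny marker universes.

The audits recover the tight constants empirically: the corrected DCJ-indel
distance is a metric **iff k ≥ 1**, the corrected DCJ-substitution distance
**iff k ≥ 3/4**.

## Worked example

The worst case for the correction is the family A_n, B_n, C where A_n and
B_n are circular genomes interleaving n common markers with n private ones
and C is empty (`dcjmetric gen --family tightness --n 5 -o fam5.txt`):

```
>A5
g1 x1 g2 x2 g3 x3 g4 x4 g5 x5 @
>B5
g1 y1 -g2 y2 -g3 y3 -g4 y4 -g5 y5 @
>C
```

Their adjacency graph is a single 10-vertex cycle in which every vertex is
labeled, so the DCJ-indel bound is (n−1) + λ = 4 + 6 = 10 with u = 10:

```
$ dcjmetric distance A5.txt B5.txt --json
{"model": "dcj-indel", "n": 5, "c": 1, "b": 0, "dcj_distance": 4,
 "potential_sum": 6, "bound_value": 10, "u": 10, "exactness": "bound",
 "k": "1", "corrected": "20"}
```

At k = 3/4 the triangle through the empty genome is still broken
(m(A,B) = 17.5 exceeds m(A,C) + m(B,C) = 8.5 + 8.5 by the violation 1/2,
the value 2n − 2 − 2nk at n = 5), and k = 1 repairs it:

```
$ dcjmetric audit-triple A5.txt B5.txt C.txt --model dcj-indel --k 3/4 --json
{"names": ["A5", "B5", "C"], "model": "dcj-indel", "k": "3/4",
 "m_ab": "35/2", "m_ac": "17/2", "m_bc": "17/2",
 "violation": "1/2", "reduced_check": "1/2", "holds": false}

$ dcjmetric audit-triple A5.txt B5.txt C.txt --model dcj-indel --json
{"names": ["A5", "B5", "C"], "model": "dcj-indel", "k": "1",
 "m_ab": "20", "m_ac": "11", "m_bc": "11",
 "violation": "-2", "reduced_check": "-2", "holds": true}
```

The grid search over the whole family n = 1..200 pins the thresholds:

```
$ dcjmetric min-k --n-max 200 --model dcj-indel
1
$ dcjmetric min-k --n-max 200 --model dcj-substitution
3/4
```

The per-component worst-case table (`dcjmetric table1 --max-size 7`) lists,
for each component size |P|, the DCJ cost ⌊(|P|−1)/2⌋ and the maxima of
Λ, λ and σ, e.g. row 7 → `3 7 4 2`; an exhaustive search over optimal-DCJ
sorting sequences of the all-labeled 7-vertex component independently
returns the same (3 DCJs, 4 runs, 2 substitutions).  The exact brute-force
distance is available for tiny instances, e.g. one substitution turns
`a x b` into `a y b`:

```
$ dcjmetric oracle pa.txt pb.txt --model dcj-substitution
1
```

## Layout

| module | contents |
| --- | --- |
| `dcjmetric.genomes` | markers, chromosomes, genomes, text dialect, marker partitions |
| `dcjmetric.graph` | labeled adjacency graph and component classification |
| `dcjmetric.runs` | runs Λ(P), potentials λ(P), σ(P), worst-case table |
| `dcjmetric.distances` | d_DCJ, hybrid bounds, diameter bounds |
| `dcjmetric.metric` | weight schemes, corrected distances, audits, min-k grid |
| `dcjmetric.oracle` | exact search, component sorting search, exhaustive scans |
| `dcjmetric.fixtures` | tightness family, 7-vertex fixture, random/exhaustive generators |
| `dcjmetric.cli` | `dcjmetric` command-line entry point |

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
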