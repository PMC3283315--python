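# Methods

## Genome model

A genome is a set of chromosomes; a chromosome is an ordered sequence of
signed markers and is linear or circular.  Marker names are opaque strings
and no name may occur twice in a genome (duplicated markers are outside the
model).  A circular chromosome is identified with all its rotations and
with its reverse complement; a linear chromosome with its reverse
complement.  `canonical_form` picks the lexicographically minimal
representative and sorts chromosomes, which gives a content-equality test,
hashable genome states for the search oracles, and a round-trip guarantee
for the text dialect (`parse ∘ write = id` up to canonical form).  The
empty genome is first-class — it is the worst-case third genome in the
triangle-inequality analysis — and single-marker chromosomes are legal in
both topologies.

## Adjacency graph with labels

For a pair (A, B) with common marker set 𝒢, every adjacency of A (pair of
consecutive 𝒢-extremities, or extremity/telomere) is a vertex carrying as
*label* the unique markers lying between the two extremities.  A chromosome
with no common marker collapses to a single labeled vertex: a linear or
circular singleton.  Each common marker contributes one head and one tail
edge, so components alternate sides and are cycles, AB-, AA- or BB-paths,
or singletons.  Counts follow the classical theory: d_DCJ = n − (c + b/2),
the number of AB-paths is even, and the vertex total is
2n + L_A + S_A + L_B + S_B (linear chromosomes contribute telomeres,
circular singletons one vertex each).  Component traversals are serialised
deterministically (paths from their A-side or lexicographically smaller
endpoint, cycles from their smallest vertex); run counting is invariant
under that choice, which the tests verify by recounting over all rotations
and reflections.

## Runs and potentials

Concatenating a component's labels along its traversal gives a string over
the unique markers; a *run* is a maximal block from one genome, and
unlabeled vertices do not interrupt a run.  For cycles labeled on both
sides the count is circular (first and last block merge when on the same
side), which implements the rule of starting to read between a labeled
A-vertex and a labeled B-vertex.  Λ(P) ≤ |P| always.

The potentials used by the distance bounds are

* indel potential λ(P) = ⌊Λ/2⌋ + 1 for Λ ≥ 1 (else 0),
* substitution potential σ(P) = ⌈(Λ+1)/4⌉ for Λ ≥ 1 (else 0).

These closed forms are validated, not assumed: an exhaustive search over
optimal-DCJ sorting sequences (below) reproduces both on every component of
up to 6 vertices under every labeling pattern (252 cases) and on the
7-vertex worst-case fixture.  The per-size worst cases
(⌊(|P|−1)/2⌋ DCJs, Λ = |P|, λ = ⌈(|P|+1)/2⌉, σ = ⌈(|P|+1)/4⌉) are exposed
as a table; the maxima are attained exactly when every vertex is labeled.

## Distances and bounds

The package's headline pairwise values are the component-wise tight upper
bounds d_DCJ + Σλ(P) (DCJ-indel) and d_DCJ + Σσ(P) (DCJ-substitution),
reported with `exactness="bound"`.  The exact hybrid distances additionally
require path-recombination corrections between components; those are out of
scope here and are replaced by the exact search oracle at tiny scale, which
the bounds dominate on every enumerated tiny-universe pair (the equality
fraction is reported by the test suite: about 99% for DCJ-indel and 85% for
DCJ-substitution on the default universe).  Diameter bounds are
2n + L_A + S_A + L_B + S_B for DCJ-indel — reconstructed from the
per-component bound d(P) + λ(P) ≤ |P|, summed via the vertex-count
identity — and ⌈3n/2⌉ + L_A + L_B + S_A + S_B for DCJ-substitution.

## Weight framework and metric correction

Organizational operations (DCJs) weigh 1; a content operation ρ touching
m(ρ) markers weighs p + k·m(ρ) with p > 0, k ≥ 0.  In a parsimonious
scenario every unique marker is touched by exactly one content operation,
so for fixed p the weighted distance is the unweighted one plus k·u(A,B) —
the correction can be applied a posteriori, and all audits exploit this by
computing d once and varying k analytically.  Audits use exact rational
arithmetic (`fractions.Fraction`); no floating-point comparison decides a
violation.  A triple audit reorders the genomes so the largest corrected
value sits on the left and reports the violation m_AB − m_AC − m_BC
together with the equivalent uncorrected test
d_AB − d_AC − d_BC − 2k·|𝒢_AB| (reconstructed reduced form; its sign
provably agrees with the violation whenever no marker is private to the
third genome, and the tests check that agreement on 200 such triples).

`min_k_grid` scans k over {0, step, …, k_max} (default step 0.01, k_max 2)
and returns the smallest k at which no triple of the family is disrupted,
asserting on the way that the passing set is upward-closed (monotonicity of
the correction).  A grid rather than a closed-form infimum is deliberate:
the family thresholds 1 − 1/n and 3/4 − 1/n approach the true constants
from below, so a finite family (n up to 200) plus a 0.01 grid lands exactly
on 1.00 and 0.75.  With the default p = 1; the minimal k for p ≠ 1 is an
open problem and out of scope.

## The tightness family

A_n interleaves common markers g1..gn with private x1..xn on one circular
chromosome; B_n uses the same common markers, all but the first reversed,
interleaved with private y1..yn; C is empty.  This realises the worst case:
AG(A_n, B_n) is a single cycle whose 2n vertices are all labeled
(Λ = 2n, d_DCJ = n − 1), so the DCJ-indel bound is 2n while each genome is
one whole-chromosome deletion away from C.  The constructor verifies the
single-all-labeled-cycle condition, the run count and the DCJ distance at
build time instead of trusting the sign pattern.  The 7-vertex fixture
(A = linear x0 a x1 b x2 c x3, B = circular (a y1 c y2 b y3)) similarly
asserts at construction that it forms one all-labeled AA-path with Λ = 7.

## Oracles

**Exact weighted search.**  Uniform-cost search over canonical genome
states.  Neighbors: every DCJ on the extremity matching (recombinations,
fissions into telomeres, fusions of telomeres); deletions of a contiguous
block of unique markers; insertions of a contiguous block of markers of the
target absent from the current state; and, in the substitution model,
replacements of one such block by another (m counts deleted plus inserted
markers).  Two restrictions keep the search admissible and finite: content
operations never touch markers common to the endpoint pair — those must be
conserved, and allowing their deletion would let scenarios shortcut through
states that break the a-posteriori weight identity — and insertions draw
only from the target's markers (a scenario inserting anything else can be
shortened by dropping the insertion and its matching deletion).  Insertion
blocks are unrestricted in length up to the universe size; capping them
would misprice whole-chromosome insertions.  The default limit is 5
distinct markers per pair.

**Component sorting search.**  Breadth-first search over sequences of
exactly d_DCJ(P) optimal DCJs (each step raises the cycle count by one or
the AB-path count by two) applied to the adjacencies of *either* genome —
a sorting scenario can be split between the two ends, which is how labels
of both genomes accumulate and merge.  Labels enter only through their
side and size, cuts may fall at any marker boundary inside a label, and
leftover label-only fragments become linear singletons.  At the end every
component is a 2-vertex cycle, a 2-vertex AB-path or a singleton; the
minimum total of remaining runs equals λ(P) (each run costs one indel) and
the minimum number of labeled terminal components equals σ(P) (one
substitution erases a terminal A-run/B-run pair).  Restricting the DCJs to
one side is provably insufficient — the fixed opposite-side labels cannot
merge and the 7-vertex fixture would need 3 substitutions instead of 2 —
which is why the search is two-sided.

**Exhaustive triple scan.**  All canonical genomes over a tiny universe
(2 shared markers plus 1 private marker per genome, 113 forms) are
enumerated; exact pairwise distances at p = 1, k = 0 are breadth-first
searches over the operation graph of all genomes over the pair's union
universe (every operation weighs 1), with one edge set per possible
protected common set.  The 113×113 distance and u matrices then yield every
triple audit for any k by integer arithmetic, vectorised over all 113³
triples.  The scan shows genuine violations at k = 0 (worst 2 for
DCJ-indel, 1 for DCJ-substitution) and none at k = 1 respectively k = 3/4,
and the single-pair Dijkstra reproduces its entries on spot checks.

## What the generators emulate — and what they do not

The seeded random generator produces content profiles (n common, n_u
private markers per genome, chromosome counts, topology mix) with uniform
arrangement and orientation; the tightness family is an adversarial
construction.  Neither emulates realistic genome evolution: no length
distributions for synteny blocks, no rate model along a tree, no duplicated
markers, no hotspots.  Passing tests therefore certify the combinatorics
and the metric property of the correction, not biological fidelity of the
distances on real data.

## Numerical and engineering choices

* All audit arithmetic is exact (integers and `Fraction`); b/2 is asserted
  even before dividing.
* Oracle problem sizes: 5-marker pairs for the exact search, 9-vertex
  components for the sorting search, the 113-form universe for the scan —
  chosen so the whole validation suite completes in a few minutes on one
  core while still covering every component shape up to size 6
  exhaustively.
* Distance results of the exact search are memoised under a
  rename-invariant canonical signature of the pair and the weight scheme.
* Degenerate inputs: the empty genome is valid everywhere; a genome facing
  an empty partner decomposes entirely into singletons; empty chromosomes
  are unrepresentable by construction.

## Known limitations

* Pairwise values for the hybrid models are tight upper bounds, not exact
  distances; all metric conclusions drawn from them are cross-checked
  against the exact oracle only at tiny scale.
* No duplicated markers, and no inference of markers from annotation — the
  text dialect is the only input format.
* The minimal-constant search is empirical over a finite family; it
  recovers the proven constants exactly but is not itself a proof.
* p is fixed at 1 in the audits; the correct minimal k for p ≠ 1 is
  unknown.
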