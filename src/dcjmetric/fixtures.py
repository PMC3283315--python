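"""Constructed genome families and seeded random generators.

The tightness family (A_n, B_n, empty C) realises the worst case of the
metric correction: AG(A_n, B_n) is a single cycle in which every vertex is
labeled, so the corrected DCJ-indel distance violates the triangle
inequality for every k < 1 − 1/n, and the DCJ-substitution one for every
k < 3/4 − 1/n (n even).  The constructors verify the structural conditions
instead of trusting the sign pattern.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Iterator, Sequence

from .genomes import Chromosome, Genome, Marker, freeze
from .graph import build_adjacency_graph
from .runs import count_runs


@dataclass(frozen=True)
class TightnessFamilyMember:
    """One triple (A_n, B_n, C) of the tightness family."""

    n: int
    genome_a: Genome
    genome_b: Genome
    genome_c: Genome

    @property
    def triple(self) -> tuple[Genome, Genome, Genome]:
        return (self.genome_a, self.genome_b, self.genome_c)


def make_tightness_member(n: int) -> TightnessFamilyMember:
    """A_n = (g1 x1 … gn xn), B_n = (g1 y1 −g2 y2 … −gn yn), C empty.

    Both are unichromosomal circular genomes with n common and n private
    markers each; construction asserts that AG(A_n, B_n) is one cycle with
    all 2n vertices labeled and DCJ distance n − 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a_seq, b_seq = [], []
    for i in range(1, n + 1):
        a_seq += [Marker(f"g{i}"), Marker(f"x{i}")]
        b_seq += [Marker(f"g{i}", forward=(i == 1)), Marker(f"y{i}")]
    a = Genome(f"A{n}", (Chromosome(tuple(a_seq), circular=True),))
    b = Genome(f"B{n}", (Chromosome(tuple(b_seq), circular=True),))
    c = Genome("C", ())

    graph = build_adjacency_graph(a, b)
    assert len(graph.components) == 1, "family member must be one component"
    comp = graph.components[0]
    assert comp.kind == "cycle" and comp.size == 2 * n
    assert all(v.labeled for v in comp.vertices), "all vertices labeled"
    assert count_runs(comp) == 2 * n
    assert graph.n - (graph.c + graph.b // 2) == n - 1
    return TightnessFamilyMember(n, a, b, c)


def make_tightness_family(n_max: int) -> list[TightnessFamilyMember]:
    return [make_tightness_member(n) for n in range(1, n_max + 1)]


def make_path7_fixture() -> tuple[Genome, Genome]:
    """Genome pair whose adjacency graph is one all-labeled 7-vertex AA-path.

    A = linear x0 a x1 b x2 c x3, B = circular (a y1 c y2 b y3); the pair
    attains the per-component maxima for |P| = 7 (Λ = 7).
    """
    a = Genome("A", (Chromosome(tuple(
        Marker(t) for t in ("x0", "a", "x1", "b", "x2", "c", "x3"))),))
    b = Genome("B", (Chromosome(tuple(
        Marker(t) for t in ("a", "y1", "c", "y2", "b", "y3")),
        circular=True),))
    graph = build_adjacency_graph(a, b)
    assert len(graph.components) == 1
    comp = graph.components[0]
    assert comp.kind == "AA-path" and comp.size == 7
    assert all(v.labeled for v in comp.vertices)
    assert count_runs(comp) == 7
    return a, b


def random_genome_pair(n_common: int, n_unique_each: int,
                       chromosomes: int = 1,
                       topology_mix: float = 0.5,
                       seed: int | None = None) -> tuple[Genome, Genome]:
    """Seeded random pair with n_common shared and n_unique_each private
    markers per genome, split over up to ``chromosomes`` chromosomes,
    each circular with probability ``topology_mix``."""
    if seed is None:
        raise ValueError("an explicit seed is required")
    if min(n_common, n_unique_each) < 0 or chromosomes < 1:
        raise ValueError("sizes must be non-negative, chromosomes >= 1")
    rng = random.Random(seed)
    common = [f"g{i}" for i in range(n_common)]

    def build(name: str, prefix: str) -> Genome:
        order = [Marker(m, rng.random() < 0.5) for m in common]
        rng.shuffle(order)
        for i in range(n_unique_each):
            order.insert(rng.randrange(len(order) + 1),
                         Marker(f"{prefix}{i}", rng.random() < 0.5))
        if not order:
            return Genome(name, ())
        cuts = sorted(rng.sample(range(1, len(order)),
                                 min(chromosomes - 1, len(order) - 1)))
        chroms = []
        for lo, hi in zip([0] + cuts, cuts + [len(order)]):
            chroms.append(Chromosome(tuple(order[lo:hi]),
                                     circular=rng.random() < topology_mix))
        return Genome(name, tuple(chroms))

    return build("A", "x"), build("B", "y")


# ---------------------------------------------------------------------------
# Exhaustive enumeration of tiny genomes (oracle universes)

def _set_partitions(items: list[str]) -> Iterator[list[list[str]]]:
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _chromosome_forms(block: Sequence[str]) -> list[Chromosome]:
    forms: dict[tuple, Chromosome] = {}
    for perm in itertools.permutations(block):
        for signs in itertools.product((True, False), repeat=len(block)):
            seq = tuple(Marker(n, s) for n, s in zip(perm, signs))
            for circ in (False, True):
                chrom = Chromosome(seq, circ).canonical()
                forms.setdefault(chrom.key, chrom)
    return [forms[k] for k in sorted(forms)]


def enumerate_genomes(markers: Sequence[str],
                      name: str = "G") -> list[Genome]:
    """All canonical genomes whose markers form any subset of ``markers``.

    Every signed arrangement into any number of linear/circular chromosomes
    appears exactly once (up to rotation/reflection symmetry).  Intended for
    exhaustive scans over tiny universes.
    """
    out: dict[tuple, Genome] = {}
    markers = sorted(markers)
    for r in range(len(markers) + 1):
        for subset in itertools.combinations(markers, r):
            for partition in _set_partitions(list(subset)):
                per_block = [_chromosome_forms(b) for b in partition]
                for combo in itertools.product(*per_block):
                    g = Genome(name, tuple(combo)).canonical()
                    out.setdefault(freeze(g), g)
    return [out[k] for k in sorted(out)]
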