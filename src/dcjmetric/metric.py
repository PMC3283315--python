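"""Operation weights and the a-posteriori metric correction.

Organizational operations (DCJs) weigh 1; a content-modifying operation ρ
touching m(ρ) markers weighs p + k·m(ρ).  For any k the weighted distance
equals the unweighted one plus k·u(A,B), so the surcharge can be applied
*a posteriori*:  m(A,B) = d(A,B) + k·u(A,B).  This module audits genome
triples for triangle-inequality violations under that correction and finds
the smallest grid k for which a family of triples passes — the route by
which the tight constants k=1 (DCJ-indel) and k=3/4 (DCJ-substitution)
are recovered empirically.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

from .distances import DistanceReport, distance_report
from .genomes import Genome, marker_partition, triple_partition

@dataclass(frozen=True)
class WeightScheme:
    """Weights w = 1 for DCJs and w = p + k·m for content operations."""

    p: Fraction = Fraction(1)
    k: Fraction = Fraction(0)

    def __post_init__(self):
        object.__setattr__(self, "p", Fraction(self.p))
        object.__setattr__(self, "k", Fraction(self.k))
        if self.p <= 0:
            raise ValueError("p must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def content_weight(self, m: int) -> Fraction:
        return self.p + self.k * m


def corrected_distance(report: DistanceReport,
                       scheme: WeightScheme) -> Fraction:
    """A-posteriori corrected value d + k·u for a computed pair report."""
    return Fraction(report.bound_value) + scheme.k * report.u


@dataclass(frozen=True)
class TripleAudit:
    """Triangle-inequality audit of one genome triple.

    Genomes are reordered so that the corrected value m_ab is the largest;
    ``violation`` = m_ab − m_ac − m_bc is positive exactly when the triangle
    inequality is disrupted.  ``reduced_check`` is the equivalent uncorrected
    test d_ab − d_ac − d_bc − 2k·|G_AB| (G_AB = markers common to exactly
    the first two genomes), whose sign agrees with ``violation`` whenever no
    marker is private to the third genome.
    """

    names: tuple[str, str, str]
    model: str
    k: Fraction
    m_ab: Fraction
    m_ac: Fraction
    m_bc: Fraction
    violation: Fraction
    reduced_check: Fraction

    @property
    def holds(self) -> bool:
        return self.violation <= 0


PairDistance = Callable[[Genome, Genome], int]


def _pair_distance(model: str, scheme: WeightScheme,
                   backend: str) -> PairDistance:
    if backend == "bound":
        return lambda x, y: distance_report(x, y, model).bound_value
    if backend == "oracle":
        from .oracle import exact_distance_search

        base = WeightScheme(scheme.p, Fraction(0))

        def exact(x: Genome, y: Genome) -> Fraction:
            return exact_distance_search(x, y, model, base)

        return exact
    raise ValueError(f"unknown backend {backend!r}")


def audit_triple(a: Genome, b: Genome, c: Genome, model: str,
                 scheme: WeightScheme,
                 backend: str = "bound") -> TripleAudit:
    """Audit one triple under m = d + k·u, largest corrected value first."""
    dist = _pair_distance(model, scheme, backend)
    k = scheme.k
    genomes = (a, b, c)
    d = {}
    m = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        d[(i, j)] = Fraction(dist(genomes[i], genomes[j]))
        m[(i, j)] = d[(i, j)] + k * marker_partition(genomes[i],
                                                     genomes[j]).u
    # reorder so the largest corrected value plays the (A, B) role
    orders = {(0, 1): (0, 1, 2), (0, 2): (0, 2, 1), (1, 2): (1, 2, 0)}
    ia, ib, ic = orders[max(m, key=lambda key: m[key])]

    def get(table, i, j):
        return table[(i, j)] if (i, j) in table else table[(j, i)]

    m_ab, m_ac, m_bc = get(m, ia, ib), get(m, ia, ic), get(m, ib, ic)
    d_ab, d_ac, d_bc = get(d, ia, ib), get(d, ia, ic), get(d, ib, ic)
    tp = triple_partition(genomes[ia], genomes[ib], genomes[ic])
    reduced = d_ab - d_ac - d_bc - 2 * k * len(tp.common_ab)
    return TripleAudit(
        names=(genomes[ia].name, genomes[ib].name, genomes[ic].name),
        model=model, k=k,
        m_ab=m_ab, m_ac=m_ac, m_bc=m_bc,
        violation=m_ab - m_ac - m_bc,
        reduced_check=reduced,
    )


def _triple_profile(triple: Sequence[Genome], model: str,
                    scheme: WeightScheme, backend: str):
    """Distances and unique-marker counts of one triple, k-independent."""
    dist = _pair_distance(model, scheme, backend)
    a, b, c = triple
    return (
        (Fraction(dist(a, b)), marker_partition(a, b).u),
        (Fraction(dist(a, c)), marker_partition(a, c).u),
        (Fraction(dist(b, c)), marker_partition(b, c).u),
    )


def _worst_violation(profile, k: Fraction) -> Fraction:
    """Largest corrected value minus the sum of the other two."""
    ms = [d + k * u for d, u in profile]
    return 2 * max(ms) - sum(ms)


def min_k_grid(family: Iterable[Sequence[Genome]], model: str,
               grid_step: Fraction = Fraction(1, 100),
               k_max: Fraction = Fraction(2),
               p: Fraction = Fraction(1),
               backend: str = "bound") -> Fraction:
    """Smallest grid k for which no triple in the family is disrupted.

    The grid is {0, step, 2·step, …, k_max}.  Monotonicity of the correction
    (a passing k implies every larger k passes) is asserted along the way.
    """
    grid_step, k_max = Fraction(grid_step), Fraction(k_max)
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    scheme = WeightScheme(p, Fraction(0))
    profiles = [_triple_profile(t, model, scheme, backend) for t in family]
    if not profiles:
        raise ValueError("family must be non-empty")

    best: Fraction | None = None
    k = Fraction(0)
    while k <= k_max:
        passes = all(_worst_violation(pr, k) <= 0 for pr in profiles)
        if passes and best is None:
            best = k
        if best is not None and not passes:
            raise AssertionError(
                f"monotonicity violated: k={k} fails after k={best} passed"
            )
        k += grid_step
    if best is None:
        raise ValueError(f"no k <= {k_max} satisfies the triangle inequality")
    return best


def conserved_triangle_holds(a: Genome, b: Genome, c: Genome,
                             p: Fraction = Fraction(1)) -> bool:
    """Triangle check d(A,B) <= d(A,C) + d(B,C) at k = 0, exact distances.

    Requires the content condition that A and B share no marker absent from
    C; under it the concatenation of optimal scenarios A→C→B sorts A into B,
    so the inequality holds for the exact weighted distances.  Checked here
    with the brute-force search (both hybrid models give the same verdict
    route; the DCJ-indel model is used).
    """
    tp = triple_partition(a, b, c)
    if tp.common_ab:
        raise ValueError(
            "precondition failed: A and B share markers absent from C: "
            + ", ".join(sorted(tp.common_ab))
        )
    from .oracle import exact_distance_search

    scheme = WeightScheme(Fraction(p), Fraction(0))
    d_ab = exact_distance_search(a, b, "dcj-indel", scheme)
    d_ac = exact_distance_search(a, c, "dcj-indel", scheme)
    d_bc = exact_distance_search(b, c, "dcj-indel", scheme)
    return d_ab <= d_ac + d_bc
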