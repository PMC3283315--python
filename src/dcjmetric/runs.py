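"""Run counting and the indel / substitution potentials of a component.

Concatenating the labels of a component P along its traversal gives a string
over the unique markers of A and B; a *run* is a maximal block of that string
drawn from one genome.  Λ(P) runs can be reduced by accumulating and merging
labels during optimal-DCJ sorting; what remains costs one indel per run or
one substitution per consecutive run pair, which is what the potentials
λ(P) and σ(P) measure.  All values depend only on Λ(P) and |P|.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import Component


def count_runs(component: Component) -> int:
    """Number of runs Λ(P): maximal same-genome blocks of labeled vertices.

    Unlabeled vertices do not interrupt a run (only labels enter the
    concatenated string).  For cycles the count is circular: the first and
    last blocks merge when they lie on the same genome, which realises the
    rule of starting to read between a labeled adjacency of A and one of B.
    """
    sides = [v.side for v in component.vertices if v.labeled]
    if not sides:
        return 0
    runs = 1
    for prev, cur in zip(sides, sides[1:]):
        if cur != prev:
            runs += 1
    if component.is_cycle and runs > 1 and sides[0] == sides[-1]:
        runs -= 1
    return runs


def indel_potential(lambda_runs: int) -> int:
    """λ as a function of Λ: 0 if Λ=0, else ⌊Λ/2⌋ + 1.

    Minimum number of runs (hence indels) left after sorting the component
    with its minimum number of optimal DCJs; validated against the
    exhaustive sorting oracle.
    """
    if lambda_runs < 0:
        raise ValueError("run count must be non-negative")
    if lambda_runs == 0:
        return 0
    return lambda_runs // 2 + 1


def substitution_potential(lambda_runs: int) -> int:
    """σ as a function of Λ: 0 if Λ=0, else ⌈(Λ+1)/4⌉.

    Minimum number of substitutions left after an optimal-DCJ sorting; a
    substitution erases a consecutive A-run/B-run pair at once.  Validated
    against the exhaustive sorting oracle.
    """
    if lambda_runs < 0:
        raise ValueError("run count must be non-negative")
    if lambda_runs == 0:
        return 0
    return -(-(lambda_runs + 1) // 4)


@dataclass(frozen=True)
class RunProfile:
    """Run count and potentials of one component."""

    component: Component
    lambda_runs: int
    indel_potential: int
    substitution_potential: int


def run_profile(component: Component) -> RunProfile:
    lam = count_runs(component)
    assert lam <= component.size, "run count cannot exceed vertex count"
    return RunProfile(component, lam, indel_potential(lam),
                      substitution_potential(lam))


def table1_row(size: int) -> tuple[int, int, int, int]:
    """Per-component worst case for a given vertex count |P|.

    Returns (DCJ cost, max Λ, max λ, max σ) =
    (⌊(|P|−1)/2⌋, |P|, ⌈(|P|+1)/2⌉, ⌈(|P|+1)/4⌉); the maxima are attained
    when every vertex is labeled (Λ = |P|).
    """
    if size < 1:
        raise ValueError("component size must be >= 1")
    return (
        (size - 1) // 2,
        size,
        -(-(size + 1) // 2),
        -(-(size + 1) // 4),
    )
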