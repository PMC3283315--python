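"""Signed multichromosomal genomes without duplicated markers.

A genome is a set of chromosomes; each chromosome is an ordered sequence of
signed markers and is either linear or circular.  Duplicated markers are not
allowed anywhere in a genome.  The module also provides the plain-text genome
dialect (one ``>name`` header per genome, one chromosome per line, ``$``
terminating a linear and ``@`` a circular chromosome) and the marker-set
partitions used when comparing two or three genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple


class GenomeError(ValueError):
    """Invalid genome content (e.g. a duplicated marker)."""


class ParseError(ValueError):
    """Malformed genome text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Marker(NamedTuple):
    """A signed marker: an oriented genomic segment identified by name."""

    name: str
    forward: bool = True

    def reverse(self) -> "Marker":
        return Marker(self.name, not self.forward)

    def __str__(self) -> str:
        return self.name if self.forward else "-" + self.name

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, 0 if self.forward else 1)


def _seq_key(markers: tuple[Marker, ...]) -> tuple:
    return tuple(m.key for m in markers)


def _reverse_seq(markers: tuple[Marker, ...]) -> tuple[Marker, ...]:
    return tuple(m.reverse() for m in reversed(markers))


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed markers, linear or circular."""

    markers: tuple[Marker, ...]
    circular: bool = False

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        if not self.markers:
            raise GenomeError("empty chromosome is not representable")

    def reverse(self) -> "Chromosome":
        return Chromosome(_reverse_seq(self.markers), self.circular)

    def canonical(self) -> "Chromosome":
        """Lexicographically minimal representative.

        Linear chromosomes are invariant under full reversal (the molecule
        read from the other end); circular chromosomes additionally under
        rotation (no distinguished origin).
        """
        seq = self.markers
        if not self.circular:
            best = min(seq, _reverse_seq(seq), key=_seq_key)
            return Chromosome(best, False)
        candidates = []
        for s in (seq, _reverse_seq(seq)):
            for i in range(len(s)):
                candidates.append(s[i:] + s[:i])
        return Chromosome(min(candidates, key=_seq_key), True)

    @property
    def key(self) -> tuple:
        return (1 if self.circular else 0, _seq_key(self.markers))

    def __str__(self) -> str:
        body = " ".join(str(m) for m in self.markers)
        return f"{body} {'@' if self.circular else '$'}"


@dataclass(frozen=True)
class Genome:
    """A named collection of chromosomes; marker names are globally unique."""

    name: str
    chromosomes: tuple[Chromosome, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m.name in seen:
                    raise GenomeError(
                        f"duplicated marker {m.name!r} in genome {self.name!r}"
                    )
                seen.add(m.name)

    def marker_names(self) -> frozenset[str]:
        return frozenset(
            m.name for chrom in self.chromosomes for m in chrom.markers
        )

    @property
    def n_linear(self) -> int:
        return sum(1 for c in self.chromosomes if not c.circular)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def canonical(self) -> "Genome":
        chroms = sorted((c.canonical() for c in self.chromosomes),
                        key=lambda c: c.key)
        return Genome(self.name, tuple(chroms))


def canonical_form(genome: Genome) -> Genome:
    """Canonical representative: rotations/reflections normalised, sorted."""
    return genome.canonical()


def freeze(genome: Genome) -> tuple:
    """Hashable content signature of a genome, ignoring its name."""
    return tuple(c.key for c in genome.canonical().chromosomes)


def genomes_equal(a: Genome, b: Genome) -> bool:
    """Content equality under canonical form (names ignored)."""
    return freeze(a) == freeze(b)


# ---------------------------------------------------------------------------
# Text dialect

def parse_genomes(text: str) -> list[Genome]:
    """Parse the plain-text dialect into a list of genomes.

    ``>name`` starts a genome; each following non-empty, non-comment line is
    one chromosome of whitespace-separated signed markers terminated by ``$``
    (linear) or ``@`` (circular).  ``#`` starts a comment line.
    """
    genomes: list[Genome] = []
    name: str | None = None
    chroms: list[Chromosome] = []

    def flush():
        nonlocal name, chroms
        if name is not None:
            genomes.append(Genome(name, tuple(chroms)))
        name, chroms = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise ParseError("empty genome name", lineno)
            continue
        if name is None:
            raise ParseError("chromosome line before any genome header", lineno)
        tokens = line.split()
        if tokens[-1] not in ("$", "@"):
            raise ParseError(
                "chromosome line lacks a '$' or '@' terminator", lineno
            )
        circular = tokens[-1] == "@"
        markers = []
        for tok in tokens[:-1]:
            if tok in ("$", "@"):
                raise ParseError(f"stray terminator {tok!r} inside line", lineno)
            if tok.startswith("-"):
                mname, fwd = tok[1:], False
            else:
                mname, fwd = tok, True
            if not mname:
                raise ParseError("empty marker token", lineno)
            markers.append(Marker(mname, fwd))
        if not markers:
            raise ParseError("chromosome with no markers", lineno)
        try:
            chroms.append(Chromosome(tuple(markers), circular))
        except GenomeError as exc:
            raise ParseError(str(exc), lineno) from exc
    flush()
    return genomes


def write_genomes(genomes: Iterable[Genome]) -> str:
    """Serialise genomes to the text dialect (round-trips via parse)."""
    out: list[str] = []
    for g in genomes:
        out.append(f">{g.name}")
        for chrom in g.chromosomes:
            out.append(str(chrom))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Marker-set partitions

@dataclass(frozen=True)
class MarkerPartition:
    """Disjoint marker sets of a genome pair: common, A-only, B-only."""

    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def u(self) -> int:
        """Number of unique markers, |A-only| + |B-only|."""
        return len(self.only_a) + len(self.only_b)


def marker_partition(a: Genome, b: Genome) -> MarkerPartition:
    ma, mb = a.marker_names(), b.marker_names()
    return MarkerPartition(ma & mb, ma - mb, mb - ma)


@dataclass(frozen=True)
class TriplePartition:
    """The seven disjoint marker sets of a genome triple.

    ``only_*`` hold markers private to one genome; ``common_xy`` markers
    shared by exactly the two named genomes; ``common_abc`` by all three.
    """

    only_a: frozenset[str]
    only_b: frozenset[str]
    only_c: frozenset[str]
    common_ab: frozenset[str]
    common_bc: frozenset[str]
    common_ac: frozenset[str]
    common_abc: frozenset[str]

    def sets(self) -> tuple[frozenset[str], ...]:
        return (self.only_a, self.only_b, self.only_c, self.common_ab,
                self.common_bc, self.common_ac, self.common_abc)


def triple_partition(a: Genome, b: Genome, c: Genome) -> TriplePartition:
    ma, mb, mc = a.marker_names(), b.marker_names(), c.marker_names()
    return TriplePartition(
        only_a=ma - mb - mc,
        only_b=mb - ma - mc,
        only_c=mc - ma - mb,
        common_ab=(ma & mb) - mc,
        common_bc=(mb & mc) - ma,
        common_ac=(ma & mc) - mb,
        common_abc=ma & mb & mc,
    )
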