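"""Genome data model, text dialect and marker partitions."""

import pytest
from hypothesis import given, settings, strategies as st

from dcjmetric.genomes import (Chromosome, Genome, GenomeError, Marker,
                               ParseError, canonical_form,
                               genomes_equal, marker_partition,
                               parse_genomes, triple_partition,
                               write_genomes)
from dcjmetric.fixtures import random_genome_pair


def lin(*names):
    return Chromosome(tuple(Marker(n.lstrip("-"), not n.startswith("-"))
                            for n in names), circular=False)


def circ(*names):
    return Chromosome(tuple(Marker(n.lstrip("-"), not n.startswith("-"))
                            for n in names), circular=True)


class TestParsing:
    def test_minimal_linear(self):
        (g,) = parse_genomes(">A\na b $\n")
        assert g.name == "A"
        assert g.chromosomes == (lin("a", "b"),)

    def test_circular_with_reverse_marker(self):
        (g,) = parse_genomes(">B\na -b @\n")
        assert g.chromosomes == (circ("a", "-b"),)
        assert g.chromosomes[0].markers[1] == Marker("b", False)

    def test_duplicate_marker_rejected(self):
        with pytest.raises(GenomeError, match="'a'"):
            parse_genomes(">X\na b a $\n")

    def test_missing_terminator_reports_line(self):
        with pytest.raises(ParseError, match="line 3"):
            parse_genomes(">X\na b $\nc d\n")

    def test_comments_blanks_and_multiple_genomes(self):
        genomes = parse_genomes("# header\n>A\na $\n\n>B\n# note\nb @\n")
        assert [g.name for g in genomes] == ["A", "B"]

    def test_empty_genome_round_trip(self):
        text = write_genomes([Genome("E", ())])
        assert text == ">E\n"
        (g,) = parse_genomes(text)
        assert g.chromosomes == ()

    def test_write_single_circular(self):
        assert write_genomes([Genome("G", (circ("a"),))]) == ">G\na @\n"


class TestCanonicalForm:
    def test_circular_rotation(self):
        g = Genome("G", (circ("b", "a"),))
        assert canonical_form(g).chromosomes == (circ("a", "b"),)

    def test_linear_reflection_flips_orientation(self):
        g = Genome("G", (lin("-b", "-a"),))
        assert canonical_form(g).chromosomes == (lin("a", "b"),)

    def test_circular_reflection(self):
        assert genomes_equal(Genome("G", (circ("a", "b"),)),
                             Genome("H", (circ("-b", "-a"),)))

    @pytest.mark.parametrize("seed", range(40))
    def test_idempotent_and_round_trip(self, seed):
        a, b = random_genome_pair(3, 2, chromosomes=3, seed=seed)
        for g in (a, b):
            c1 = canonical_form(g)
            assert canonical_form(c1) == c1
            assert genomes_equal(parse_genomes(write_genomes([g]))[0], g)


class TestValidation:
    def test_duplicate_across_chromosomes(self):
        with pytest.raises(GenomeError):
            Genome("G", (lin("a"), circ("a")))

    def test_reverse_twice_is_identity(self):
        m = Marker("a")
        assert m.reverse().reverse() == m


class TestPartitions:
    def test_equal_content_u_zero(self):
        a = Genome("A", (lin("a", "b"),))
        b = Genome("B", (lin("b", "a"),))
        assert marker_partition(a, b).u == 0

    def test_simple_partition(self):
        a = Genome("A", (lin("a", "x"),))
        b = Genome("B", (lin("a", "y"),))
        p = marker_partition(a, b)
        assert (p.common, p.only_a, p.only_b) == ({"a"}, {"x"}, {"y"})
        assert p.u == 2

    def test_partition_covers_and_disjoint(self):
        a, b = random_genome_pair(4, 3, chromosomes=2, seed=11)
        p = marker_partition(a, b)
        assert p.common | p.only_a == a.marker_names()
        assert p.common | p.only_b == b.marker_names()
        assert not (p.common & p.only_a or p.common & p.only_b
                    or p.only_a & p.only_b)

    def test_triple_all_equal(self):
        g = Genome("G", (lin("a"),))
        tp = triple_partition(g, g, g)
        assert tp.common_abc == {"a"}
        assert all(not s for s in tp.sets()[:-1])

    def test_triple_with_empty_c(self):
        a = Genome("A", (lin("a", "x"),))
        b = Genome("B", (lin("a", "y"),))
        tp = triple_partition(a, b, Genome("C", ()))
        assert tp.common_ab == {"a"}
        assert tp.only_c == tp.common_bc == tp.common_ac == frozenset()
        assert tp.common_abc == frozenset()

    @pytest.mark.parametrize("seed", range(25))
    def test_triple_consistent_with_pairwise(self, seed):
        a, _ = random_genome_pair(3, 2, chromosomes=2, seed=seed)
        b, c = random_genome_pair(2, 2, chromosomes=1, seed=seed + 500)
        tp = triple_partition(a, b, c)
        assert sum(len(s) for s in tp.sets()) == len(
            a.marker_names() | b.marker_names() | c.marker_names())
        assert marker_partition(a, b).u == (
            len(tp.only_a) + len(tp.common_ac)
            + len(tp.only_b) + len(tp.common_bc))


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                max_size=6))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_chromosome_canonical_invariant_under_reversal(spec):
    markers = tuple(Marker(f"m{i}", fwd) for i, (fwd, _) in enumerate(spec))
    for circular in (False, True):
        c = Chromosome(markers, circular)
        assert c.canonical() == c.reverse().canonical()
        if circular:
            rot = Chromosome(markers[1:] + markers[:1], True)
            assert rot.canonical() == c.canonical()
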