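"""Brute-force oracles: exact search, component sorting, exhaustive scan."""

import itertools
from fractions import Fraction

import pytest

from dcjmetric.genomes import marker_partition, parse_genomes
from dcjmetric.metric import WeightScheme
from dcjmetric.oracle import (OracleSizeError, _abs_decompose, _abs_runs,
                              bound_equality_report, component_sorting_search,
                              exact_distance_search, exhaustive_triple_scan,
                              posterior_identity_check,
                              optimal_content_marker_sum, scan_tables,
                              sort_component_search, worst_violation_scan)
from dcjmetric.runs import indel_potential, substitution_potential, table1_row


def genome(text):
    (g,) = parse_genomes(text)
    return g


class TestExactSearch:
    def test_equal_genomes(self):
        g = genome(">A\na b $")
        assert exact_distance_search(g, g, "dcj-indel") == 0

    def test_single_deletion(self):
        d = exact_distance_search(genome(">A\na x b $"), genome(">B\na b $"),
                                  "dcj-indel", WeightScheme())
        assert d == 1

    def test_substitution_cheaper_than_indel(self):
        a, b = genome(">A\na x b $"), genome(">B\na y b $")
        assert exact_distance_search(a, b, "dcj-indel") == 2
        assert exact_distance_search(a, b, "dcj-substitution") == 1

    def test_plain_dcj_transposition(self):
        a, b = genome(">A\na b $"), genome(">B\nb a $")
        assert exact_distance_search(a, b, "dcj") == 2

    def test_symmetric(self):
        a, b = genome(">A\na x b @"), genome(">B\n-a y b $")
        for model in ("dcj-indel", "dcj-substitution"):
            assert (exact_distance_search(a, b, model)
                    == exact_distance_search(b, a, model))

    def test_size_limit(self):
        a = genome(">A\na b c d $")
        b = genome(">B\ne f g $")
        with pytest.raises(OracleSizeError):
            exact_distance_search(a, b, "dcj-indel", max_markers=5)

    def test_whole_chromosome_insertion_single_operation(self):
        empty = genome(">A\n")
        target = genome(">B\na b c d $")
        assert exact_distance_search(empty, target, "dcj-indel") == 1


class TestPosteriorIdentity:
    @pytest.mark.parametrize("idx", range(12))
    def test_posterior_identity_and_marker_sum(self, idx, tiny_pairs_50):
        a, b = tiny_pairs_50[idx]
        for model in ("dcj-indel", "dcj-substitution"):
            assert posterior_identity_check(a, b, model, k=Fraction(1, 2))
            total = optimal_content_marker_sum(
                a, b, model, WeightScheme(1, Fraction(1, 2)))
            assert total == marker_partition(a, b).u


def component_shapes(max_size):
    """Abstract adjacency skeletons of every component kind and size."""
    for m in range(1, max_size // 2 + 1):
        size = 2 * m
        e = [f"e{i}" for i in range(1, size + 1)]
        yield ("cycle",
               [(e[2 * i], e[2 * i + 1]) for i in range(m)],
               [(e[(2 * i + 1) % size], e[(2 * i + 2) % size])
                for i in range(m)])
        yield ("AB-path",
               [(None, e[0])] + [(e[2 * i + 1], e[2 * i + 2])
                                 for i in range(m - 1)],
               [(e[2 * i], e[2 * i + 1]) for i in range(m - 1)]
               + [(e[size - 2], None)])
    for m in range(1, (max_size - 1) // 2 + 1):
        e = [f"e{i}" for i in range(1, 2 * m + 1)]
        a_side = ([(None, e[0])]
                  + [(e[2 * i + 1], e[2 * i + 2]) for i in range(m - 1)]
                  + [(e[2 * m - 1], None)])
        b_side = [(e[2 * i], e[2 * i + 1]) for i in range(m)]
        yield ("AA-path", a_side, b_side)
        yield ("BB-path", b_side, a_side)
    yield ("singleton", [(None, None)], [])
    yield ("singleton", [], [(None, None)])


class TestComponentSorting:
    def test_two_sided_size2_cycle(self):
        res = sort_component_search([("e1", "e2", 1)], [("e1", "e2", 1)])
        assert (res.dcj_cost, res.min_runs, res.min_substitutions) == (
            0, 2, 1)

    def test_unlabeled_components_cost_only_dcjs(self):
        for kind, ea, eb in component_shapes(6):
            adj_a = [(x, y, 0) for x, y in ea]
            adj_b = [(x, y, 0) for x, y in eb]
            res = sort_component_search(adj_a, adj_b)
            assert (res.min_runs, res.min_substitutions) == (0, 0)
            size = len(adj_a) + len(adj_b)
            expected = size // 2 - 1 if kind == "cycle" else (size - 1) // 2
            assert res.dcj_cost == expected

    def test_potentials_match_search_on_all_small_components(self):
        """The authoritative validation of the adopted λ and σ formulas:
        exhaustive agreement on every component of size <= 6 under every
        labeling pattern."""
        for kind, ea, eb in component_shapes(6):
            na = len(ea)
            for labels in itertools.product((0, 1), repeat=na + len(eb)):
                adj_a = [(x, y, labels[i]) for i, (x, y) in enumerate(ea)]
                adj_b = [(x, y, labels[na + i])
                         for i, (x, y) in enumerate(eb)]
                comps, _c, _b = _abs_decompose(adj_a, adj_b)
                assert len(comps) == 1
                lam = _abs_runs(*comps[0])
                res = sort_component_search(adj_a, adj_b)
                assert res.min_runs == indel_potential(lam)
                assert res.min_substitutions == substitution_potential(lam)

    def test_seven_vertex_fixture(self, path7_component):
        res = component_sorting_search(path7_component)
        assert (res.dcj_cost, res.min_runs, res.min_substitutions) == (
            3, 4, 2)
        assert res.dcj_cost == table1_row(7)[0]

    def test_size_limit(self):
        adj_a = [(f"e{i}", f"e{i+1}", 1) for i in range(0, 12, 2)]
        with pytest.raises(OracleSizeError):
            sort_component_search(adj_a, adj_a, max_size=9)


class TestExhaustiveScan:
    def test_distances_match_single_pair_search(self):
        import random

        from dcjmetric.oracle import _rename

        forms, d_id, u_mat = scan_tables("dcj-indel")
        _, d_sb, _ = scan_tables("dcj-substitution")
        rng = random.Random(123)
        for _ in range(8):
            i, j = rng.randrange(len(forms)), rng.randrange(len(forms))
            b = _rename(forms[j], {"pa0": "pb0"}, "B")
            assert exact_distance_search(
                forms[i], b, "dcj-indel") == d_id[i, j]
            assert exact_distance_search(
                forms[i], b, "dcj-substitution") == d_sb[i, j]
            assert marker_partition(forms[i], b).u == u_mat[i, j]

    def test_uncorrected_distances_violate_triangle(self):
        worst, _ = worst_violation_scan("dcj-indel", Fraction(0))
        assert worst > 0
        worst, _ = worst_violation_scan("dcj-substitution", Fraction(0))
        assert worst > 0

    def test_corrected_distances_are_metrics(self):
        worst, _ = worst_violation_scan("dcj-indel", Fraction(1))
        assert worst <= 0
        worst, _ = worst_violation_scan("dcj-substitution", Fraction(3, 4))
        assert worst <= 0

    def test_worst_audit_object(self):
        audit = exhaustive_triple_scan("dcj-indel", Fraction(1, 2))
        assert audit.violation > 0
        assert audit.m_ab >= audit.m_ac and audit.m_ab >= audit.m_bc

    def test_bound_dominates_oracle(self):
        frac, total = bound_equality_report("dcj-indel")
        assert total == 6441 and frac > Fraction(1, 2)
        frac_sb, _ = bound_equality_report("dcj-substitution")
        assert frac_sb > Fraction(1, 2)
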