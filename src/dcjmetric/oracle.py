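"""Brute-force exact computations at tiny scale.

Three independent search oracles back the closed-form machinery:

* ``exact_distance_search`` — uniform-cost search over whole genomes under
  DCJ + indel (or + substitution) operations with weights 1 and p + k·m,
  giving the exact weighted distance for marker universes of a handful of
  markers.
* ``component_sorting_search`` — exhaustive search over optimal-DCJ sorting
  sequences inside one adjacency-graph component, returning the minimum
  number of runs (validating the indel potential λ) and of substitutions
  (validating σ) achievable.
* ``exhaustive_triple_scan`` — enumerates every genome triple over a tiny
  marker universe, computes exact pairwise distances by breadth-first search
  over the operation graph (all operations weigh 1 at p = 1, k = 0; the
  k-surcharge is applied a posteriori, which is exactly what the weight
  framework licenses), and reports the worst triangle-inequality violation.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from heapq import heappop, heappush
from typing import Iterable, Iterator, Sequence

import numpy as np

from .distances import distance_report
from .fixtures import enumerate_genomes
from .genomes import (Chromosome, Genome, Marker, canonical_form, freeze,
                      marker_partition, triple_partition)
from .graph import Component
from .metric import WeightScheme


class OracleSizeError(ValueError):
    """Instance exceeds the configured brute-force limits."""


# ---------------------------------------------------------------------------
# Genome <-> extremity matching (for DCJ enumeration)

def _left_ext(m: Marker) -> tuple[str, str]:
    return (m.name, "t" if m.forward else "h")


def _right_ext(m: Marker) -> tuple[str, str]:
    return (m.name, "h" if m.forward else "t")


def _to_matching(genome: Genome) -> tuple[set[frozenset], set[tuple]]:
    """Adjacency set and free (telomeric) extremities of a genome."""
    adjs: set[frozenset] = set()
    frees: set[tuple] = set()
    for chrom in genome.chromosomes:
        ms = chrom.markers
        if chrom.circular:
            for i in range(len(ms)):
                adjs.add(frozenset((_right_ext(ms[i]),
                                    _left_ext(ms[(i + 1) % len(ms)]))))
        else:
            frees.add(_left_ext(ms[0]))
            frees.add(_right_ext(ms[-1]))
            for i in range(len(ms) - 1):
                adjs.add(frozenset((_right_ext(ms[i]), _left_ext(ms[i + 1]))))
    return adjs, frees


def _from_matching(adjs: Iterable[frozenset],
                   marker_names: Iterable[str]) -> tuple[Chromosome, ...]:
    partner: dict[tuple, tuple] = {}
    for adj in adjs:
        x, y = tuple(adj)
        partner[x], partner[y] = y, x
    names = sorted(marker_names)
    visited: set[str] = set()
    chroms: list[Chromosome] = []

    frees = sorted(e for g in names for e in ((g, "t"), (g, "h"))
                   if e not in partner)
    for start in frees:
        if start[0] in visited:
            continue
        seq: list[Marker] = []
        cur = start
        while True:
            g, end = cur
            seq.append(Marker(g, end == "t"))
            visited.add(g)
            other = (g, "h" if end == "t" else "t")
            if other not in partner:
                break
            cur = partner[other]
        chroms.append(Chromosome(tuple(seq), circular=False))
    for g0 in names:
        if g0 in visited:
            continue
        seq = []
        cur = (g0, "t")
        while True:
            g, end = cur
            seq.append(Marker(g, end == "t"))
            visited.add(g)
            other = (g, "h" if end == "t" else "t")
            nxt = partner[other]
            if nxt[0] == g0:
                break
            cur = nxt
        chroms.append(Chromosome(tuple(seq), circular=True))
    return tuple(chroms)


def _dcj_neighbors(genome: Genome) -> Iterator[Genome]:
    """All genomes reachable by one DCJ (two cuts and a rejoin, including
    fissions into telomeres and fusions of telomeres)."""
    adjs, frees = _to_matching(genome)
    names = genome.marker_names()
    adj_list = sorted(adjs, key=lambda a: sorted(a))
    free_list = sorted(frees)
    seen: set[tuple] = set()

    def emit(new_adjs: set[frozenset]) -> Iterator[Genome]:
        g = Genome(genome.name, _from_matching(new_adjs, names)).canonical()
        key = freeze(g)
        if key not in seen:
            seen.add(key)
            yield g

    for a1, a2 in itertools.combinations(adj_list, 2):
        p, q = tuple(a1)
        r, s = tuple(a2)
        for pair in ((frozenset((p, r)), frozenset((q, s))),
                     (frozenset((p, s)), frozenset((q, r)))):
            yield from emit((adjs - {a1, a2}) | set(pair))
    for a1 in adj_list:
        p, q = tuple(a1)
        for f in free_list:
            yield from emit((adjs - {a1}) | {frozenset((p, f))})
            yield from emit((adjs - {a1}) | {frozenset((q, f))})
        yield from emit(adjs - {a1})  # fission into two telomeres
    for f1, f2 in itertools.combinations(free_list, 2):
        yield from emit(adjs | {frozenset((f1, f2))})


# ---------------------------------------------------------------------------
# Content-modifying neighbors

def _insertion_blocks(insertable: Sequence[str],
                      max_block: int | None) -> Iterator[tuple[Marker, ...]]:
    top = len(insertable) if max_block is None else min(max_block,
                                                        len(insertable))
    for r in range(1, top + 1):
        for perm in itertools.permutations(sorted(insertable), r):
            for signs in itertools.product((True, False), repeat=r):
                yield tuple(Marker(n, s) for n, s in zip(perm, signs))


def _content_neighbors(genome: Genome, insertable: frozenset[str],
                       model: str, max_block: int | None = None,
                       protected: frozenset[str] = frozenset()
                       ) -> Iterator[tuple[Genome, int]]:
    """(neighbor, m) for every deletion, insertion and — in the
    substitution model — every proper block substitution.  ``m`` counts the
    deleted plus inserted markers; duplicate target states keep their
    minimum m.

    Content operations never touch ``protected`` markers (the markers
    common to the compared pair): every unique marker is affected by
    exactly one content operation in a parsimonious scenario, which is what
    makes the weighted distance equal the unweighted one plus k·u."""
    chroms = genome.chromosomes
    best: dict[tuple, tuple[Genome, int]] = {}

    def emit(new_chroms: Sequence[Chromosome], m: int):
        g = Genome(genome.name, tuple(new_chroms)).canonical()
        key = freeze(g)
        if key not in best or m < best[key][1]:
            best[key] = (g, m)

    def replaced(ci: int, chrom: Chromosome | None) -> list[Chromosome]:
        out = list(chroms[:ci]) + list(chroms[ci + 1:])
        if chrom is not None:
            out.append(chrom)
        return out

    def deletable(block: Sequence[Marker]) -> bool:
        return not any(m.name in protected for m in block)

    blocks = list(_insertion_blocks(sorted(insertable), max_block))
    subs = model == "dcj-substitution"

    # deletions, and substitutions sharing the deletion site
    for ci, chrom in enumerate(chroms):
        ms, L = chrom.markers, len(chrom.markers)
        if chrom.circular:
            if deletable(ms):
                emit(replaced(ci, None), L)  # delete the whole chromosome
                if subs:
                    for block in blocks:
                        emit(replaced(ci, Chromosome(block, True)),
                             L + len(block))
            for s in range(L):
                for l in range(1, L):
                    cut = [ms[(s + t) % L] for t in range(l)]
                    if not deletable(cut):
                        continue
                    rest = tuple(ms[(s + l + t) % L] for t in range(L - l))
                    emit(replaced(ci, Chromosome(rest, True)), l)
                    if subs:
                        for block in blocks:
                            emit(replaced(ci, Chromosome(rest + block, True)),
                                 l + len(block))
        else:
            for i in range(L):
                for j in range(i + 1, L + 1):
                    if not deletable(ms[i:j]):
                        continue
                    rest = ms[:i] + ms[j:]
                    emit(replaced(ci, Chromosome(rest, False) if rest
                                  else None), j - i)
                    if subs:
                        for block in blocks:
                            emit(replaced(
                                ci, Chromosome(ms[:i] + block + ms[j:],
                                               False)), j - i + len(block))

    # insertions
    for block in blocks:
        emit(list(chroms) + [Chromosome(block, False)], len(block))
        emit(list(chroms) + [Chromosome(block, True)], len(block))
        for ci, chrom in enumerate(chroms):
            ms, L = chrom.markers, len(chrom.markers)
            positions = range(L + 1) if not chrom.circular else range(L)
            for pos in positions:
                emit(replaced(ci, Chromosome(ms[:pos] + block + ms[pos:],
                                             chrom.circular)), len(block))

    yield from best.values()


# ---------------------------------------------------------------------------
# Exact weighted distance by uniform-cost search

_DIST_CACHE: dict[tuple, Fraction] = {}


def _pair_signature(a: Genome, b: Genome) -> tuple:
    """Rename-invariant-ish canonical key of a genome pair."""
    part = marker_partition(a, b)
    mapping: dict[str, str] = {}
    counters = {"c": 0, "a": 0, "b": 0}

    def visit(genome: Genome, private: frozenset[str], tag: str):
        for chrom in genome.canonical().chromosomes:
            for m in chrom.markers:
                if m.name not in mapping:
                    cat = tag if m.name in private else "c"
                    mapping[m.name] = f"{cat}{counters[cat]}"
                    counters[cat] += 1

    visit(a, part.only_a, "a")
    visit(b, part.only_b, "b")
    return (_rename_freeze(a, mapping), _rename_freeze(b, mapping))


def _rename_freeze(genome: Genome, mapping: dict[str, str]) -> tuple:
    chroms = tuple(
        Chromosome(tuple(Marker(mapping[m.name], m.forward)
                         for m in c.markers), c.circular)
        for c in genome.chromosomes
    )
    return freeze(Genome(genome.name, chroms))


def exact_distance_search(a: Genome, b: Genome, model: str,
                          scheme: WeightScheme = WeightScheme(),
                          max_markers: int = 5,
                          max_insert_block: int | None = None,
                          return_operations: bool = False):
    """Minimum total weight of a sequence of operations turning A into B.

    Operations: all DCJs (weight 1); deletions of a contiguous block of
    unique markers, insertions of a contiguous block of markers of B absent
    from the current genome (weight p + k·m); in the substitution model also
    replacements of one such block by another (weight p + k·(deleted +
    inserted)).  Content operations never touch the markers common to A and
    B — those must be conserved, which is what makes each unique marker the
    subject of exactly one content operation in a parsimonious scenario —
    and inserting markers absent from B is never part of an optimal
    sequence; both restrictions also keep the state space finite.

    Returns the distance as a Fraction, or ``(distance, operations)`` with
    ``operations`` a list of ("dcj" | "content", m) steps when
    ``return_operations`` is set.
    """
    if model not in ("dcj", "dcj-indel", "dcj-substitution"):
        raise ValueError(f"unknown model {model!r}")
    universe = a.marker_names() | b.marker_names()
    if len(universe) > max_markers:
        raise OracleSizeError(
            f"{len(universe)} distinct markers exceed limit {max_markers}"
        )
    target_names = b.marker_names()
    protected = frozenset(a.marker_names() & target_names)
    if model == "dcj" and a.marker_names() != target_names:
        raise ValueError("plain DCJ model requires equal marker content")

    cache_key = None
    if not return_operations:
        cache_key = (_pair_signature(a, b), model, scheme.p, scheme.k,
                     max_insert_block)
        if cache_key in _DIST_CACHE:
            return _DIST_CACHE[cache_key]

    start = canonical_form(a)
    start_key, target_key = freeze(start), freeze(b)
    dist: dict[tuple, Fraction] = {start_key: Fraction(0)}
    parents: dict[tuple, tuple] = {}
    genomes: dict[tuple, Genome] = {start_key: start}
    heap: list[tuple[Fraction, int, tuple]] = [(Fraction(0), 0, start_key)]
    counter = itertools.count(1)
    done: set[tuple] = set()

    while heap:
        cost, _, key = heappop(heap)
        if key in done:
            continue
        done.add(key)
        if key == target_key:
            if cache_key is not None:
                _DIST_CACHE[cache_key] = cost
            if return_operations:
                ops: list[tuple[str, int]] = []
                k = key
                while k != start_key:
                    pk, kind, m = parents[k]
                    ops.append((kind, m))
                    k = pk
                return cost, list(reversed(ops))
            return cost
        g = genomes[key]

        def relax(ng: Genome, w: Fraction, kind: str, m: int):
            nk = freeze(ng)
            nc = cost + w
            if nk not in dist or nc < dist[nk]:
                dist[nk] = nc
                genomes[nk] = ng
                parents[nk] = (key, kind, m)
                heappush(heap, (nc, next(counter), nk))

        for ng in _dcj_neighbors(g):
            relax(ng, Fraction(1), "dcj", 0)
        if model != "dcj":
            insertable = frozenset(target_names - g.marker_names())
            for ng, m in _content_neighbors(g, insertable, model,
                                            max_insert_block, protected):
                relax(ng, scheme.content_weight(m), "content", m)

    raise RuntimeError("target genome unreachable (should not happen)")


def posterior_identity_check(a: Genome, b: Genome, model: str,
                             p: Fraction = Fraction(1),
                             k: Fraction = Fraction(1, 2),
                             max_markers: int = 5) -> bool:
    """Exact a-posteriori identity: d_{p,k} = d_{p,0} + k·u(A,B)."""
    p, k = Fraction(p), Fraction(k)
    d_k = exact_distance_search(a, b, model, WeightScheme(p, k), max_markers)
    d_0 = exact_distance_search(a, b, model, WeightScheme(p, Fraction(0)),
                                max_markers)
    return d_k == d_0 + k * marker_partition(a, b).u


def optimal_content_marker_sum(a: Genome, b: Genome, model: str,
                               scheme: WeightScheme,
                               max_markers: int = 5) -> int:
    """Σ m(ρ) over content-modifying steps of one recovered optimal
    scenario (equals u(A,B) whenever the surcharge k is positive)."""
    _, ops = exact_distance_search(a, b, model, scheme, max_markers,
                                   return_operations=True)
    return sum(m for kind, m in ops if kind == "content")


# ---------------------------------------------------------------------------
# Component-level optimal-DCJ sorting search

# An abstract adjacency is (end1, end2, m): ends are opaque extremity tokens
# or None (telomere); m is the label length.  Only label sizes matter to run
# counting, never their content.
AbsAdj = tuple


def _norm_adj(e1, e2, m: int) -> AbsAdj:
    k1 = (0,) if e1 is None else (1, e1)
    k2 = (0,) if e2 is None else (1, e2)
    return (e1, e2, m) if k1 <= k2 else (e2, e1, m)


def _abs_decompose(adj_a: Sequence[AbsAdj], adj_b: Sequence[AbsAdj]):
    """Components of the abstract graph: (kind, traversal[(side, m)]) list
    plus the cycle and AB-path counts."""
    verts = [("A",) + tuple(adj) for adj in adj_a]
    verts += [("B",) + tuple(adj) for adj in adj_b]
    tok: dict[object, dict[str, int]] = {}
    for vid, (side, e1, e2, _m) in enumerate(verts):
        for e in (e1, e2):
            if e is not None:
                tok.setdefault(e, {})[side] = vid
    nbrs: dict[int, list[tuple[int, object]]] = {i: [] for i in
                                                 range(len(verts))}
    for e, sides in sorted(tok.items(), key=lambda kv: repr(kv[0])):
        if len(sides) == 2:
            va, vb = sides["A"], sides["B"]
            nbrs[va].append((vb, e))
            nbrs[vb].append((va, e))

    comps = []
    c = b = 0
    seen: set[int] = set()
    for root in range(len(verts)):
        if root in seen:
            continue
        stack, nodes = [root], {root}
        while stack:
            v = stack.pop()
            for w, _ in nbrs[v]:
                if w not in nodes:
                    nodes.add(w)
                    stack.append(w)
        seen |= nodes
        endpoints = sorted((v for v in nodes if len(nbrs[v]) < 2),
                           key=lambda v: (verts[v][0] != "A", v))
        if len(nodes) == 1 and not nbrs[root]:
            kind = "singleton"
            order = [root]
        elif endpoints:
            sides = "".join(sorted(verts[v][0] for v in endpoints))
            kind = {"AB": "AB-path", "AA": "AA-path", "BB": "BB-path"}[sides]
            order = _abs_walk(endpoints[0], nbrs, len(nodes), cycle=False)
        else:
            kind = "cycle"
            c += 1
            order = _abs_walk(min(nodes), nbrs, len(nodes), cycle=True)
        if kind == "AB-path":
            b += 1
        comps.append((kind, [(verts[v][0], verts[v][3]) for v in order]))
    return comps, c, b


def _abs_walk(start: int, nbrs, size: int, cycle: bool) -> list[int]:
    order = [start]
    used: set[tuple] = set()
    cur = start
    while True:
        step = None
        for w, e in sorted(nbrs[cur], key=lambda t: (t[0], repr(t[1]))):
            eid = (min(cur, w), max(cur, w), e)
            if eid not in used:
                step = (w, eid)
                break
        if step is None:
            break
        w, eid = step
        used.add(eid)
        if cycle and w == start:
            break
        order.append(w)
        cur = w
    assert len(order) == size
    return order


def _abs_runs(kind: str, traversal: list[tuple[str, int]]) -> int:
    sides = [s for s, m in traversal if m > 0]
    if not sides:
        return 0
    runs = 1 + sum(1 for x, y in zip(sides, sides[1:]) if x != y)
    if kind == "cycle" and runs > 1 and sides[0] == sides[-1]:
        runs -= 1
    return runs


def _component_dcj_cost(kind: str, size: int) -> int:
    if kind == "singleton":
        return 0
    if kind == "cycle":
        return size // 2 - 1
    return (size - 1) // 2


def _abs_moves(state: tuple[AbsAdj, ...]) -> Iterator[tuple[AbsAdj, ...]]:
    """All DCJ rewritings of the A-side adjacency multiset: recombinations
    of two adjacencies (labels split at any point), fissions into telomeric
    ends and fusions of telomeric ends."""
    adjs = list(state)

    def rebuild(drop: list[int], add: list[AbsAdj]) -> tuple[AbsAdj, ...]:
        keep = [adj for i, adj in enumerate(adjs) if i not in drop]
        keep += [a for a in add if a != (None, None, 0)]
        return tuple(sorted(keep, key=lambda t: (repr(t[0]), repr(t[1]),
                                                 t[2])))

    for i, j in itertools.combinations(range(len(adjs)), 2):
        g1, g2, m1 = adjs[i]
        g3, g4, m2 = adjs[j]
        for s1 in range(m1 + 1):
            for s2 in range(m2 + 1):
                yield rebuild([i, j], [_norm_adj(g1, g3, s1 + s2),
                                       _norm_adj(g2, g4,
                                                 (m1 - s1) + (m2 - s2))])
                yield rebuild([i, j], [_norm_adj(g1, g4, s1 + (m2 - s2)),
                                       _norm_adj(g3, g2, s2 + (m1 - s1))])
    for i, (g1, g2, m) in enumerate(adjs):
        for s in range(m + 1):
            yield rebuild([i], [_norm_adj(g1, None, s),
                                _norm_adj(None, g2, m - s)])
    for i, j in itertools.combinations(range(len(adjs)), 2):
        g1, g2, m1 = adjs[i]
        g3, g4, m2 = adjs[j]
        for x, xo in ((g1, g2), (g2, g1)):
            if x is not None:
                continue
            for y, yo in ((g3, g4), (g4, g3)):
                if y is not None:
                    continue
                yield rebuild([i, j], [_norm_adj(xo, yo, m1 + m2)])


@dataclass(frozen=True)
class ComponentSortingResult:
    dcj_cost: int
    min_runs: int
    min_substitutions: int


def _sort_key(adj: AbsAdj) -> tuple:
    return (repr(adj[0]), repr(adj[1]), adj[2])


def sort_component_search(adj_a: Sequence[AbsAdj], adj_b: Sequence[AbsAdj],
                          max_size: int = 9) -> ComponentSortingResult:
    """Exhaustive optimal-DCJ sorting of one component.

    Explores every sequence of d_DCJ(P) DCJs, applied to either genome's
    adjacencies (a sorting scenario can be split between the two ends, which
    is how labels of both genomes accumulate), in which each step increases
    the cycle count by one or the AB-path count by two.  Reports the minimum
    achievable total number of remaining runs and of remaining labeled
    terminal components (one substitution erases the A-run/B-run pair of a
    terminal component)."""
    size = len(adj_a) + len(adj_b)
    if size > max_size:
        raise OracleSizeError(f"component size {size} exceeds {max_size}")
    comps, c0, b0 = _abs_decompose(adj_a, adj_b)
    if len(comps) != 1:
        raise ValueError("input must be a single component")
    kind, _ = comps[0]
    depth = _component_dcj_cost(kind, size)

    def pack(adjs: Iterable[AbsAdj]) -> tuple[AbsAdj, ...]:
        return tuple(sorted((_norm_adj(*adj) for adj in adjs),
                            key=_sort_key))

    state0 = (pack(adj_a), pack(adj_b))
    frontier: dict[tuple, tuple[int, int]] = {state0: (c0, b0)}
    for _ in range(depth):
        nxt: dict[tuple, tuple[int, int]] = {}
        for (sa, sb), (c_cur, b_cur) in frontier.items():
            candidates = {(na, sb) for na in _abs_moves(sa)}
            candidates |= {(sa, nb) for nb in _abs_moves(sb)}
            for new_st in candidates:
                if new_st in nxt:
                    continue
                _, c_new, b_new = _abs_decompose(*new_st)
                if (c_new - c_cur, b_new - b_cur) in ((1, 0), (0, 2)):
                    nxt[new_st] = (c_new, b_new)
        frontier = nxt
    assert frontier, "optimal DCJ-sorting must exist"

    min_runs = min_subs = None
    for sa, sb in frontier:
        parts, _, _ = _abs_decompose(sa, sb)
        assert all(len(tr) <= 2 for _, tr in parts), "state must be sorted"
        runs = sum(_abs_runs(kd, tr) for kd, tr in parts)
        subs = sum(1 for kd, tr in parts if _abs_runs(kd, tr) >= 1)
        min_runs = runs if min_runs is None else min(min_runs, runs)
        min_subs = subs if min_subs is None else min(min_subs, subs)
    return ComponentSortingResult(depth, min_runs, min_subs)


def component_sorting_search(component: Component,
                             max_size: int = 9) -> ComponentSortingResult:
    """Run the sorting search on a component of a built adjacency graph."""
    adj_a = [(v.gamma1, v.gamma2, len(v.label))
             for v in component.vertices if v.side == "A"]
    adj_b = [(v.gamma1, v.gamma2, len(v.label))
             for v in component.vertices if v.side == "B"]
    return sort_component_search(adj_a, adj_b, max_size)


# ---------------------------------------------------------------------------
# Exhaustive triple scan over a tiny universe

_SCAN_GRAPH_CACHE: dict[tuple, tuple] = {}
_SCAN_TABLE_CACHE: dict[tuple, tuple] = {}


def _scan_graph(universe: tuple[str, ...], common_pool: tuple[str, ...]):
    """State graphs of all genomes over subsets of ``universe`` with one
    edge per operation (unit weights: p = 1, k = 0).

    Content-operation legality depends on the markers common to the pair
    of genomes being compared (they may not be touched), so one adjacency
    structure is built per candidate protected set — every subset of the
    shared marker pool."""
    key = (universe, common_pool)
    if key in _SCAN_GRAPH_CACHE:
        return _SCAN_GRAPH_CACHE[key]
    states = enumerate_genomes(universe)
    index = {freeze(g): i for i, g in enumerate(states)}
    variants = [frozenset(c) for r in range(len(common_pool) + 1)
                for c in itertools.combinations(common_pool, r)]
    uni = frozenset(universe)
    adj: dict[tuple[str, frozenset], list[list[int]]] = {
        (model, g_set): []
        for model in ("dcj-indel", "dcj-substitution") for g_set in variants
    }
    for g in states:
        dcj = {index[freeze(n)] for n in _dcj_neighbors(g)}
        insertable = uni - g.marker_names()
        for g_set in variants:
            ind = {index[freeze(n)] for n, _m in _content_neighbors(
                g, insertable - g_set, "dcj-indel", protected=g_set)}
            sub = {index[freeze(n)] for n, _m in _content_neighbors(
                g, insertable - g_set, "dcj-substitution", protected=g_set)}
            adj[("dcj-indel", g_set)].append(sorted(dcj | ind))
            adj[("dcj-substitution", g_set)].append(sorted(dcj | ind | sub))
    result = (states, index, adj)
    _SCAN_GRAPH_CACHE[key] = result
    return result


def _bfs(adj: list[list[int]], src: int) -> np.ndarray:
    dist = np.full(len(adj), -1, dtype=np.int64)
    dist[src] = 0
    queue = deque([src])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def _rename(genome: Genome, mapping: dict[str, str], name: str) -> Genome:
    chroms = tuple(
        Chromosome(tuple(Marker(mapping.get(m.name, m.name), m.forward)
                         for m in c.markers), c.circular)
        for c in genome.chromosomes
    )
    return Genome(name, chroms).canonical()


def scan_tables(model: str, n_common: int = 2, n_private: int = 1):
    """Exact pairwise d_{1,0} distances and unique-marker counts between all
    genome forms over a tiny universe (n_common shared markers plus
    n_private markers per genome, private markers always disjoint).

    Returns (forms, D, U): forms are genomes over {g1.., pa..}; D[i, j] is
    the exact model distance between form i (privates "pa*") and form j with
    privates renamed to "pb*"; U[i, j] the corresponding u value.
    """
    key = (model, n_common, n_private)
    if key in _SCAN_TABLE_CACHE:
        return _SCAN_TABLE_CACHE[key]
    if n_common > 2 or n_private > 1:
        raise OracleSizeError("universe too large for the exhaustive scan")
    common = [f"g{i + 1}" for i in range(n_common)]
    pa = [f"pa{i}" for i in range(n_private)]
    pb = [f"pb{i}" for i in range(n_private)]
    forms = enumerate_genomes(common + pa)
    universe = tuple(common + pa + pb)
    states, index, adj = _scan_graph(universe, tuple(common))
    ab = dict(zip(pa, pb))

    n_forms = len(forms)
    target_idx = np.empty(n_forms, dtype=np.int64)
    marker_sets = []
    for j, f in enumerate(forms):
        target_idx[j] = index[freeze(_rename(f, ab, f.name))]
        marker_sets.append(f.marker_names())
    common_parts = [ms & frozenset(common) for ms in marker_sets]

    # the protected set is pair-dependent (markers common to both forms),
    # so one BFS per source and per subset of its shared markers
    D = np.full((n_forms, n_forms), -1, dtype=np.int64)
    for i, f in enumerate(forms):
        src = index[freeze(f)]
        ca = common_parts[i]
        for r in range(len(ca) + 1):
            for sub in itertools.combinations(sorted(ca), r):
                g_set = frozenset(sub)
                dist = _bfs(adj[(model, g_set)], src)
                cols = [j for j in range(n_forms)
                        if ca & common_parts[j] == g_set]
                D[i, cols] = dist[target_idx[cols]]
    assert (D >= 0).all() and (D == D.T).all()

    U = np.empty((n_forms, n_forms), dtype=np.int64)
    for i, ma in enumerate(marker_sets):
        ca = {m for m in ma if not m.startswith("pa")}
        na = len(ma) - len(ca)
        for j, mb in enumerate(marker_sets):
            cb = {m for m in mb if not m.startswith("pa")}
            U[i, j] = na + (len(mb) - len(cb)) + len(ca ^ cb)
    result = (forms, D, U)
    _SCAN_TABLE_CACHE[key] = result
    return result


def worst_violation_scan(model: str, k: Fraction,
                         n_common: int = 2, n_private: int = 1):
    """Worst triangle violation m_xy − m_xz − m_yz over every genome triple
    of the tiny universe, in exact arithmetic.

    Returns (violation, (i, j, l)) with the maximising form indices."""
    k = Fraction(k)
    _forms, D, U = scan_tables(model, n_common, n_private)
    x = k.denominator * D + k.numerator * U
    v = x[:, :, None] - x[:, None, :] - x[None, :, :]
    flat = int(np.argmax(v))
    i, j, l = np.unravel_index(flat, v.shape)
    worst = Fraction(int(v[i, j, l]), k.denominator)
    return worst, (int(i), int(j), int(l))


def exhaustive_triple_scan(model: str, k: Fraction,
                           n_common: int = 2, n_private: int = 1):
    """Audit every triple over the tiny universe; return the worst one."""
    from .metric import TripleAudit

    k = Fraction(k)
    forms, D, U = scan_tables(model, n_common, n_private)
    worst, (i, j, l) = worst_violation_scan(model, k, n_common, n_private)

    pa = [f"pa{t}" for t in range(n_private)]
    a = _rename(forms[i], {p: p.replace("pa", "ua") for p in pa}, "A")
    b = _rename(forms[j], {p: p.replace("pa", "ub") for p in pa}, "B")
    c = _rename(forms[l], {p: p.replace("pa", "uc") for p in pa}, "C")

    pairs = {(0, 1): (i, j), (0, 2): (i, l), (1, 2): (j, l)}
    m = {key: Fraction(int(D[idx])) + k * int(U[idx])
         for key, idx in pairs.items()}
    order = {(0, 1): (0, 1, 2), (0, 2): (0, 2, 1), (1, 2): (1, 2, 0)}[
        max(m, key=lambda key: m[key])]
    genomes = (a, b, c)
    scan_idx = (i, j, l)

    def pair(x_, y_):
        key = (min(x_, y_), max(x_, y_))
        return pairs[key]

    ia, ib, ic = order
    d_ab = int(D[pair(ia, ib)])
    d_ac = int(D[pair(ia, ic)])
    d_bc = int(D[pair(ib, ic)])
    tp = triple_partition(genomes[ia], genomes[ib], genomes[ic])
    m_ab = m[(min(ia, ib), max(ia, ib))]
    m_ac = m[(min(ia, ic), max(ia, ic))]
    m_bc = m[(min(ib, ic), max(ib, ic))]
    return TripleAudit(
        names=(genomes[ia].name, genomes[ib].name, genomes[ic].name),
        model=model, k=k, m_ab=m_ab, m_ac=m_ac, m_bc=m_bc,
        violation=m_ab - m_ac - m_bc,
        reduced_check=Fraction(d_ab - d_ac - d_bc)
        - 2 * k * len(tp.common_ab),
    )


def bound_equality_report(model: str, n_common: int = 2,
                          n_private: int = 1) -> tuple[Fraction, int]:
    """Check oracle <= bound over every form pair of the tiny universe.

    Returns (fraction of pairs where the component-wise bound is exact,
    number of pairs checked).  Raises if the bound is ever exceeded."""
    forms, D, _U = scan_tables(model, n_common, n_private)
    pa = [f"pa{t}" for t in range(n_private)]
    renamed = [_rename(f, dict(zip(pa, (p.replace("pa", "pb") for p in pa))),
                       f.name) for f in forms]
    equal = total = 0
    for i, fa in enumerate(forms):
        for j in range(i, len(forms)):
            bound = distance_report(fa, renamed[j], model).bound_value
            d = int(D[i, j])
            if d > bound:
                raise AssertionError(
                    f"oracle distance {d} exceeds bound {bound} for pair "
                    f"({i}, {j})"
                )
            total += 1
            equal += d == bound
    return Fraction(equal, total), total
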