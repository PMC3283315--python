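"""Labeled adjacency graph of two genomes and its component decomposition.

Every adjacency of genome A (respectively B) — a pair of consecutive
common-marker extremities or an extremity/telomere pair, carrying the unique
markers lying between them as its *label* — is one vertex.  For each common
marker g there is one edge joining the two vertices containing g's head and
one joining the two containing g's tail.  The graph decomposes into cycles,
AB-/AA-/BB-paths and singletons; the counts (n, c, b) drive the DCJ distance
n − (c + b/2), and the vertex total obeys 2n + L_A + S_A + L_B + S_B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .genomes import Chromosome, Genome, GenomeError, Marker

# An extremity is (marker_name, "h"|"t"); a telomere is None.
Extremity = Optional[tuple[str, str]]
TELOMERE: Extremity = None


def _left_ext(m: Marker) -> tuple[str, str]:
    return (m.name, "t" if m.forward else "h")


def _right_ext(m: Marker) -> tuple[str, str]:
    return (m.name, "h" if m.forward else "t")


@dataclass(frozen=True)
class Vertex:
    """One labeled adjacency (or singleton chromosome) of one genome."""

    side: str                       # "A" or "B"
    gamma1: Extremity
    gamma2: Extremity
    label: tuple[Marker, ...] = ()  # unique markers read from gamma1 to gamma2
    singleton: str | None = None    # None | "linear" | "circular"

    @property
    def labeled(self) -> bool:
        return bool(self.label)

    @property
    def key(self) -> tuple:
        def ek(e: Extremity):
            return (0,) if e is None else (1, e)
        return (self.side, tuple(sorted(map(ek, (self.gamma1, self.gamma2)))))

    def __str__(self) -> str:
        def es(e: Extremity) -> str:
            return "o" if e is None else f"{e[0]}{e[1]}"
        lab = ",".join(str(m) for m in self.label)
        return f"{self.side}[{es(self.gamma1)}|{lab}|{es(self.gamma2)}]"


@dataclass
class Component:
    """One connected component, with its canonical ordered traversal."""

    kind: str                 # cycle | AB-path | AA-path | BB-path |
                              # linear-singleton | circular-singleton
    vertices: list[Vertex]    # traversal order, sides strictly alternating

    @property
    def size(self) -> int:
        return len(self.vertices)

    @property
    def is_cycle(self) -> bool:
        return self.kind == "cycle"


@dataclass
class AdjacencyGraph:
    """AG(A, B) with classified components and the (n, c, b) counts."""

    n: int                    # number of common markers
    components: list[Component]
    l_a: int                  # linear chromosomes of A
    l_b: int
    s_a: int                  # circular singletons of A
    s_b: int

    @property
    def c(self) -> int:
        """Cycles of size >= 2 (a circular singleton is not a cycle here)."""
        return sum(1 for p in self.components if p.kind == "cycle")

    @property
    def b(self) -> int:
        return sum(1 for p in self.components if p.kind == "AB-path")

    @property
    def vertex_total(self) -> int:
        return sum(p.size for p in self.components)


def _chromosome_vertices(chrom: Chromosome, side: str,
                         common: frozenset[str]) -> list[Vertex]:
    """Split one chromosome into labeled adjacencies (or one singleton)."""
    idx = [i for i, m in enumerate(chrom.markers) if m.name in common]
    if not idx:
        kind = "circular" if chrom.circular else "linear"
        return [Vertex(side, TELOMERE, TELOMERE, chrom.markers, kind)]

    verts: list[Vertex] = []
    ms = chrom.markers
    if chrom.circular:
        for j, i in enumerate(idx):
            nxt = idx[(j + 1) % len(idx)]
            if nxt > i:
                label = ms[i + 1:nxt]
            else:  # wrap around the origin
                label = ms[i + 1:] + ms[:nxt]
            verts.append(Vertex(side, _right_ext(ms[i]), _left_ext(ms[nxt]),
                                label))
    else:
        verts.append(Vertex(side, TELOMERE, _left_ext(ms[idx[0]]),
                            ms[:idx[0]]))
        for j in range(len(idx) - 1):
            i, nxt = idx[j], idx[j + 1]
            verts.append(Vertex(side, _right_ext(ms[i]), _left_ext(ms[nxt]),
                                ms[i + 1:nxt]))
        verts.append(Vertex(side, _right_ext(ms[idx[-1]]), TELOMERE,
                            ms[idx[-1] + 1:]))
    return verts


def build_adjacency_graph(a: Genome, b: Genome) -> AdjacencyGraph:
    """Construct AG(A, B) and decompose it into classified components."""
    names_a, names_b = a.marker_names(), b.marker_names()
    common = names_a & names_b

    vertices: list[Vertex] = []
    sides = {"A": a, "B": b}
    per_side_index: dict[str, dict[tuple[str, str], int]] = {"A": {}, "B": {}}
    for side, genome in sides.items():
        for chrom in genome.chromosomes:
            for v in _chromosome_vertices(chrom, side, common):
                vid = len(vertices)
                vertices.append(v)
                for e in (v.gamma1, v.gamma2):
                    if e is not None:
                        if e in per_side_index[side]:
                            raise GenomeError(
                                f"extremity {e} occurs twice on side {side}"
                            )
                        per_side_index[side][e] = vid

    graph = nx.MultiGraph()
    graph.add_nodes_from(range(len(vertices)))
    for g in sorted(common):
        for end in ("h", "t"):
            graph.add_edge(per_side_index["A"][(g, end)],
                           per_side_index["B"][(g, end)], key=(g, end))

    components = [
        _trace_component(graph, vertices, comp)
        for comp in nx.connected_components(graph)
    ]
    components.sort(key=lambda p: p.vertices[0].key)

    return AdjacencyGraph(
        n=len(common),
        components=components,
        l_a=a.n_linear,
        l_b=b.n_linear,
        s_a=sum(1 for v in vertices
                if v.side == "A" and v.singleton == "circular"),
        s_b=sum(1 for v in vertices
                if v.side == "B" and v.singleton == "circular"),
    )


def _trace_component(graph: nx.MultiGraph, vertices: list[Vertex],
                     nodes: set[int]) -> Component:
    """Classify one component and order its vertices along the walk.

    Paths start at a canonical endpoint (A-side first; ties broken by vertex
    key); cycles at their smallest vertex.  Run counting is invariant under
    this choice, the order only fixes a deterministic serialisation.
    """
    if len(nodes) == 1:
        (vid,) = nodes
        v = vertices[vid]
        if graph.degree(vid) == 0:
            assert v.singleton is not None
            return Component(f"{v.singleton}-singleton", [v])

    endpoints = sorted((vid for vid in nodes if graph.degree(vid) < 2),
                       key=lambda vid: (vertices[vid].side != "A",
                                        vertices[vid].key))
    if endpoints:
        start = endpoints[0]
        end_sides = sorted(vertices[vid].side for vid in endpoints)
        kind = {"AB": "AB-path", "AA": "AA-path", "BB": "BB-path"}[
            "".join(end_sides)]
    else:
        start = min(nodes, key=lambda vid: vertices[vid].key)
        kind = "cycle"

    order = [start]
    used_edges: set[tuple] = set()
    current = start
    while True:
        step = None
        for _, nbr, ekey in sorted(graph.edges(current, keys=True),
                                   key=lambda e: e[2]):
            edge_id = (min(current, nbr), max(current, nbr), ekey)
            if edge_id not in used_edges:
                step = (nbr, edge_id)
                break
        if step is None:
            break
        nbr, edge_id = step
        used_edges.add(edge_id)
        if kind == "cycle" and nbr == start:
            break
        order.append(nbr)
        current = nbr

    assert len(order) == len(nodes), "component walk must visit every vertex"
    walked = [vertices[vid] for vid in order]
    for u, v in zip(walked, walked[1:]):
        assert u.side != v.side, "traversal must alternate genome sides"
    return Component(kind, walked)


def vertex_count_check(graph: AdjacencyGraph) -> bool:
    """Vertex-count identity: Σ|P| = 2n + L_A + S_A + L_B + S_B."""
    return graph.vertex_total == (
        2 * graph.n + graph.l_a + graph.s_a + graph.l_b + graph.s_b
    )


def dump(graph: AdjacencyGraph) -> str:
    """Tab-separated debug dump: component id, kind, size, vertices."""
    lines = []
    for i, p in enumerate(graph.components):
        verts = " ".join(str(v) for v in p.vertices)
        lines.append(f"{i}\t{p.kind}\t{p.size}\t{verts}")
    return "\n".join(lines) + ("\n" if lines else "")
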