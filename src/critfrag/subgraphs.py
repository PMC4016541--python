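"""Subgraph enumeration and fragment weights.

A subgraph of a fragment is a species-disjoint collection of cycles and
edges in which every fragment species starts exactly one component and
whose components jointly consume exactly the fragment's reaction
multiset (a cycle of order q consumes q reaction instances, an edge
one).  Its weight is

    K_g = (-1)^c * prod(K_C over cycles) * prod(-K_E over edges),

with c the number of cycles.  The fragment weight K_S is the sum of its
subgraph weights; the fragment is *critical* when K_S < 0.  Critical
fragments of order r = rank(S) are necessary for multistability, and of
order k < n for Turing instability or oscillations.

Enumeration proceeds in two stages rather than by filtering the
cartesian product of per-species components:

1. *Path graph* Phi: one node per path of the fragment (negative paths
   in both orientations), an arc p -> q when p ends where q starts.
   Elementary circuits of Phi whose start species are pairwise distinct
   are exactly the cycles of the fragment; the circuit search prunes a
   growing circuit as soon as a start species repeats.
2. *Cycle graph* Gamma: one node per valid cycle, an undirected edge
   between species-disjoint cycles.  Every clique of Gamma (including
   the empty clique, which yields the edges-only subgraphs) is
   completed to full subgraphs by assigning the leftover species to
   leftover reaction instances through existing edges, by exhaustive
   fail-fast backtracking.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Union

import networkx as nx

from .bigraph import BipartiteDigraph, Cycle, DirectedPath, Edge, make_cycle
from .fragments import FragmentKey

__all__ = [
    "Subgraph",
    "WeightedFragment",
    "PathGraph",
    "CycleGraph",
    "admissible_pairs",
    "component_table",
    "build_path_graph",
    "enumerate_cycles",
    "build_cycle_graph",
    "enumerate_subgraphs",
    "subgraph_weight",
    "fragment_weight",
]

Component = Union[Edge, DirectedPath]


@dataclass(frozen=True)
class Subgraph:
    cycles: tuple[Cycle, ...]  # sorted by canonical key
    edges: tuple[Edge, ...]    # sorted

    @property
    def weight(self) -> int:
        w = (-1) ** len(self.cycles)
        for c in self.cycles:
            w *= c.weight
        for e in self.edges:
            w *= -e.weight
        return w

    @property
    def species(self) -> frozenset[int]:
        out: set[int] = set(e.species for e in self.edges)
        for c in self.cycles:
            out |= c.species
        return frozenset(out)

    @property
    def reactions(self) -> Counter:
        consumed = Counter(e.reaction for e in self.edges)
        for c in self.cycles:
            consumed += c.reactions
        return consumed

    @property
    def canonical_key(self) -> tuple:
        return (tuple(c.canonical_key for c in self.cycles),
                tuple((e.species, e.reaction) for e in self.edges))


@dataclass(frozen=True)
class WeightedFragment:
    key: FragmentKey
    subgraphs: tuple[Subgraph, ...]
    weight: int

    @property
    def critical(self) -> bool:
        return self.weight < 0

    @property
    def order(self) -> int:
        return self.key.order


def admissible_pairs(graph: BipartiteDigraph,
                     key: FragmentKey) -> set[tuple[int, int]]:
    """Species-reaction pairs realizable in a full edge assignment.

    A pair (s, j) is admissible when the fragment has at least one
    edges-only assignment mapping s to j -- equivalently, when some
    subgraph of the fragment can route s through j.  Components built
    from inadmissible pairs could never complete to a subgraph, so they
    are excluded from the lookup table up front.
    """
    key_rxns = Counter(key.reactions)
    pairs: set[tuple[int, int]] = set()
    for s in key.species:
        rest = [x for x in key.species if x != s]
        for j in sorted(set(key.reactions)):
            if not graph.has_edge(s, j):
                continue
            budget = key_rxns.copy()
            budget[j] -= 1
            if next(_complete_with_edges(graph, rest, budget), None) is not None:
                pairs.add((s, j))
    return pairs


def component_table(graph: BipartiteDigraph,
                    key: FragmentKey) -> dict[int, list[Component]]:
    """All admissible components of a fragment, grouped by start species.

    For each fragment species s and each reaction j the fragment can
    pair it with (see :func:`admissible_pairs`): the edge [s, j] and the
    positive/negative paths through j whose end species also belongs to
    the fragment.
    """
    sp_set = set(key.species)
    pairs = admissible_pairs(graph, key)
    table: dict[int, list[Component]] = {}
    for s in key.species:
        comps: list[Component] = []
        for j in sorted(j for (x, j) in pairs if x == s):
            comps.append(graph.edge(s, j))
            for e in sorted(sp_set):
                if graph.beta[j].get(e, 0) > 0:
                    comps.append(graph.positive_path(s, j, e))
                if e != s and graph.alpha[j].get(e, 0) > 0:
                    comps.append(graph.negative_path(s, j, e))
        table[s] = comps
    return table


class PathGraph:
    """Digraph Phi on the fragment's paths (expanded orientations)."""

    def __init__(self, paths: list[DirectedPath]):
        # deterministic node order; signatures are unique by construction
        self.nodes: list[DirectedPath] = sorted(paths)
        self.succ: list[list[int]] = [
            [q for q, pq in enumerate(self.nodes) if p.end == pq.start]
            for p in self.nodes
        ]


def build_path_graph(table: dict[int, list[Component]]) -> PathGraph:
    paths = [c for comps in table.values() for c in comps
             if isinstance(c, DirectedPath)]
    return PathGraph(paths)


def enumerate_cycles(pg: PathGraph) -> list[Cycle]:
    """All cycles of the fragment, via elementary circuits of Phi.

    Circuit enumeration in the style of Johnson's algorithm: each
    circuit is rooted at its smallest node index, the search only
    descends to larger indices, and a branch is abandoned as soon as a
    path start species repeats -- so closed walks revisiting a species
    are never generated, which keeps memory proportional to the current
    stack rather than to the number of raw circuits.
    """
    nodes = pg.nodes
    cycles: dict[tuple, Cycle] = {}
    stack: list[int] = []

    def dfs(root: int, cur: int, used: set[int]) -> None:
        for nxt in pg.succ[cur]:
            if nxt == root:
                cyc = make_cycle([nodes[i] for i in stack])
                cycles[cyc.canonical_key] = cyc
            elif nxt > root and nodes[nxt].start not in used:
                used.add(nodes[nxt].start)
                stack.append(nxt)
                dfs(root, nxt, used)
                stack.pop()
                used.discard(nodes[nxt].start)

    for root in range(len(nodes)):
        stack[:] = [root]
        dfs(root, root, {nodes[root].start})
    return [cycles[k] for k in sorted(cycles)]


class CycleGraph:
    """Undirected graph Gamma: nodes are cycles, edges join species-disjoint ones."""

    def __init__(self, cycles: list[Cycle]):
        self.cycles = cycles
        self.graph = nx.Graph()
        self.graph.add_nodes_from(range(len(cycles)))
        for a in range(len(cycles)):
            for b in range(a + 1, len(cycles)):
                if not (cycles[a].species & cycles[b].species):
                    self.graph.add_edge(a, b)

    def cliques(self) -> Iterator[tuple[int, ...]]:
        """All cliques, the empty one included (edges-only subgraphs)."""
        yield ()
        if self.graph.number_of_nodes():
            for clique in nx.enumerate_all_cliques(self.graph):
                yield tuple(sorted(clique))


def build_cycle_graph(graph: BipartiteDigraph, key: FragmentKey) -> CycleGraph:
    table = component_table(graph, key)
    key_rxns = Counter(key.reactions)
    cycles = [c for c in enumerate_cycles(build_path_graph(table))
              if c.reactions <= key_rxns]
    return CycleGraph(cycles)


def _complete_with_edges(graph: BipartiteDigraph, remaining: list[int],
                         budget: Counter) -> Iterator[tuple[Edge, ...]]:
    """Assign each remaining species one edge, consuming ``budget`` exactly.

    Backtracking picks the most constrained species first (fewest
    admissible edges) so that dead branches fail fast; each complete
    assignment is one distinct edge set.
    """
    if not remaining:
        yield ()
        return
    options = {
        s: [j for j in sorted(budget) if budget[j] > 0 and graph.has_edge(s, j)]
        for s in remaining
    }
    s = min(remaining, key=lambda x: len(options[x]))
    rest = [x for x in remaining if x != s]
    for j in options[s]:
        budget[j] -= 1
        for tail in _complete_with_edges(graph, rest, budget):
            yield (graph.edge(s, j),) + tail
        budget[j] += 1


def enumerate_subgraphs(graph: BipartiteDigraph,
                        key: FragmentKey) -> list[Subgraph]:
    """All subgraphs of a fragment, deduplicated and deterministically sorted."""
    key_rxns = Counter(key.reactions)
    cg = build_cycle_graph(graph, key)
    out: dict[tuple, Subgraph] = {}
    for clique in cg.cliques():
        cycles = [cg.cycles[i] for i in clique]
        used_species: set[int] = set()
        used_rxns: Counter = Counter()
        ok = True
        for c in cycles:
            if used_species & c.species:
                ok = False
                break
            used_species |= c.species
            used_rxns += c.reactions
        if not ok or not used_rxns <= key_rxns:
            continue
        remaining = [s for s in key.species if s not in used_species]
        budget = key_rxns - used_rxns
        if len(remaining) != sum(budget.values()):
            continue
        for edges in _complete_with_edges(graph, remaining, budget):
            sg = Subgraph(
                cycles=tuple(sorted(cycles, key=lambda c: c.canonical_key)),
                edges=tuple(sorted(edges)))
            out[sg.canonical_key] = sg
    return [out[k] for k in sorted(out)]


def subgraph_weight(g: Subgraph) -> int:
    return g.weight


def fragment_weight(graph: BipartiteDigraph, key: FragmentKey,
                    keep_subgraphs: bool = True) -> WeightedFragment:
    """Weight a fragment by summing its subgraph weights."""
    subgraphs = enumerate_subgraphs(graph, key)
    weight = sum(g.weight for g in subgraphs)
    return WeightedFragment(key=key,
                            subgraphs=tuple(subgraphs) if keep_subgraphs else (),
                            weight=weight)
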