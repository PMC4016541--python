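"""Bipartite species-reaction digraph and its weighted structural elements.

The digraph G of a mechanism has one node per species A_k and one per
reaction B_j, an arc A_k -> B_j whenever alpha_jk > 0 (A_k is a
reactant of B_j) and an arc B_j -> A_i whenever beta_ji > 0 (A_i is a
product).  Stability-relevant structure is carried by three weighted
elements built from the arcs:

* edge [A_k, B_j]          weight  K_E = -alpha_jk**2
* positive path [A_k,B_j,A_i]   weight  alpha_jk * beta_ji
  (production of A_i from A_k through B_j; A_i may equal A_k)
* negative path [A_k,B_j,~A_i]  weight  -alpha_jk * alpha_ji
  (A_k and A_i co-reacting in B_j; the two orientations are distinct
  paths, and A_i != A_k)

A cycle is a chain of paths, each ending where the next starts, whose
start species are pairwise distinct; its weight is the product of the
path weights, so it is negative exactly when it contains an odd number
of negative paths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import networkx as nx

from .mechanism import Mechanism

__all__ = [
    "Edge",
    "DirectedPath",
    "Cycle",
    "BipartiteDigraph",
    "build_graph",
    "edge_weight",
    "path_weight",
    "cycle_weight",
    "make_cycle",
]


@dataclass(frozen=True, order=True)
class Edge:
    """Species-reaction edge [A_k, B_j]; exists iff alpha_jk > 0."""

    species: int
    reaction: int
    weight: int  # -alpha_jk**2


@dataclass(frozen=True, order=True)
class DirectedPath:
    """A positive or negative path through one reaction node.

    Identified by (start, reaction, end, polarity); for a negative path
    the two orientations are two distinct objects.
    """

    start: int
    reaction: int
    end: int
    positive: bool
    weight: int

    @property
    def signature(self) -> tuple[int, int, int, bool]:
        return (self.start, self.reaction, self.end, self.positive)


@dataclass(frozen=True)
class Cycle:
    """A chain of paths closing on itself, stored in canonical rotation."""

    paths: tuple[DirectedPath, ...]

    @property
    def order(self) -> int:
        return len(self.paths)

    @property
    def weight(self) -> int:
        w = 1
        for p in self.paths:
            w *= p.weight
        return w

    @property
    def species(self) -> frozenset[int]:
        return frozenset(p.start for p in self.paths)

    @property
    def reactions(self) -> Counter:
        return Counter(p.reaction for p in self.paths)

    @property
    def canonical_key(self) -> tuple:
        return tuple(p.signature for p in self.paths)


def make_cycle(paths: tuple[DirectedPath, ...] | list[DirectedPath]) -> Cycle:
    """Build a cycle in canonical rotation (smallest start species first).

    Validates the chain condition and that start species are pairwise
    distinct; rotation-invariance makes duplicates from circuit
    enumeration collapse under equality.
    """
    paths = tuple(paths)
    starts = [p.start for p in paths]
    if len(set(starts)) != len(starts):
        raise ValueError("cycle start species must be pairwise distinct")
    for p, q in zip(paths, paths[1:] + paths[:1]):
        if p.end != q.start:
            raise ValueError("paths do not chain into a cycle")
    shift = starts.index(min(starts))
    return Cycle(paths=paths[shift:] + paths[:shift])


class BipartiteDigraph:
    """Bipartite digraph of a mechanism with weighted-element accessors."""

    def __init__(self, mech: Mechanism):
        self.mechanism = mech
        self.n = mech.n
        self.m = mech.m
        # alpha[j][i], beta[j][i]: stoichiometric coefficients, 1-based keys
        self.alpha: dict[int, dict[int, int]] = {}
        self.beta: dict[int, dict[int, int]] = {}
        for r in mech.reactions:
            self.alpha[r.index] = dict(r.reactants)
            self.beta[r.index] = dict(r.products)
        # out_reactions[i]: reactions in which species i is a reactant,
        # i.e. the targets of the edges starting at i
        self.out_reactions: dict[int, tuple[int, ...]] = {
            i: tuple(sorted(j for j in self.alpha if self.alpha[j].get(i, 0) > 0))
            for i in range(1, self.n + 1)
        }

    # -- arcs ---------------------------------------------------------

    def species_arcs(self) -> Iterator[tuple[int, int]]:
        """Arcs A_k -> B_j (alpha_jk > 0)."""
        for i, js in self.out_reactions.items():
            for j in js:
                yield (i, j)

    def reaction_arcs(self) -> Iterator[tuple[int, int]]:
        """Arcs B_j -> A_i (beta_ji > 0)."""
        for j in sorted(self.beta):
            for i in sorted(self.beta[j]):
                if self.beta[j][i] > 0:
                    yield (j, i)

    # -- weighted elements --------------------------------------------

    def edge(self, species: int, reaction: int) -> Edge:
        a = self.alpha[reaction].get(species, 0)
        if a <= 0:
            raise ValueError(
                f"[A{species}, B{reaction}] is not an edge (alpha = 0)")
        return Edge(species=species, reaction=reaction, weight=-a * a)

    def has_edge(self, species: int, reaction: int) -> bool:
        return self.alpha[reaction].get(species, 0) > 0

    def positive_path(self, start: int, reaction: int, end: int) -> DirectedPath:
        a = self.alpha[reaction].get(start, 0)
        b = self.beta[reaction].get(end, 0)
        if a <= 0 or b <= 0:
            raise ValueError(
                f"[A{start}, B{reaction}, A{end}] is not a positive path")
        return DirectedPath(start=start, reaction=reaction, end=end,
                            positive=True, weight=a * b)

    def negative_path(self, start: int, reaction: int, end: int) -> DirectedPath:
        a1 = self.alpha[reaction].get(start, 0)
        a2 = self.alpha[reaction].get(end, 0)
        if start == end:
            raise ValueError("a negative path needs two distinct reactant species")
        if a1 <= 0 or a2 <= 0:
            raise ValueError(
                f"[A{start}, B{reaction}, ~A{end}] is not a negative path")
        return DirectedPath(start=start, reaction=reaction, end=end,
                            positive=False, weight=-a1 * a2)

    # -- export -------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for sp in self.mechanism.species:
            g.add_node(("A", sp.index), name=sp.name, bipartite=0)
        for r in self.mechanism.reactions:
            g.add_node(("B", r.index), name=r.rate_label, bipartite=1)
        for i, j in self.species_arcs():
            g.add_edge(("A", i), ("B", j), coeff=self.alpha[j][i])
        for j, i in self.reaction_arcs():
            g.add_edge(("B", j), ("A", i), coeff=self.beta[j][i])
        return g

    def to_dot(self) -> str:
        """DOT export: circles for species, squares for reactions."""
        lines = ["digraph mechanism {"]
        for sp in self.mechanism.species:
            lines.append(f'  A{sp.index} [label="{sp.name}", shape=circle];')
        for r in self.mechanism.reactions:
            lines.append(f'  B{r.index} [label="B{r.index}", shape=square];')
        for i, j in self.species_arcs():
            lines.append(f"  A{i} -> B{j};")
        for j, i in self.reaction_arcs():
            lines.append(f"  B{j} -> A{i};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_graph(mech: Mechanism) -> BipartiteDigraph:
    """Build the bipartite digraph of a mechanism."""
    return BipartiteDigraph(mech)


def edge_weight(e: Edge) -> int:
    return e.weight


def path_weight(p: DirectedPath) -> int:
    return p.weight


def cycle_weight(c: Cycle) -> int:
    return c.weight
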