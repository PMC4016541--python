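"""Fragment enumeration.

A fragment of order k pairs k distinct species with a multiset of k
reactions.  Every fragment contains at least one subgraph made of edges
only, and conversely each choice of one outgoing edge per species of a
k-subset induces a fragment; enumerating those edge assignments and
deduplicating the induced (species set, reaction multiset) keys
therefore yields exactly the fragments present in the digraph, far
fewer candidates than the combinatorial C(N,k)*R^k baseline kept here
as an oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterator

from .bigraph import BipartiteDigraph

__all__ = [
    "FragmentKey",
    "enumerate_fragments",
    "combinatorial_fragments",
    "count_generated",
    "CombinatorialCapError",
]


class CombinatorialCapError(ValueError):
    """The combinatorial baseline would generate too many candidates."""


@dataclass(frozen=True, order=True)
class FragmentKey:
    """Identity of a fragment: k distinct species, k reactions with multiplicity.

    Two edge assignments pairing the same species with the same reaction
    multiset are the same fragment (they contribute to one monomial of
    the characteristic-polynomial coefficient), so the pairing itself is
    not part of the identity.
    """

    species: tuple[int, ...]   # sorted, no repeats
    reactions: tuple[int, ...]  # sorted, repeats allowed

    def __post_init__(self):
        if tuple(sorted(set(self.species))) != self.species:
            raise ValueError("species must be a sorted tuple without repeats")
        if tuple(sorted(self.reactions)) != self.reactions:
            raise ValueError("reactions must be a sorted tuple")
        if len(self.species) != len(self.reactions):
            raise ValueError("species and reactions must have equal size k")

    @property
    def order(self) -> int:
        return len(self.species)


def _check_order(graph: BipartiteDigraph, k: int) -> None:
    if not 1 <= k <= graph.n:
        raise ValueError(f"order k={k} outside 1..{graph.n}")


def enumerate_fragments(graph: BipartiteDigraph, k: int) -> Iterator[FragmentKey]:
    """Stream all fragments of order k, without duplicates.

    For every k-subset of species, every choice of one outgoing edge per
    species induces a key; keys are deduplicated per species subset and
    emitted lexicographically (by species tuple, then reaction multiset),
    so the order is deterministic and memory stays bounded by the number
    of distinct multisets of one subset.
    """
    _check_order(graph, k)
    for combo in itertools.combinations(range(1, graph.n + 1), k):
        choices = [graph.out_reactions[i] for i in combo]
        if any(not c for c in choices):
            continue
        seen: set[tuple[int, ...]] = set()
        for assignment in itertools.product(*choices):
            seen.add(tuple(sorted(assignment)))
        for reactions in sorted(seen):
            yield FragmentKey(species=combo, reactions=reactions)


def combinatorial_fragments(graph: BipartiteDigraph, k: int,
                            cap: int = 2_000_000) -> Iterator[FragmentKey]:
    """Baseline: pair every k-subset of species with every R^k reaction tuple.

    A candidate survives when each species has an edge to the reaction it
    is paired with; surviving candidates collapse to deduplicated keys.
    Guarded by ``cap`` on C(N,k)*R^k since this is for oracle use on
    small instances only.
    """
    _check_order(graph, k)
    total = comb(graph.n, k) * graph.m ** k
    if total > cap:
        raise CombinatorialCapError(
            f"combinatorial baseline would generate {total} candidates (cap {cap})")
    reactions = range(1, graph.m + 1)
    for combo in itertools.combinations(range(1, graph.n + 1), k):
        seen: set[tuple[int, ...]] = set()
        for pairing in itertools.product(reactions, repeat=k):
            if all(graph.has_edge(i, j) for i, j in zip(combo, pairing)):
                seen.add(tuple(sorted(pairing)))
        for rxns in sorted(seen):
            yield FragmentKey(species=combo, reactions=rxns)


def count_generated(graph: BipartiteDigraph, k: int, method: str) -> int:
    """Raw candidate count (before dedup/filtering) for cost comparison.

    ``combinatorial``: C(N,k) * R^k.  ``correspondence``: the number of
    edge assignments, i.e. the k-th elementary symmetric function of the
    species out-degrees.
    """
    _check_order(graph, k)
    if method == "combinatorial":
        return comb(graph.n, k) * graph.m ** k
    if method == "correspondence":
        degrees = [len(graph.out_reactions[i]) for i in range(1, graph.n + 1)]
        # elementary symmetric polynomial e_k via polynomial product
        coeffs = [1]
        for d in degrees:
            coeffs = [c + d * (coeffs[idx - 1] if idx else 0)
                      for idx, c in enumerate(coeffs)] + [d * coeffs[-1]]
        return coeffs[k]
    raise ValueError(f"unknown method {method!r}")
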