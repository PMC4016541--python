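"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive generation plus
filtering, deliberately avoiding the pruned/structured code paths it is
used to check.
"""

from __future__ import annotations

import itertools
from collections import Counter

from critfrag.bigraph import BipartiteDigraph, DirectedPath, Edge, make_cycle
from critfrag.fragments import FragmentKey
from critfrag.subgraphs import Subgraph


def rank_oracle(S) -> int:
    """Exact rank via sympy's rref over the rationals."""
    import sympy

    M = sympy.Matrix([[int(x) for x in row] for row in S])
    return len(M.rref()[1])


def membership_components(graph: BipartiteDigraph, key: FragmentKey):
    """Per-species components admitted by bare reaction-multiset membership.

    Wider than the assignment-restricted lookup table the implementation
    uses; selections drawn from it are filtered for validity afterwards.
    """
    sp = key.species
    comps = {}
    for s in sp:
        lst = []
        for j in sorted(set(key.reactions)):
            if not graph.has_edge(s, j):
                continue
            lst.append(graph.edge(s, j))
            for e in sp:
                if graph.beta[j].get(e, 0) > 0:
                    lst.append(graph.positive_path(s, j, e))
                if e != s and graph.alpha[j].get(e, 0) > 0:
                    lst.append(graph.negative_path(s, j, e))
        comps[s] = lst
    return comps


def subgraph_oracle(graph: BipartiteDigraph, key: FragmentKey,
                    cap: int = 100_000) -> set:
    """All subgraph canonical keys by cartesian selection + validity filter.

    One component is chosen per species; a selection is a subgraph iff
    its reaction multiset equals the key's and its chosen paths close
    into cycles (the start -> end map is a permutation of the
    path-choosing species).
    """
    comps = membership_components(graph, key)
    n_cand = 1
    for lst in comps.values():
        n_cand *= len(lst)
    if n_cand > cap:
        raise ValueError(f"combinatorial candidate count {n_cand} exceeds cap")
    key_rxns = Counter(key.reactions)
    found = set()
    for sel in itertools.product(*[comps[s] for s in key.species]):
        if Counter(c.reaction for c in sel) != key_rxns:
            continue
        paths = {c.start: c for c in sel if isinstance(c, DirectedPath)}
        edges = [c for c in sel if isinstance(c, Edge)]
        ends = [p.end for p in paths.values()]
        if len(set(ends)) != len(ends) or any(e not in paths for e in ends):
            continue
        cycles = []
        visited = set()
        for s0 in sorted(paths):
            if s0 in visited:
                continue
            chain, cur = [], s0
            while cur not in visited:
                visited.add(cur)
                chain.append(paths[cur])
                cur = paths[cur].end
            cycles.append(make_cycle(chain))
        sg = Subgraph(cycles=tuple(sorted(cycles, key=lambda c: c.canonical_key)),
                      edges=tuple(sorted(edges)))
        found.add(sg.canonical_key)
    return found


def cycle_oracle(path_graph) -> set:
    """Cycles via stock elementary-circuit enumeration plus post-filtering.

    Uses networkx simple_cycles on the path digraph, then discards
    circuits whose path start species repeat -- the unpruned reference
    for the search that prunes during descent.
    """
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(len(path_graph.nodes)))
    for i, succ in enumerate(path_graph.succ):
        for q in succ:
            g.add_edge(i, q)
    found = set()
    for circuit in nx.simple_cycles(g):
        paths = [path_graph.nodes[i] for i in circuit]
        starts = [p.start for p in paths]
        if len(set(starts)) != len(starts):
            continue
        found.add(make_cycle(paths).canonical_key)
    return found


def assignment_pairs_oracle(graph: BipartiteDigraph, key: FragmentKey) -> set:
    """(species, reaction) pairs over all edges-only assignments, brute force."""
    options = [[j for j in sorted(set(key.reactions)) if graph.has_edge(s, j)]
               for s in key.species]
    key_rxns = Counter(key.reactions)
    pairs = set()
    for assign in itertools.product(*options):
        if Counter(assign) == key_rxns:
            pairs.update(zip(key.species, assign))
    return pairs


def minor_sum_oracle(J, k):
    """a_k as the explicit sum of the k x k principal minors of -J."""
    import sympy

    n = J.n
    M = -J.matrix
    total = sympy.Integer(0)
    for rows in itertools.combinations(range(n), k):
        total += M.extract(rows, rows).det()
    return sympy.cancel(total)
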