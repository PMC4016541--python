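from collections import Counter

import pytest

from critfrag import (build_graph, enumerate_fragments, fragment_weight,
                      parse_mechanism)
from critfrag.fragments import FragmentKey
from critfrag.fixtures import RandomMechanismSpec, random_mechanism
from critfrag.subgraphs import (admissible_pairs, build_path_graph,
                                component_table, enumerate_cycles,
                                enumerate_subgraphs)

from oracles import (assignment_pairs_oracle, cycle_oracle,
                     membership_components, subgraph_oracle)

S3_KEY = FragmentKey(species=(1, 2, 3), reactions=(3, 4, 5))


def random_fragments(n_mechs, per_mech, max_k=4, n_species=5, n_reactions=7,
                     seed0=0):
    """Deterministic sample of fragments from seeded random mechanisms."""
    out = []
    for seed in range(n_mechs):
        mech = random_mechanism(RandomMechanismSpec(
            n_species=n_species, n_reactions=n_reactions, seed=seed0 + seed))
        g = build_graph(mech)
        keys = [key for k in range(1, min(max_k, g.n) + 1)
                for key in enumerate_fragments(g, k)]
        step = max(1, len(keys) // per_mech)
        out.extend((g, key) for key in keys[::step][:per_mech])
    return out


class TestComponentTable:
    def test_worked_fragment_entry_for_A1(self, substrate_inhibition_graph):
        table = component_table(substrate_inhibition_graph, S3_KEY)
        # the only full edge assignment routes A1 through B5
        a1 = {(type(c).__name__, c.reaction) for c in table[1]}
        assert a1 == {("Edge", 5), ("DirectedPath", 5)}

    def test_unrealizable_species_empties_fragment(self):
        # A2's only edge is into B2, absent from the key: no assignment exists
        g = build_graph(parse_mechanism(
            "A1 -> A2 ; k1\nA2 -> A1 ; k2\nA1 -> 0 ; k3\n"))
        key = FragmentKey(species=(1, 2), reactions=(1, 3))
        assert enumerate_subgraphs(g, key) == []
        assert fragment_weight(g, key).weight == 0

    @pytest.mark.parametrize("gi", range(0, 60, 7))
    def test_admissible_pairs_match_assignment_scan(self, gi):
        frags = random_fragments(6, 10)
        g, key = frags[gi % len(frags)]
        assert admissible_pairs(g, key) == assignment_pairs_oracle(g, key)

    def test_table_is_subset_of_membership_components(self):
        for g, key in random_fragments(4, 8):
            wide = membership_components(g, key)
            table = component_table(g, key)
            for s in key.species:
                assert set(table[s]) <= set(wide[s])


class TestCycleEnumeration:
    def test_worked_fragment_has_exactly_two_cycles(self, substrate_inhibition_graph):
        pg = build_path_graph(component_table(substrate_inhibition_graph, S3_KEY))
        cycles = enumerate_cycles(pg)
        assert len(cycles) == 2
        assert sorted(c.order for c in cycles) == [2, 3]
        assert sorted(c.weight for c in cycles) == [1, 1]

    def test_edges_only_fragment_has_no_cycles(self):
        g = build_graph(parse_mechanism(
            "A1 -> 0 ; k1\nA2 -> 0 ; k2\n0 -> A1 ; k3\n0 -> A2 ; k4\n"))
        key = FragmentKey(species=(1, 2), reactions=(1, 2))
        pg = build_path_graph(component_table(g, key))
        assert enumerate_cycles(pg) == []

    def test_pruned_search_equals_filtered_stock_enumeration(self):
        for g, key in random_fragments(10, 6):
            pg = build_path_graph(component_table(g, key))
            mine = {c.canonical_key for c in enumerate_cycles(pg)}
            assert mine == cycle_oracle(pg)


class TestSubgraphEnumeration:
    def test_worked_fragment_subgraphs(self, substrate_inhibition_graph):
        subs = enumerate_subgraphs(substrate_inhibition_graph, S3_KEY)
        assert len(subs) == 3
        by_shape = {(len(s.cycles), len(s.edges)): s.weight for s in subs}
        assert by_shape == {
            (1, 0): -1,   # the order-3 cycle alone
            (1, 1): -1,   # 2-cycle A2,A3;B3,B4 completed by edge [A1,B5]
            (0, 3): 1,    # edges only
        }

    def test_edges_only_subgraph_from_empty_clique(self, substrate_inhibition_graph):
        subs = enumerate_subgraphs(substrate_inhibition_graph, S3_KEY)
        pure_edges = [s for s in subs if not s.cycles]
        assert len(pure_edges) == 1
        assert {(e.species, e.reaction) for e in pure_edges[0].edges} == \
            {(1, 5), (2, 3), (3, 4)}

    def test_matches_combinatorial_filter_oracle(self):
        for g, key in random_fragments(12, 9):
            mine = {s.canonical_key for s in enumerate_subgraphs(g, key)}
            assert mine == subgraph_oracle(g, key)

    def test_reaction_multiset_conservation(self):
        for g, key in random_fragments(6, 8):
            for s in enumerate_subgraphs(g, key):
                assert sum(c.order for c in s.cycles) + len(s.edges) == key.order
                assert s.reactions == Counter(key.reactions)
                assert s.species == frozenset(key.species)

    def test_negative_pair_cycle_consumes_reaction_twice(self, substrate_inhibition_graph):
        # fragment on A1, A2 with B3 twice: the 2-cycle of the two
        # negative paths through B3 consumes both instances of B3, and
        # the edges-only subgraph {[A1,B3],[A2,B3]} does likewise; their
        # weights -1 and +1 cancel exactly (no w3^2 monomial in a_2)
        g = substrate_inhibition_graph
        key = FragmentKey(species=(1, 2), reactions=(3, 3))
        subs = enumerate_subgraphs(g, key)
        assert len(subs) == 2
        cyclic = [s for s in subs if s.cycles]
        assert len(cyclic) == 1 and not cyclic[0].edges
        assert cyclic[0].cycles[0].order == 2
        assert cyclic[0].weight == -1  # (-1)^1 * (+1 cycle weight)
        assert fragment_weight(g, key).weight == 0

    def test_criticality_invariant_under_relabeling(self, glycolysis):
        from critfrag import serialize_mechanism
        text = serialize_mechanism(glycolysis)
        # permute reaction lines and rename species consistently
        lines = text.strip().split("\n")
        perm = lines[::-1]
        renamed = "\n".join(perm).replace("A1", "Z9").replace("A4", "Z4")
        shuffled = parse_mechanism(renamed)
        g1, g2 = build_graph(glycolysis), build_graph(shuffled)
        crit1 = sum(1 for key in enumerate_fragments(g1, 2)
                    if fragment_weight(g1, key).weight < 0)
        crit2 = sum(1 for key in enumerate_fragments(g2, 2)
                    if fragment_weight(g2, key).weight < 0)
        assert crit1 == crit2


class TestFragmentWeights:
    def test_worked_fragment_is_critical(self, substrate_inhibition_graph):
        wf = fragment_weight(substrate_inhibition_graph, S3_KEY)
        assert wf.weight == -1 and wf.critical

    def test_all_order4_fragments_vanish(self, substrate_inhibition_graph):
        # rank(S) = 3 forces a_4 == 0, hence every order-4 weight is 0
        g = substrate_inhibition_graph
        weights = [fragment_weight(g, key).weight
                   for key in enumerate_fragments(g, 4)]
        assert weights and all(w == 0 for w in weights)

    def test_edges_only_fragment_weight_positive(self):
        g = build_graph(parse_mechanism(
            "A1 -> 0 ; k1\nA2 -> 0 ; k2\n0 -> A1 ; k3\n0 -> A2 ; k4\n"))
        key = FragmentKey(species=(1, 2), reactions=(1, 2))
        wf = fragment_weight(g, key)
        assert wf.weight == 1 and not wf.critical
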