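# Methods

## Model and scope

`critfrag` analyzes isothermal mass-action mechanisms: `n` species,
`m` elementary reactions with nonnegative integer stoichiometric
coefficients `alpha_ji` (reactants) and `beta_ji` (products), rate
functions `w_j = k_j * prod_i u_i^alpha_ji`. Reversible steps are two
reactions. The analysis assumes the ODE model `u' = S w(u)` has a
positive equilibrium, and that every species is consumed and produced by
at least one true (non-inflow/outflow) reaction; violations of the
latter are reported as warnings, not errors, because the enumeration
itself remains well defined.

The package decides only *necessary* structural conditions: whether
critical fragments of the relevant orders exist. It does not compute
bifurcations, choose `(u, w)` values that realize an instability, or
simulate reaction–diffusion dynamics.

## Graph elements and weights

The bipartite digraph has arcs `A_k -> B_j` iff `alpha_jk > 0` and
`B_j -> A_i` iff `beta_ji > 0`. Weighted elements:

| element | condition | weight |
|---|---|---|
| edge `[A_k, B_j]` | `alpha_jk > 0` | `-alpha_jk^2` |
| positive path `[A_k, B_j, A_i]` | `alpha_jk, beta_ji > 0` | `alpha_jk * beta_ji` |
| negative path `[A_k, B_j, ~A_i]` | `alpha_jk, alpha_ji > 0`, `i != k` | `-alpha_jk * alpha_ji` |

A cycle chains paths (end species = next start species) over pairwise
distinct start species; its weight is the product of path weights. A
subgraph of a fragment covers each fragment species with exactly one
component (edge, or path inside a cycle) and consumes exactly the
fragment's reaction multiset; `K_g = (-1)^c * prod K_C * prod(-K_E)`.
`K_S = sum K_g`; `K_S < 0` marks the fragment critical.

The edge weight deserves a note. For the coefficient identity

    a_k(u,w) = sum_S K_S * prod(w_j) / prod(u_i)

to hold entrywise against `J_ik = sum_j S_ji alpha_jk w_j / u_k`, the
order-1 case already forces `-K_E = alpha^2`: the fragment `({i},{j})`
must contribute `(alpha_ji^2 - alpha_ji beta_ji) * w_j/u_i`, which is
the edge term `alpha^2` minus the self-loop 1-cycle term `alpha*beta`.
Defining `K_E = -alpha` instead breaks the identity whenever a reactant
coefficient exceeds 1. The randomized symbolic tests (coefficients up
to 2) pin this down empirically; with unit coefficients, as in all
packaged mechanisms, the two conventions coincide. Negative paths
require two *distinct* reactant species; a species appearing with
`alpha = 2` interacts with itself only through the `alpha^2` edge term,
not through a negative self-path (the same order-1 derivation shows a
negative self-path would double-count).

## Enumeration pipeline

1. **Fragments.** Every fragment contains an edges-only subgraph, and
   every choice of one outgoing edge per species of a `k`-subset induces
   a fragment. Enumeration therefore walks `k`-subsets of species and
   the cartesian product of their edge targets, collapsing assignments
   to deduplicated `(species set, reaction multiset)` keys. Two
   assignments with the same key are the *same* fragment — without the
   merge, fragment weights would double-count monomials and the
   coefficient identity fails. Keys stream lazily in lexicographic
   order; memory is bounded by the per-subset key set. The
   `C(N,k) * R^k` combinatorial generator is retained as a test oracle
   and for cost reporting (`count_generated`).
2. **Lookup table.** For one fragment, components are generated per
   species, restricted to pairs `(s, j)` that occur in at least one full
   edge assignment of the key (a matching-feasibility check). Bare
   multiset membership would be correct too — components that cannot
   complete never survive — but the assignment-restricted table
   reproduces the published worked example's path graph exactly and
   prunes earlier.
3. **Cycles: path graph.** Nodes are the fragment's paths (negative
   paths in both orientations), identified by
   `(start, reaction, end, polarity)`; arcs chain end to start;
   self-loops allowed. Cycles are elementary circuits, enumerated by a
   rooted depth-first search that only descends to larger node indices
   (each circuit reported once, rotations collapsed by a canonical
   rotation) and abandons a branch as soon as a start species repeats —
   the pruning happens during the search, not post hoc, so invalid
   closed walks are never materialized. A stock circuit enumerator plus
   post-filtering serves as the test oracle.
4. **Subgraphs: cycle graph.** Nodes are the fragment's cycles
   (pre-filtered to those whose reaction multiset fits the key), edges
   join species-disjoint cycles. Every clique — enumerated via
   networkx, with the empty clique added explicitly since edges-only
   subgraphs come from it — is checked for joint reaction-multiset
   feasibility, then completed by assigning each uncovered species an
   edge from the remaining reaction budget, most-constrained species
   first, by exhaustive backtracking. Each completion is one subgraph;
   whole subgraphs are deduplicated by the sorted canonical forms of
   their components.

Fragments are independent work units: the driver optionally spreads
them over a `multiprocessing` pool (the published tool's separate
server/client scripts are collapsed into this in-process queue, same
semantics without a network surface), and the report is sorted by
`(order, species, reactions)` so any worker count yields byte-identical
output.

## Symbolic verification layer

`critfrag.charpoly` rebuilds each `a_k` directly from the Jacobian:
`det(lambda*I - J)` is computed as
`det(lambda*diag(u) - J*diag(u)) / prod(u)` so the determinant stays
polynomial (division-free Berkowitz), and the graph-side coefficient is
assembled from fragment weights. Equality is decided exactly — the
difference is expanded over the common denominator `u_1...u_n` and must
vanish identically; no numerical sampling, no tolerance. The layer is
guarded at `n <= 9`, past which symbolic expansion stops being a
practical oracle. `a_k` is defined as the sum of the `k x k` principal
minors of `-J` (so `a_n = det(-J)`), the convention under which the
published worked coefficient comes out verbatim.

Exact arithmetic is used wherever a criterion gates on a value: the
stoichiometric rank (fraction-free Gaussian elimination over the
rationals, cross-checked in tests against sympy's rref) and all weight
sums (integers).

## Packaged mechanisms and corrections

Five published networks ship as plain-text fixtures: reversible
substrate inhibition (n=4, m=6, rank 3), the glycolysis–gluconeogenesis
switch (7, 10, rank 5), the yeast Cdc42 polarity network (8, 12), and
the single- (9, 12, rank 6) and double-layer (12, 18, rank 9) MAPK
cascades. Three printed lines are evidently typos, and the package is
explicit about each:

* **Cdc42 B12** `RDIm -> RDIm`: a net-zero self-loop.
* **Cdc42 B5** `Em + RD -> Em`: destroys conservation of total Cdc42
  and leaves rank 6 where the published analysis has 5. The underlying
  polarity model's step is the Em-catalyzed activation
  `Em + RD -> Em + RT`, the analogue of B6.
* **Single-layer MAPK B6** `ApE1 -> App`: loses the kinase (rank 7, not
  the published 6); the double-layer listing prints the analogous step
  as `ApE1 -> App + E1`, which the fixture adopts.

`cdc42_as_printed` keeps the listing verbatim (rank 6, 51 negative
fragments at order 5); `cdc42_corrected_b12` fixes B5 and B12 and
reproduces the published rank 5 and exactly 35 critical fragments at
order 5 — the corrected variant is what the acceptance script reports.
The single-layer MAPK fixture ships corrected, since the verbatim line
reproduces none of the published numbers.

## Double-layer MAPK at full order

The order-9 screen of the double-layer cascade enumerates 82,880
fragments in roughly three minutes on one CPU and finds **80** critical
fragments (each of weight −1), where the original report states 88.
Because the symbolic layer cannot expand an `n = 12` determinant, the
result is validated numerically-exactly instead (`identity_at_points`,
exercised by the test suite's full-scale screen): at random rational
`(u, w)` points, the fragment-weight sum over all 82,880 order-9
fragments equals the `a_9` coefficient of `det(lambda*I - J)` of the
12×12 Jacobian exactly (rational arithmetic, two independent points).
Any missed or misweighted fragment would break this equality except on
a measure-zero set of points. The count of 80 is therefore correct for
the reaction list as printed; the larger published figure most likely
reflects a differing supplementary mechanism file or duplicate counting
in the original implementation. An assignment-multiplicity reading
(counting a fragment once per edges-only assignment) is ruled out too:
every critical fragment here has exactly one edges-only subgraph.

## Randomized test conditions

The random-mechanism generator draws, per reaction, up to two distinct
reactant and up to two distinct product species with coefficients in
`[1, max_stoich]` (default 2 — the smallest value that distinguishes
the `alpha^2` edge weight from `alpha`), and with probability 0.2 makes
the reaction a pure inflow or outflow instead, mirroring the boundary
flows common in the published examples. Species left unused are
appended as a product of a random reaction so mechanism invariants
hold. Draws are reproducible from an integer seed. Test sizes
(`n <= 6`, `m <= 8`) keep the brute-force oracles exhaustive; they
exercise every structural feature the algorithm branches on (self-loop
paths, negative-pair cycles, repeated reactions, catalysts, boundary
flows) but not, of course, the scale of real signaling networks — scale
correctness rests on the exact-identity validations above.

## Known limitations

* Mass-action kinetics only; integer stoichiometry; no SBML import.
* The symbolic oracle is exponential in `n` (guarded at 9); larger
  networks rely on the graph pipeline plus pointwise exact identity
  checks.
* Criticality is a necessary condition: a critical fragment licenses,
  but does not prove, the corresponding instability.
* Subgraph enumeration is exact, never sampled; fragments with enormous
  cycle sets are handled by the clique decomposition but have no
  approximate fallback.
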