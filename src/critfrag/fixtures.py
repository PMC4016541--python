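"""Packaged example mechanisms and a seeded random-mechanism generator.

The packaged fixtures are the mechanisms analyzed in the source
literature for this method: reversible substrate inhibition, the
glycolysis-gluconeogenesis switch, the yeast Cdc42 polarity network
(in two variants, see below), and the single- and double-layer MAPK
cascades.  The random generator supports the randomized oracle tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .mechanism import Mechanism, Reaction, Species, parse_mechanism

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_text",
           "RandomMechanismSpec", "random_mechanism"]

#: Available fixture names.  ``cdc42_as_printed`` keeps the published
#: reaction list verbatim, including two apparent typos: B12 is the
#: net-zero self-loop RDIm -> RDIm, and B5 (Em + RD -> Em) destroys the
#: conservation of total Cdc42, leaving the stoichiometric rank at 6
#: instead of the documented 5.  ``cdc42_corrected_b12`` restores the
#: membrane-detachment step B12: RDIm -> RDIc and the Em-catalyzed
#: activation B5: Em + RD -> Em + RT (the analogue of B6), which
#: recovers the three conservation relations and rank 5.
FIXTURE_NAMES = (
    "reversible_substrate_inhibition",
    "glycolysis_gluconeogenesis",
    "cdc42_as_printed",
    "cdc42_corrected_b12",
    "mapk_single",
    "mapk_double",
)


def fixture_text(name: str) -> str:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return (resources.files("critfrag.data") / f"{name}.txt").read_text()


def load_fixture(name: str) -> Mechanism:
    """Load a packaged mechanism by name."""
    return parse_mechanism(fixture_text(name))


@dataclass(frozen=True)
class RandomMechanismSpec:
    """Parameters of the random-mechanism draw.

    Each reaction draws up to two distinct reactant species and up to
    two distinct product species, with coefficients uniform in
    [1, max_stoich]; with probability ``boundary_prob`` the reaction is
    instead a pure inflow or outflow of one species.  Species left
    unused are appended as a product of a random reaction so the
    mechanism invariant (every species appears somewhere) holds.
    """

    n_species: int
    n_reactions: int
    max_stoich: int = 2
    boundary_prob: float = 0.2
    seed: int = 0


def random_mechanism(spec: RandomMechanismSpec) -> Mechanism:
    """Draw a mechanism reproducibly from ``spec.seed``."""
    if spec.n_species < 1 or spec.n_reactions < 1:
        raise ValueError("need at least one species and one reaction")
    rng = random.Random(spec.seed)
    n = spec.n_species
    reactions: list[Reaction] = []

    def draw_side() -> dict[int, int]:
        count = rng.randint(0, min(2, n))
        chosen = rng.sample(range(1, n + 1), count)
        return {i: rng.randint(1, spec.max_stoich) for i in sorted(chosen)}

    for j in range(1, spec.n_reactions + 1):
        if rng.random() < spec.boundary_prob:
            sp = rng.randint(1, n)
            if rng.random() < 0.5:
                reactants, products = {}, {sp: 1}
            else:
                reactants, products = {sp: 1}, {}
        else:
            reactants = draw_side()
            products = draw_side()
            while not reactants and not products:
                reactants = draw_side()
                products = draw_side()
        reactions.append(Reaction(index=j, reactants=reactants,
                                  products=products, rate_label=f"k{j}"))
    used = set()
    for r in reactions:
        used |= set(r.reactants) | set(r.products)
    for i in range(1, n + 1):
        if i not in used:
            j = rng.randrange(len(reactions))
            r = reactions[j]
            reactions[j] = Reaction(index=r.index, reactants=r.reactants,
                                    products={**r.products, i: 1},
                                    rate_label=r.rate_label)
    species = [Species(index=i, name=f"A{i}") for i in range(1, n + 1)]
    return Mechanism(species=species, reactions=reactions)
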