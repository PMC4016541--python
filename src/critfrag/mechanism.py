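"""Mass-action mechanism model: parsing, stoichiometry, structural checks.

A mechanism is a list of elementary reactions

    B_j:  sum_i alpha_ji A_i  ->  sum_i beta_ji A_i,      j = 1..m

over species A_1..A_n, with nonnegative integer stoichiometric
coefficients and one rate constant per reaction.  Reversible steps are
written as two separate lines.  The plain-text dialect is one reaction
per line::

    A1 + A2 -> A3 ; k3
    2 A1 -> 0 ; k7        # coefficient prefix, "0" (or nothing) is the
                          # empty complex; "#" starts a comment

Species are numbered 1..n in order of first appearance, reactions 1..m
in file order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "Mechanism",
    "MechanismParseError",
    "parse_mechanism",
    "serialize_mechanism",
    "stoichiometric_matrix",
    "stoich_rank",
    "validate_mechanism",
]


class MechanismParseError(ValueError):
    """Raised for malformed mechanism text; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Species:
    """A chemical species: 1-based index and unique name."""

    index: int
    name: str


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction.

    ``reactants`` and ``products`` map species index -> positive integer
    stoichiometric coefficient (absent means 0).  Either side may be
    empty: an inflow has no reactants, an outflow no products.
    """

    index: int
    reactants: dict[int, int]
    products: dict[int, int]
    rate_label: str

    def alpha(self, i: int) -> int:
        return self.reactants.get(i, 0)

    def beta(self, i: int) -> int:
        return self.products.get(i, 0)

    @property
    def is_inflow(self) -> bool:
        return not self.reactants

    @property
    def is_outflow(self) -> bool:
        return not self.products

    @property
    def is_true_reaction(self) -> bool:
        """True when the reaction is neither a pure inflow nor a pure outflow."""
        return bool(self.reactants) and bool(self.products)


@dataclass
class Mechanism:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def m(self) -> int:
        return len(self.reactions)

    def species_name(self, i: int) -> str:
        return self.species[i - 1].name

    def species_index(self, name: str) -> int:
        for sp in self.species:
            if sp.name == name:
                return sp.index
        raise KeyError(name)


_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _parse_side(text: str, line_no: int, names: dict[str, int],
                species: list[Species]) -> dict[int, int]:
    """Parse one side of a reaction into {species index: coefficient}."""
    text = text.strip()
    if text in ("", "0"):
        return {}
    out: dict[int, int] = {}
    for term in text.split("+"):
        tokens = term.split()
        if not tokens:
            raise MechanismParseError("empty term", line_no)
        if len(tokens) == 1:
            coeff, name = 1, tokens[0]
        elif len(tokens) == 2:
            if not tokens[0].isdigit() or int(tokens[0]) <= 0:
                raise MechanismParseError(
                    f"coefficient {tokens[0]!r} is not a positive integer", line_no)
            coeff, name = int(tokens[0]), tokens[1]
        else:
            raise MechanismParseError(f"cannot parse term {term.strip()!r}", line_no)
        if not _NAME_RE.match(name):
            raise MechanismParseError(f"invalid species name {name!r}", line_no)
        if name not in names:
            names[name] = len(species) + 1
            species.append(Species(index=len(species) + 1, name=name))
        out[names[name]] = out.get(names[name], 0) + coeff
    return out


def parse_mechanism(text: str) -> Mechanism:
    """Parse mechanism-file contents into a :class:`Mechanism`.

    Species are numbered in order of first appearance; reactions in file
    order.  Raises :class:`MechanismParseError` on malformed lines,
    duplicate rate labels, or an empty file.
    """
    names: dict[str, int] = {}
    species: list[Species] = []
    reactions: list[Reaction] = []
    labels: set[str] = set()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise MechanismParseError("missing '->' arrow", line_no)
        lhs, rhs = line.split("->", 1)
        if ";" not in rhs:
            raise MechanismParseError("missing '; rate_label' clause", line_no)
        rhs, label = rhs.rsplit(";", 1)
        label = label.strip()
        if not label:
            raise MechanismParseError("empty rate label", line_no)
        if label in labels:
            raise MechanismParseError(f"duplicate rate label {label!r}", line_no)
        labels.add(label)
        reactants = _parse_side(lhs, line_no, names, species)
        products = _parse_side(rhs, line_no, names, species)
        if not reactants and not products:
            raise MechanismParseError("reaction with both sides empty", line_no)
        reactions.append(Reaction(index=len(reactions) + 1,
                                  reactants=reactants, products=products,
                                  rate_label=label))
    if not reactions:
        raise MechanismParseError("no reactions found (empty mechanism file)")
    return Mechanism(species=species, reactions=reactions)


def _side_to_text(side: dict[int, int], mech: Mechanism) -> str:
    if not side:
        return "0"
    terms = []
    for i in sorted(side, key=mech.species_name):
        c = side[i]
        name = mech.species_name(i)
        terms.append(name if c == 1 else f"{c} {name}")
    return " + ".join(terms)


def serialize_mechanism(mech: Mechanism) -> str:
    """Canonical text form; ``parse_mechanism`` inverts it exactly."""
    lines = []
    for r in mech.reactions:
        lines.append(f"{_side_to_text(r.reactants, mech)} -> "
                     f"{_side_to_text(r.products, mech)} ; {r.rate_label}")
    return "\n".join(lines) + "\n"


def stoichiometric_matrix(mech: Mechanism) -> np.ndarray:
    """The n x m integer matrix S with S[i-1, j-1] = beta_ji - alpha_ji."""
    S = np.zeros((mech.n, mech.m), dtype=np.int64)
    for r in mech.reactions:
        for i, c in r.reactants.items():
            S[i - 1, r.index - 1] -= c
        for i, c in r.products.items():
            S[i - 1, r.index - 1] += c
    return S


def stoich_rank(S: np.ndarray | Mechanism) -> int:
    """Exact rank of the stoichiometric matrix over the rationals.

    The rank gates the multistability criterion (it is the order at which
    critical fragments are required), so it is computed with exact
    fraction-free Gaussian elimination rather than a floating-point SVD.
    """
    if isinstance(S, Mechanism):
        S = stoichiometric_matrix(S)
    rows = [[Fraction(int(x)) for x in row] for row in np.asarray(S)]
    rank = 0
    n_rows = len(rows)
    n_cols = len(rows[0]) if n_rows else 0
    col = 0
    while rank < n_rows and col < n_cols:
        pivot = next((r for r in range(rank, n_rows) if rows[r][col] != 0), None)
        if pivot is None:
            col += 1
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        pv = rows[rank][col]
        for r in range(rank + 1, n_rows):
            if rows[r][col] != 0:
                f = rows[r][col] / pv
                rows[r] = [a - f * b for a, b in zip(rows[r], rows[rank])]
        rank += 1
        col += 1
    return rank


def validate_mechanism(mech: Mechanism) -> list[str]:
    """Check the consumed-and-produced-in-a-true-reaction assumption.

    The graph-theoretic stability results assume every species is both
    consumed and produced by at least one true reaction (one that is
    neither a pure inflow nor a pure outflow).  Returns one warning
    string per violating species; warnings do not block analysis.
    """
    warnings = []
    for sp in mech.species:
        consumed = any(r.is_true_reaction and r.alpha(sp.index) > 0
                       for r in mech.reactions)
        produced = any(r.is_true_reaction and r.beta(sp.index) > 0
                       for r in mech.reactions)
        if not (consumed and produced):
            missing = []
            if not consumed:
                missing.append("consumed")
            if not produced:
                missing.append("produced")
            warnings.append(
                f"species {sp.name} is not {' or '.join(missing)} "
                f"in any true (non-inflow/outflow) reaction")
    return warnings
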