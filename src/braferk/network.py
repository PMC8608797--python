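"""Reaction-network data model and the BRAFV600E-MEK-ERK cascade builder.

The cascade couples three ingredients:

* a reduced MAPK cascade in which the top tier is a single, constitutively
  active node (mutant BRAF), and MEK and ERK require double phosphorylation
  for activation, with phosphatases (phosph1, phosph2) reversing each step;
* explicit ATP-dependent phosphorylation — a kinase must carry a bound ATP,
  which is converted to ADP when the phosphate is transferred;
* the two inhibitors: dabrafenib (DBF) competes with ATP for BRAF's
  nucleotide pocket, while trametinib (TMT) occupies a third, allosteric MEK
  site and blocks catalysis without excluding ATP or substrate.

The full inventory (both drugs enabled) is 36 reactions over 36 molecular
species.  Reversible binding steps are counted as single reactions carrying a
forward (``a``) and reverse (``d``) constant, as in the governing mass-action
equations; catalytic steps are irreversible with a ``k`` constant.

The reaction list itself is data, not code: it is shipped as a tab-separated
table (``data/reactions.tsv``) that the builder reads, so the inventory can be
audited and edited without touching the builder.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping

__all__ = [
    "Species",
    "Reaction",
    "ElementaryStep",
    "ReactionNetwork",
    "Violation",
    "ValidationReport",
    "build_cascade_network",
    "species_inventory",
    "validate_network",
    "load_reaction_table",
    "DOT",
]

#: Separator used in complex names (e.g. ``BRAF·ATP·MEK``).
DOT = "·"

Role = Literal["kinase", "substrate", "phosphatase", "drug", "nucleotide", "complex"]
DrugTag = Literal["none", "dbf", "tmt"]

_ROLE_BY_NAME: dict[str, Role] = {
    "BRAF": "kinase",
    "MEK": "substrate",
    "pMEK": "substrate",
    "ppMEK": "kinase",  # doubly phosphorylated MEK is the active tier-2 enzyme
    "ERK": "substrate",
    "pERK": "substrate",
    "ppERK": "substrate",
    "phosph1": "phosphatase",
    "phosph2": "phosphatase",
    "ATP": "nucleotide",
    "ADP": "nucleotide",
    "DBF": "drug",
    "TMT": "drug",
}

_PHOSPHO_RE = re.compile(r"^(p{1,2})(?=[A-Z])")


@dataclass(frozen=True)
class Species:
    """A molecular entity: free protein, nucleotide, drug, or bound complex.

    ``phospho_count`` counts phosphate groups carried by the species' own
    name (0 for complexes, whose phosphorylation state lives on their
    constituents).  ``constituents`` is empty unless the species is a
    complex, in which case it lists the primitive species names in the
    canonical order enzyme · ATP · drug · substrate.
    """

    name: str
    role: Role
    phospho_count: int = 0
    constituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role == "complex":
            if len(self.constituents) < 2:
                raise ValueError(f"complex {self.name!r} needs >=2 constituents")
        elif self.constituents:
            raise ValueError(f"non-complex {self.name!r} cannot have constituents")
        if self.phospho_count not in (0, 1, 2):
            raise ValueError(f"{self.name!r}: phospho_count must be 0, 1 or 2")

    @property
    def is_complex(self) -> bool:
        return self.role == "complex"

    def base_name(self) -> str:
        """Name with phosphorylation prefixes stripped (``ppMEK`` -> ``MEK``)."""
        return self.name[self.phospho_count:]


def classify_species(name: str) -> Species:
    """Build a :class:`Species` for a cascade name (complexes via dot notation)."""
    if DOT in name:
        return Species(name=name, role="complex", constituents=tuple(name.split(DOT)))
    m = _PHOSPHO_RE.match(name)
    phospho = len(m.group(1)) if m else 0
    role = _ROLE_BY_NAME.get(name)
    if role is None:
        # generic fallback used by toy fixture networks
        role = "substrate"
    return Species(name=name, role=role, phospho_count=phospho)


@dataclass(frozen=True)
class Reaction:
    """One numbered reaction: a reversible binding step or an irreversible
    catalytic step.

    A ``binding`` reaction has two reactants and one product and carries both
    a forward (association) and reverse (dissociation) rate-constant
    reference; a ``catalysis`` reaction has a single complex reactant, two or
    more products, and only a forward (catalytic) reference.
    """

    rid: str
    kind: Literal["binding", "catalysis"]
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    fwd_rate: str
    rev_rate: str | None = None
    drug_tag: DrugTag = "none"

    def __post_init__(self) -> None:
        if self.kind == "binding" and self.rev_rate is None:
            raise ValueError(f"{self.rid}: binding reactions are reversible")
        if self.kind == "catalysis" and self.rev_rate is not None:
            raise ValueError(f"{self.rid}: catalytic reactions are irreversible")

    def participants(self) -> tuple[str, ...]:
        return self.reactants + self.products


@dataclass(frozen=True)
class ElementaryStep:
    """A single directed mass-action step derived from a :class:`Reaction`."""

    rid: str
    kind: Literal["binding", "dissociation", "catalysis"]
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_ref: str
    drug_tag: DrugTag = "none"


@dataclass(frozen=True)
class ReactionNetwork:
    """Species and reaction inventory with independent per-drug toggles."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    include_dbf: bool = True
    include_tmt: bool = True

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def lookup(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def elementary_steps(self) -> tuple[ElementaryStep, ...]:
        """Expand reversible bindings into directed binding + dissociation steps."""
        steps: list[ElementaryStep] = []
        for r in self.reactions:
            if r.kind == "binding":
                steps.append(ElementaryStep(r.rid, "binding", r.reactants, r.products,
                                            r.fwd_rate, r.drug_tag))
                steps.append(ElementaryStep(r.rid, "dissociation", r.products, r.reactants,
                                            r.rev_rate, r.drug_tag))  # type: ignore[arg-type]
            else:
                steps.append(ElementaryStep(r.rid, "catalysis", r.reactants, r.products,
                                            r.fwd_rate, r.drug_tag))
        return tuple(steps)

    def moiety_counts(self, name: str) -> Counter[str]:
        """Primitive-constituent multiset of a species (phospho prefixes stripped)."""
        sp = self.lookup(name)
        if sp.is_complex:
            out: Counter[str] = Counter()
            for c in sp.constituents:
                out.update(self.moiety_counts(c))
            return out
        return Counter({sp.base_name(): 1})

    def phospho_load(self, name: str) -> int:
        """Total phosphate groups carried by a species, including constituents."""
        sp = self.lookup(name)
        if sp.is_complex:
            return sum(self.phospho_load(c) for c in sp.constituents)
        return sp.phospho_count


# ---------------------------------------------------------------------------
# reaction-table loading and network construction
# ---------------------------------------------------------------------------

def _split_side(side: str) -> tuple[str, ...]:
    return tuple(tok.strip() for tok in side.split("+"))


def load_reaction_table(text: str | None = None) -> tuple[Reaction, ...]:
    """Parse the packaged (or a user-supplied) reaction table.

    The table has one row per numbered reaction with columns
    ``id  kind  reactants  products  fwd_rate  rev_rate  drug_tag``;
    ``#`` lines are comments and reactant/product lists are ``+``-separated.
    """
    if text is None:
        text = (resources.files("braferk") / "data" / "reactions.tsv").read_text("utf-8")
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = rows[0].split("\t")
    expected = ["id", "kind", "reactants", "products", "fwd_rate", "rev_rate", "drug_tag"]
    if header != expected:
        raise ValueError(f"unexpected reaction-table header: {header}")
    reactions = []
    for ln in rows[1:]:
        rid, kind, reactants, products, fwd, rev, tag = (ln.split("\t") + [""])[:7]
        reactions.append(Reaction(
            rid=rid,
            kind=kind,  # type: ignore[arg-type]
            reactants=_split_side(reactants),
            products=_split_side(products),
            fwd_rate=fwd.strip(),
            rev_rate=rev.strip() or None,
            drug_tag=tag.strip() or "none",  # type: ignore[arg-type]
        ))
    return tuple(reactions)


def build_cascade_network(include_dbf: bool = True, include_tmt: bool = True,
                          table: str | None = None) -> ReactionNetwork:
    """Construct the cascade network, optionally without one or both drugs.

    Disabling a drug removes exactly the reactions tagged with it (and, by
    closure, every species containing that drug).  The species inventory is
    the closure of all reaction participants, ordered by first appearance in
    the reaction table, which makes construction deterministic.
    """
    keep = {"none"} | ({"dbf"} if include_dbf else set()) | ({"tmt"} if include_tmt else set())
    reactions = tuple(r for r in load_reaction_table(table) if r.drug_tag in keep)
    names: list[str] = []
    seen: set[str] = set()
    for r in reactions:
        for n in r.participants():
            if n not in seen:
                seen.add(n)
                names.append(n)
    species = tuple(classify_species(n) for n in names)
    return ReactionNetwork(species=species, reactions=reactions,
                           include_dbf=include_dbf, include_tmt=include_tmt)


def species_inventory(network: ReactionNetwork) -> list[Species]:
    """Deduplicated, deterministically ordered species list (one ODE each)."""
    out: list[Species] = []
    seen: set[str] = set()
    for s in network.species:
        if s.name not in seen:
            seen.add(s.name)
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    reaction_id: str | None
    check: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, reaction_id: str | None, check: str, message: str) -> None:
        self.violations.append(Violation(reaction_id, check, message))

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


_DRUG_MOIETY = {"dbf": "DBF", "tmt": "TMT"}


def validate_network(network: ReactionNetwork) -> ValidationReport:
    """Check every structural invariant; violations are reported, not raised.

    Checks cover species well-formedness, reaction arities, constituent
    (moiety) balance including the ATP->ADP bookkeeping of phosphorylation,
    drug tags, orphan species, and drug-flag consistency.
    """
    rep = ValidationReport()
    names = [s.name for s in network.species]
    for n, c in Counter(names).items():
        if c > 1:
            rep.add(None, "unique-names", f"species {n!r} listed {c} times")
    known = set(names)

    for s in network.species:
        if s.is_complex:
            missing = [c for c in s.constituents if c not in known]
            if missing:
                rep.add(None, "constituents",
                        f"complex {s.name!r} has unknown constituents {missing}")
        if s.role in ("drug", "nucleotide", "phosphatase") and s.phospho_count != 0:
            rep.add(None, "phospho", f"{s.name!r} ({s.role}) must have phospho_count 0")
        if s.name == "BRAF" and s.phospho_count != 0:
            rep.add(None, "phospho", "BRAF carries no explicit phosphorylation state")

    referenced: set[str] = set()
    for r in network.reactions:
        referenced.update(r.participants())
        unknown = [n for n in r.participants() if n not in known]
        if unknown:
            rep.add(r.rid, "orphan", f"references unknown species {unknown}")
            continue
        _check_arity(network, r, rep)
        _check_balance(network, r, rep)
        _check_drug_tag(network, r, rep)

    for n in known - referenced:
        rep.add(None, "orphan", f"species {n!r} appears in no reaction")

    for flag, tag in (("include_dbf", "dbf"), ("include_tmt", "tmt")):
        if not getattr(network, flag):
            offenders = [r.rid for r in network.reactions if r.drug_tag == tag]
            if offenders:
                rep.add(None, "flag-consistency",
                        f"{tag} reactions present while {flag} is false: {offenders}")
            moiety = _DRUG_MOIETY[tag]
            carriers = [s.name for s in network.species
                        if s.name in known and moiety in network.moiety_counts(s.name)]
            if carriers:
                rep.add(None, "flag-consistency",
                        f"{moiety}-containing species present while {flag} is false: {carriers}")

    if network.include_dbf and network.include_tmt and network.n_reactions != 36:
        rep.add(None, "count",
                f"full network must have 36 reactions, found {network.n_reactions}")
    return rep


def _check_arity(network: ReactionNetwork, r: Reaction, rep: ValidationReport) -> None:
    if r.kind == "binding":
        if len(r.reactants) != 2 or len(r.products) != 1:
            rep.add(r.rid, "arity", "binding must have 2 reactants and 1 product")
        elif not network.lookup(r.products[0]).is_complex:
            rep.add(r.rid, "arity", "binding product must be a complex")
    else:  # catalysis
        if len(r.reactants) != 1 or len(r.products) < 2:
            rep.add(r.rid, "arity", "catalysis must have 1 reactant and >=2 products")
        elif not network.lookup(r.reactants[0]).is_complex:
            rep.add(r.rid, "arity", "catalysis reactant must be a complex")


def _side_counts(network: ReactionNetwork, side: Iterable[str]) -> tuple[Counter[str], int]:
    moieties: Counter[str] = Counter()
    phospho = 0
    for n in side:
        moieties.update(network.moiety_counts(n))
        phospho += network.phospho_load(n)
    return moieties, phospho


def _check_balance(network: ReactionNetwork, r: Reaction, rep: ValidationReport) -> None:
    lhs, p_lhs = _side_counts(network, r.reactants)
    rhs, p_rhs = _side_counts(network, r.products)
    if r.kind == "binding":
        if lhs != rhs or p_lhs != p_rhs:
            rep.add(r.rid, "balance", f"binding does not conserve constituents: "
                                      f"{dict(lhs)}/{p_lhs} -> {dict(rhs)}/{p_rhs}")
        return
    # catalysis: either a phosphorylation (one ATP becomes ADP, phospho +1) or a
    # dephosphorylation (constituents identical, phospho -1)
    kinase_like = (p_rhs == p_lhs + 1
                   and rhs.get("ATP", 0) == lhs.get("ATP", 0) - 1
                   and rhs.get("ADP", 0) == lhs.get("ADP", 0) + 1
                   and {k: v for k, v in lhs.items() if k not in ("ATP", "ADP")}
                   == {k: v for k, v in rhs.items() if k not in ("ATP", "ADP")})
    phosphatase_like = (p_rhs == p_lhs - 1 and lhs == rhs)
    if not (kinase_like or phosphatase_like):
        rep.add(r.rid, "balance",
                f"catalysis is neither a phosphorylation (ATP->ADP, +1 P) nor a "
                f"dephosphorylation (-1 P): {dict(lhs)}/{p_lhs} -> {dict(rhs)}/{p_rhs}")


def _check_drug_tag(network: ReactionNetwork, r: Reaction, rep: ValidationReport) -> None:
    present = Counter()
    for n in r.participants():
        present.update(network.moiety_counts(n))
    for tag, moiety in _DRUG_MOIETY.items():
        has = present.get(moiety, 0) > 0
        if has and r.drug_tag != tag:
            rep.add(r.rid, "drug-tag", f"involves {moiety} but is tagged {r.drug_tag!r}")
        if r.drug_tag == tag and not has:
            rep.add(r.rid, "drug-tag", f"tagged {tag!r} but no participant contains {moiety}")
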