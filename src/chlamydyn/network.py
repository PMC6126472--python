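"""Compartmentalized genome-scale metabolic networks.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions, the implied stoichiometric matrix ``S`` (metabolites x reactions),
flux bounds in mmol/gDW/h, and a biomass objective.  Metabolite ids carry a
compartment suffix (``accoa_c`` = acetyl-CoA, cytosol); the ten compartments
are those of the *Chlamydomonas reinhardtii* reconstruction this package
models (extracellular space plus nine organellar/cytosolic compartments).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "COMPARTMENT_TAGS",
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkStats",
    "NetworkValidationError",
    "compute_stats",
]

#: compartment name -> id suffix tag ("_<tag>" on metabolite ids)
COMPARTMENTS: dict[str, str] = {
    "extracellular": "e",
    "cytosol": "c",
    "chloroplast": "h",
    "mitochondria": "m",
    "nucleus": "n",
    "eyespot": "s",
    "flagellum": "f",
    "glyoxysome": "x",
    "thylakoid_lumen": "l",
    "golgi": "g",
}
#: tag -> compartment name
COMPARTMENT_TAGS: dict[str, str] = {v: k for k, v in COMPARTMENTS.items()}

#: magnitude used for "unbounded" reactions, mmol/gDW/h
DEFAULT_BOUND = 1000.0

CATEGORIES = ("internal", "transport", "exchange", "biomass")


class NetworkValidationError(ValueError):
    """A network (or one of its components) violates a structural invariant."""


def split_compartment(met_id: str) -> tuple[str, str]:
    """Split a compartment-tagged metabolite id into (base_id, compartment).

    Raises :class:`NetworkValidationError` if the suffix is not one of the
    ten known tags.
    """
    base, sep, tag = met_id.rpartition("_")
    if sep and tag in COMPARTMENT_TAGS:
        return base, COMPARTMENT_TAGS[tag]
    raise NetworkValidationError(
        f"metabolite id {met_id!r} has no recognised compartment suffix "
        f"(expected one of {sorted(COMPARTMENT_TAGS)})"
    )


@dataclass(frozen=True)
class Metabolite:
    """A compartment-tagged chemical species."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            _, comp = split_compartment(self.id)
            object.__setattr__(self, "compartment", comp)
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"unknown compartment {self.compartment!r} for metabolite {self.id!r}"
            )
        if not self.name:
            object.__setattr__(self, "name", self.id)

    @property
    def base_id(self) -> str:
        """Metabolite id with its compartment suffix stripped (if tagged)."""
        tag = COMPARTMENTS[self.compartment]
        suffix = "_" + tag
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``category`` is one of internal / transport / exchange /
    biomass; leave it ``None`` to have it inferred from structure.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    category: str | None = None
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise NetworkValidationError(
                f"reaction {self.id!r}: unknown category {self.category!r}"
            )
        if not self.name:
            self.name = self.id

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    @property
    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


def infer_category(rxn: Reaction, met_compartment: Mapping[str, str]) -> str:
    """Infer a reaction's category from its structure.

    exchange  - touches exactly one metabolite (boundary pseudo-reaction);
    transport - moves identical base ids between exactly two compartments
                with no chemical change;
    internal  - everything else.  Biomass is never inferred; it must be
                tagged explicitly (or implied by the network objective).
    """
    if len(rxn.stoichiometry) == 1:
        return "exchange"
    comps = {met_compartment[m] for m in rxn.stoichiometry}
    if len(comps) == 2:
        lhs = Counter(_base(m, met_compartment[m]) for m in rxn.reactants)
        rhs = Counter(_base(m, met_compartment[m]) for m in rxn.products)
        if lhs and lhs == rhs:
            return "transport"
    return "internal"


def _base(met_id: str, compartment: str) -> str:
    suffix = "_" + COMPARTMENTS[compartment]
    return met_id[: -len(suffix)] if met_id.endswith(suffix) else met_id


def duplicate_key(rxn: Reaction) -> tuple:
    """Canonical stoichiometry key for duplicate-reaction detection.

    Coefficients are scaled to the smallest integer vector (via rational
    approximation) and the sign is canonicalized so the lexicographically
    smallest metabolite has a positive coefficient; a reaction and its exact
    reverse therefore map to the same key.
    """
    items = sorted(rxn.stoichiometry.items())
    pivot = items[0][1]  # any common real scale factor cancels here
    fracs = [Fraction(c / pivot).limit_denominator(10**6) for _, c in items]
    denom_lcm = 1
    for f in fracs:
        denom_lcm = denom_lcm * f.denominator // math.gcd(denom_lcm, f.denominator)
    ints = [int(f * denom_lcm) for f in fracs]
    g = 0
    for v in ints:
        g = math.gcd(g, abs(v))
    if g:
        ints = [v // g for v in ints]
    lead = next((v for v in ints if v != 0), 1)
    if lead < 0:
        ints = [-v for v in ints]
    return tuple((m, v) for (m, _), v in zip(items, ints))


@dataclass
class MetabolicNetwork:
    """Ordered metabolites + reactions with an optional biomass objective."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    default_bound: float = DEFAULT_BOUND
    id: str = "network"

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- lookup ---------------------------------------------------------
    @property
    def met_index(self) -> dict[str, int]:
        return self._met_index

    @property
    def rxn_index(self) -> dict[str, int]:
        return self._rxn_index

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- structure ------------------------------------------------------
    def stoichiometric_matrix(self, reactions: Iterable[str] | None = None) -> np.ndarray:
        """Dense S (m x n), columns restricted/ordered by ``reactions`` if given."""
        rxns = (
            self.reactions
            if reactions is None
            else [self.reaction(r) for r in reactions]
        )
        S = np.zeros((self.n_metabolites, len(rxns)))
        for j, rxn in enumerate(rxns):
            for met, coeff in rxn.stoichiometry.items():
                S[self._met_index[met], j] = coeff
        return S

    def infer_categories(self) -> None:
        """Fill in ``category`` for untagged reactions (idempotent; never
        reclassifies an explicit tag).  The objective reaction becomes
        biomass if untagged."""
        comp = {m.id: m.compartment for m in self.metabolites}
        for rxn in self.reactions:
            if rxn.category is None:
                if rxn.id == self.objective_id:
                    rxn.category = "biomass"
                else:
                    rxn.category = infer_category(rxn, comp)

    def validate(self) -> None:
        """Check all structural invariants; raise NetworkValidationError."""
        if not self.reactions:
            raise NetworkValidationError("network has no reactions")
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = [i for i, n in Counter(ids).items() if n > 1]
            raise NetworkValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = [i for i, n in Counter(rids).items() if n > 1]
            raise NetworkValidationError(f"duplicate reaction ids: {dup}")
        known = set(self._met_index)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
            if rxn.category == "exchange" and len(rxn.stoichiometry) != 1:
                raise NetworkValidationError(
                    f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
                )
        if self.objective_id is not None:
            if self.objective_id not in self._rxn_index:
                raise NetworkValidationError(
                    f"objective reaction {self.objective_id!r} not in network"
                )
            biomass = [r.id for r in self.reactions if r.category == "biomass"]
            if len(biomass) != 1:
                raise NetworkValidationError(
                    f"expected exactly one biomass reaction, found {biomass}"
                )

    # -- editing --------------------------------------------------------
    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective_id=self.objective_id,
            default_bound=self.default_bound,
            id=self.id,
        )

    def remove_reaction(self, rxn_id: str) -> None:
        self.reactions = [r for r in self.reactions if r.id != rxn_id]
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.category == "exchange"]

    def internal_reactions(self) -> list[Reaction]:
        """Everything that is not a boundary pseudo-reaction."""
        return [r for r in self.reactions if r.category != "exchange"]


@dataclass(frozen=True)
class NetworkStats:
    """Table-1-style summary counts of a network."""

    n_reactions: int
    n_metabolites: int
    n_unique_metabolites: int
    n_transport: int
    n_exchange: int
    per_compartment_metabolites: dict[str, int] = field(default_factory=dict)
    per_compartment_reaction_fraction: dict[str, float] = field(default_factory=dict)


def compute_stats(network: MetabolicNetwork) -> NetworkStats:
    """Summarize a network: sizes, unique (base-id) metabolites, transport and
    exchange counts, per-compartment tallies.

    Internal and biomass reactions are assigned to the compartment of their
    reactants (majority vote, ties broken lexicographically); exchange
    reactions tally as extracellular; transport reactions span compartments
    and are counted separately, so the fractions sum to <= 1.
    """
    network.infer_categories()
    met_comp = {m.id: m.compartment for m in network.metabolites}
    n_transport = sum(r.category == "transport" for r in network.reactions)
    n_exchange = sum(r.category == "exchange" for r in network.reactions)

    per_comp_met: Counter[str] = Counter(m.compartment for m in network.metabolites)

    rxn_comp: Counter[str] = Counter()
    for rxn in network.reactions:
        if rxn.category == "exchange":
            rxn_comp["extracellular"] += 1
        elif rxn.category == "transport":
            continue
        else:
            side = rxn.reactants or rxn.stoichiometry
            votes = Counter(met_comp[m] for m in side)
            top = max(votes.values())
            rxn_comp[min(c for c, v in votes.items() if v == top)] += 1

    n = network.n_reactions
    fractions = {c: v / n for c, v in sorted(rxn_comp.items())}
    return NetworkStats(
        n_reactions=n,
        n_metabolites=network.n_metabolites,
        n_unique_metabolites=len({m.base_id for m in network.metabolites}),
        n_transport=n_transport,
        n_exchange=n_exchange,
        per_compartment_metabolites=dict(sorted(per_comp_met.items())),
        per_compartment_reaction_fraction=fractions,
    )
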