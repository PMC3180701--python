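"""Core domain types for stoichiometric metabolic networks.

A metabolic network is a hypergraph: nodes are compounds, hyperedges are
reactions.  Internal compounds carry a steady-state mass-balance constraint;
external (boundary) compounds are treated as buffered reservoirs and are
exempt from balancing.  All stoichiometric coefficients are stored as exact
:class:`fractions.Fraction` values because downstream pathway analysis
(elementary-mode enumeration) requires exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

INTERNAL = "internal"
EXTERNAL = "external"


class NetworkError(Exception):
    """Base class for network construction/validation problems."""


class ValidationError(NetworkError):
    """The network violates a structural invariant."""


class LookupError_(NetworkError, KeyError):
    """Unknown compound or reaction id."""


def as_fraction(x) -> Fraction:
    """Convert ``x`` to an exact Fraction.

    Decimal strings are converted digit-exactly (``"0.15" -> 3/20``); floats
    are accepted but routed through their shortest repr so that a literal
    like ``0.15`` also maps to 3/20 rather than its binary expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(repr(x))
    return Fraction(str(x))


@dataclass
class Compound:
    """A metabolite node.

    role is ``"internal"`` (mass-balanced) or ``"external"`` (buffered
    boundary reservoir).
    """

    id: str
    name: str = ""
    role: str = INTERNAL

    def __post_init__(self) -> None:
        if self.role not in (INTERNAL, EXTERNAL):
            raise ValidationError(f"bad role {self.role!r} for compound {self.id}")

    @property
    def is_external(self) -> bool:
        return self.role == EXTERNAL


@dataclass
class Reaction:
    """A stoichiometric reaction.

    stoichiometry maps compound id -> signed rational coefficient
    (negative = consumed, positive = produced).  ``bounds`` are optional
    flux bounds in mmol/kg/h; ``default_rate`` is an optional fixed default
    flux (None when unknown).  ``gene_label`` is free-text enzyme/gene
    annotation such as ``"DFR(cy)"`` and is reporting metadata only.
    """

    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool = False
    gene_label: str | None = None
    bounds: tuple[Fraction, Fraction] | None = None
    default_rate: Fraction | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = {
            cid: as_fraction(c) for cid, c in self.stoichiometry.items()
        }
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValidationError(f"zero coefficient in reaction {self.id}")
        if self.bounds is not None:
            lo, hi = (as_fraction(self.bounds[0]), as_fraction(self.bounds[1]))
            if lo > hi:
                raise ValidationError(
                    f"reaction {self.id}: bound min {lo} > max {hi}"
                )
            self.bounds = (lo, hi)

    @property
    def substrates(self) -> set[str]:
        return {c for c, v in self.stoichiometry.items() if v < 0}

    @property
    def products(self) -> set[str]:
        return {c for c, v in self.stoichiometry.items() if v > 0}

    def mentions(self, compound_id: str) -> bool:
        return compound_id in self.stoichiometry


@dataclass
class MetabolicNetwork:
    """An ordered collection of compounds and reactions."""

    name: str = ""
    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)

    # -- construction -------------------------------------------------

    def add_compound(self, compound: Compound) -> None:
        if compound.id in self.compounds:
            raise ValidationError(f"duplicate compound id {compound.id}")
        self.compounds[compound.id] = compound

    def add_reaction(self, reaction: Reaction) -> None:
        if any(r.id == reaction.id for r in self.reactions):
            raise ValidationError(f"duplicate reaction id {reaction.id}")
        missing = sorted(set(reaction.stoichiometry) - set(self.compounds))
        if missing:
            raise ValidationError(
                f"reaction {reaction.id} references undeclared compounds: "
                + ", ".join(missing)
            )
        self.reactions.append(reaction)

    def validate(self) -> None:
        """Check referential integrity and that internal compounds are used."""
        for rxn in self.reactions:
            missing = sorted(set(rxn.stoichiometry) - set(self.compounds))
            if missing:
                raise ValidationError(
                    f"reaction {rxn.id} references undeclared compounds: "
                    + ", ".join(missing)
                )
        for cid, cpd in self.compounds.items():
            if not cpd.is_external and self.connectivity(cid) == 0:
                raise ValidationError(f"internal compound {cid} is in no reaction")

    # -- lookups ------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise LookupError_(f"unknown reaction id {rid!r}")

    def compound(self, cid: str) -> Compound:
        try:
            return self.compounds[cid]
        except KeyError:
            raise LookupError_(f"unknown compound id {cid!r}") from None

    def reactions_of(self, compound_id: str) -> list[Reaction]:
        """All reactions whose stoichiometry mentions the compound."""
        self.compound(compound_id)
        return [r for r in self.reactions if r.mentions(compound_id)]

    def connectivity(self, compound_id: str) -> int:
        """Number of reactions in which the compound participates.

        Either side counts; a reversible reaction counts once.
        """
        return len(self.reactions_of(compound_id))

    @property
    def internal_compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds.values() if not c.is_external]

    @property
    def external_compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds.values() if c.is_external]

    # -- matrices -----------------------------------------------------

    def stoichiometric_matrix(
        self, compound_ids: Iterable[str] | None = None
    ) -> tuple[list[str], list[list[Fraction]]]:
        """Exact stoichiometric matrix (rows = compounds, cols = reactions).

        Defaults to one row per internal compound, the convention under
        which steady state means S v = 0.
        """
        rows = (
            list(compound_ids)
            if compound_ids is not None
            else self.internal_compound_ids
        )
        S = [
            [rxn.stoichiometry.get(cid, Fraction(0)) for rxn in self.reactions]
            for cid in rows
        ]
        return rows, S

    def stoichiometric_array(
        self, compound_ids: Iterable[str] | None = None
    ) -> tuple[list[str], np.ndarray]:
        rows, S = self.stoichiometric_matrix(compound_ids)
        return rows, np.array([[float(x) for x in row] for row in S], dtype=float)

    # -- derived networks ---------------------------------------------

    def subnetwork(self, reaction_ids: Iterable[str], name: str = "") -> "MetabolicNetwork":
        """Induced subnetwork on the given reactions.

        Compounds mentioned by the chosen reactions are carried over with
        their current roles; role refinement is the caller's business
        (see :mod:`flavnet.extraction`).
        """
        keep = set(reaction_ids)
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise LookupError_(f"unknown reaction ids {sorted(unknown)}")
        rxns = [r for r in self.reactions if r.id in keep]
        mentioned = {cid for r in rxns for cid in r.stoichiometry}
        sub = MetabolicNetwork(name=name or f"{self.name}[sub]")
        for cid, cpd in self.compounds.items():
            if cid in mentioned:
                sub.add_compound(replace(cpd))
        for r in rxns:
            sub.add_reaction(
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    reversible=r.reversible,
                    gene_label=r.gene_label,
                    bounds=r.bounds,
                    default_rate=r.default_rate,
                )
            )
        return sub

    def without_reactions(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        drop = set(reaction_ids)
        return self.subnetwork(
            [rid for rid in self.reaction_ids if rid not in drop],
            name=f"{self.name}[-{len(drop)}]",
        )

    def set_roles(self, roles: Mapping[str, str]) -> None:
        for cid, role in roles.items():
            self.compound(cid).role = role
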