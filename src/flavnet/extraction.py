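"""Coherent-subnetwork extraction.

A genome-scale plant network is too large for exhaustive pathway analysis,
so a self-contained subnetwork is carved out around seed pathways.  The
heuristic iterates three steps to a fixed point:

1. compounds that are external in the growing prototype but internal in the
   full network have their full-network reactions traced back/forward and
   added;
2. compounds internal in both, but with full-network connectivity C_f much
   larger than subnetwork connectivity C_s, are reclassified external —
   they are ubiquitous carrier-like hubs buffered by the rest of
   metabolism; otherwise they are traced as in 1;
3. traced reactions join the prototype.

The result is *coherent* when every internal node of the subnetwork has
exactly the same set of incident reactions in the subnetwork as in the full
network, and every boundary node is either external in the full network,
on the curated buffered list, or hub-reclassified.  Termination is not
guaranteed in general; a growth guard aborts runaway extractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from .network import EXTERNAL, INTERNAL, MetabolicNetwork, as_fraction

__all__ = [
    "ExtractionConfig",
    "CoherenceReport",
    "ExtractionError",
    "preliminary_classification",
    "extract_coherent_subnetwork",
    "check_coherence",
]


class ExtractionError(RuntimeError):
    pass


@dataclass
class ExtractionConfig:
    """Knobs for the extraction heuristic.

    buffered_list: compound ids treated as external reservoirs (carriers,
    nucleoside phosphates, amino acids, nutrients — a curated list).
    hub_ratio / hub_min_connectivity interpret "C_f >> C_s": a compound is
    hub-reclassified external when C_f >= hub_ratio * C_s and
    C_f >= hub_min_connectivity.  max_growth_fraction aborts extractions
    that swallow most of the full network.
    """

    buffered_list: frozenset[str] = frozenset()
    seed_reaction_ids: frozenset[str] = frozenset()
    hub_ratio: Fraction = Fraction(3)
    hub_min_connectivity: int = 10
    max_iterations: int = 100
    max_growth_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.buffered_list = frozenset(self.buffered_list)
        self.seed_reaction_ids = frozenset(self.seed_reaction_ids)
        self.hub_ratio = as_fraction(self.hub_ratio)
        if self.hub_ratio <= 1:
            raise ValueError("hub_ratio must exceed 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class CoherenceReport:
    offending_nodes: list[tuple[str, int, int, str]] = field(default_factory=list)

    @property
    def coherent(self) -> bool:
        return not self.offending_nodes


def preliminary_classification(network: MetabolicNetwork) -> dict[str, str]:
    """Classify compounds external when they consistently appear on one side.

    A compound occurring only as a substrate in every reaction that mentions
    it (or only as a product) is a boundary input (output).  Participants of
    reversible reactions can sit on either side, so a reversible mention
    disqualifies the rule and the compound stays internal.  Compounds in no
    reaction are external by convention (flagged with a warning).
    """
    roles: dict[str, str] = {}
    for cid in network.compounds:
        rxns = network.reactions_of(cid)
        if not rxns:
            warnings.warn(f"compound {cid} is in no reaction; treated as external")
            roles[cid] = EXTERNAL
            continue
        sides = set()
        for r in rxns:
            if r.reversible:
                sides.update({"sub", "prod"})
            else:
                if r.stoichiometry[cid] < 0:
                    sides.add("sub")
                else:
                    sides.add("prod")
        roles[cid] = EXTERNAL if len(sides) == 1 else INTERNAL
    return roles


def extract_coherent_subnetwork(
    full: MetabolicNetwork, config: ExtractionConfig
) -> MetabolicNetwork:
    """Grow a coherent subnetwork around the seed reactions.

    Returns the converged subnetwork with compound roles assigned:
    internal for coherent interior nodes, external for full-network
    externals, buffered compounds and hub-reclassified compounds.
    Deterministic: compounds and candidate reactions are visited in sorted
    order.
    """
    missing_seeds = config.seed_reaction_ids - set(full.reaction_ids)
    if missing_seeds:
        raise ExtractionError(f"seed reactions not in network: {sorted(missing_seeds)}")
    if not config.seed_reaction_ids:
        raise ExtractionError("no seed reactions given")
    unknown_buffered = config.buffered_list - set(full.compounds)
    if unknown_buffered:
        warnings.warn(
            "buffered compounds not in network (ignored): "
            + ", ".join(sorted(unknown_buffered))
        )

    full_roles = preliminary_classification(full)
    externally_marked = set(config.buffered_list & set(full.compounds))
    externally_marked |= {c for c, role in full_roles.items() if role == EXTERNAL}
    # compounds already flagged external on the source network are honoured
    externally_marked |= set(full.external_compound_ids)

    sub_rxns: set[str] = set(config.seed_reaction_ids)
    hub_reclassified: set[str] = set()

    for _ in range(config.max_iterations):
        sub = full.subnetwork(sorted(sub_rxns))
        changed = False
        for cid in sorted(sub.compounds):
            if cid in externally_marked or cid in hub_reclassified:
                continue
            c_f = full.connectivity(cid)
            c_s = sub.connectivity(cid)
            if c_f == c_s:
                continue
            if (
                c_f >= config.hub_ratio * c_s
                and c_f >= config.hub_min_connectivity
            ):
                hub_reclassified.add(cid)
                continue
            for rxn in full.reactions_of(cid):
                if rxn.id not in sub_rxns:
                    sub_rxns.add(rxn.id)
                    changed = True
        if changed and len(sub_rxns) > config.max_growth_fraction * len(
            full.reactions
        ):
            raise ExtractionError(
                f"extraction swallowed {len(sub_rxns)}/{len(full.reactions)} "
                f"reactions (> {config.max_growth_fraction:.0%} guard); "
                "frontier is not converging"
            )
        if not changed:
            break
    else:
        raise ExtractionError(
            f"no fixed point within {config.max_iterations} iterations; "
            f"current subnetwork has {len(sub_rxns)} reactions"
        )

    result = full.subnetwork(sorted(sub_rxns), name=f"{full.name}[coherent]")
    for cid, cpd in result.compounds.items():
        if cid in externally_marked or cid in hub_reclassified:
            cpd.role = EXTERNAL
        else:
            cpd.role = INTERNAL
    return result


def check_coherence(full: MetabolicNetwork, sub: MetabolicNetwork) -> CoherenceReport:
    """Report internal subnetwork nodes whose incident-reaction sets differ
    between the subnetwork and the full network."""
    extra = set(sub.reaction_ids) - set(full.reaction_ids)
    if extra:
        raise ExtractionError(
            f"subnetwork reactions absent from full network: {sorted(extra)}"
        )
    report = CoherenceReport()
    for cid in sorted(sub.compounds):
        if sub.compounds[cid].is_external:
            continue
        sub_set = {r.id for r in sub.reactions_of(cid)}
        full_set = {r.id for r in full.reactions_of(cid)}
        if sub_set != full_set:
            report.offending_nodes.append(
                (
                    cid,
                    len(full_set),
                    len(sub_set),
                    "internal node missing reactions "
                    + ", ".join(sorted(full_set - sub_set)),
                )
            )
    return report
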