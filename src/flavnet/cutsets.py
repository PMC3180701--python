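"""Minimal cut sets (MCSs) and fragility coefficients.

A cut set for a set of objective reactions is a set of reactions whose
simultaneous blocking removes all steady-state flux through every
objective; it is minimal when no proper subset still does.  Because any
flux routing through an objective is a combination of the elementary modes
containing that objective (the *target* modes), the MCSs are exactly the
minimal hitting sets of the target-mode supports.  Enumeration uses the
Berge-style incremental dualisation: fold in one target support at a time,
extending each partial hitting set that misses it and pruning supersets.

The fragility coefficient of a reaction r is the mean of 1/|C| over the
MCSs C containing r: a reaction confined to large cut sets needs many
accomplices to matter, so its individual failure is less crucial for the
objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .elementary_modes import ElementaryMode
from .network import MetabolicNetwork

__all__ = [
    "ObjectiveSpec",
    "CutSet",
    "FragilityReport",
    "UncuttableModeError",
    "select_target_ems",
    "enumerate_mcs",
    "minimal_hitting_sets",
    "unaffected_counts",
    "fragility",
]


class UncuttableModeError(ValueError):
    """A target mode has no candidate reaction in its support."""


@dataclass
class ObjectiveSpec:
    """Objective reactions plus an optional restriction of cut candidates."""

    objective_reaction_ids: frozenset[str]
    candidate_reaction_ids: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.objective_reaction_ids = frozenset(self.objective_reaction_ids)
        if not self.objective_reaction_ids:
            raise ValueError("objective_reaction_ids must be nonempty")
        if self.candidate_reaction_ids is not None:
            self.candidate_reaction_ids = frozenset(self.candidate_reaction_ids)


@dataclass
class CutSet:
    reaction_ids: frozenset[str]
    unaffected_em_count: int | None = None
    gene_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reaction_ids = frozenset(self.reaction_ids)

    @property
    def size(self) -> int:
        return len(self.reaction_ids)

    def hits(self, support: frozenset[str]) -> bool:
        return bool(self.reaction_ids & support)


@dataclass
class FragilityReport:
    """Per-reaction fragility coefficients, exact.

    Only reactions occurring in at least one cut set appear; values lie in
    (0, 1].
    """

    fc: dict[str, Fraction]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {rid: round(float(v), ndigits) for rid, v in self.fc.items()}


def select_target_ems(
    ems: list[ElementaryMode],
    objective: ObjectiveSpec,
    network: MetabolicNetwork | None = None,
) -> list[ElementaryMode]:
    """Modes whose support intersects the objective reactions."""
    if network is not None:
        unknown = objective.objective_reaction_ids - set(network.reaction_ids)
        if unknown:
            raise KeyError(f"objective reactions not in network: {sorted(unknown)}")
    return [em for em in ems if em.support & objective.objective_reaction_ids]


def minimal_hitting_sets(
    sets: list[frozenset[str]],
) -> list[frozenset[str]]:
    """All minimal hitting sets of a family of nonempty sets (Berge)."""
    for s in sets:
        if not s:
            raise ValueError("cannot hit an empty set")
    hitting: list[frozenset[str]] = [frozenset()]
    for s in sorted(sets, key=lambda x: (len(x), tuple(sorted(x)))):
        hit = [h for h in hitting if h & s]
        miss = [h for h in hitting if not (h & s)]
        candidates = hit + [h | {r} for h in miss for r in sorted(s)]
        # prune non-minimal
        candidates.sort(key=len)
        pruned: list[frozenset[str]] = []
        for c in candidates:
            if not any(p <= c for p in pruned if p != c):
                if c not in pruned:
                    pruned.append(c)
        hitting = pruned
    return sorted(hitting, key=lambda h: (len(h), tuple(sorted(h))))


def enumerate_mcs(
    target_ems: list[ElementaryMode],
    candidates: frozenset[str] | None = None,
    network: MetabolicNetwork | None = None,
) -> list[CutSet]:
    """Minimal cut sets for the target modes.

    ``candidates`` restricts which reactions may appear in cuts; by default
    any reaction in a target support may.  A target mode whose support
    avoids the candidate set entirely cannot be blocked and raises
    :class:`UncuttableModeError`.  Results are sorted by size, then
    lexicographically; gene labels are attached when the network is given.
    """
    if not target_ems:
        return []
    if candidates is None:
        candidates = frozenset().union(*(em.support for em in target_ems))
    candidates = frozenset(candidates)
    supports = []
    for em in target_ems:
        cut_support = frozenset(em.support & candidates)
        if not cut_support:
            raise UncuttableModeError(
                "target mode with support "
                f"{sorted(em.support)} contains no candidate reaction"
            )
        supports.append(cut_support)
    label_of = {}
    if network is not None:
        label_of = {r.id: r.gene_label for r in network.reactions}
    cuts = []
    for h in minimal_hitting_sets(supports):
        labels = [
            label_of[rid]
            for rid in sorted(h)
            if label_of.get(rid) is not None
        ]
        cuts.append(CutSet(reaction_ids=h, gene_labels=labels))
    return cuts


def unaffected_counts(
    cutsets: list[CutSet],
    ems: list[ElementaryMode],
    universe: str | list[ElementaryMode] = "all",
    objective: ObjectiveSpec | None = None,
) -> list[CutSet]:
    """Fill in, per cut set, how many modes of the universe it leaves intact.

    A mode is unaffected when its support is disjoint from the cut.  The
    universe is either an explicit list of modes, ``"all"`` (every mode),
    or ``"non-target"`` (modes not hit by the objective reactions, the
    natural reading of "other processes"); class-restricted universes can
    be passed explicitly after :func:`classify_ems`.
    """
    if isinstance(universe, str):
        if universe == "all":
            pool = list(ems)
        elif universe == "non-target":
            if objective is None:
                raise ValueError("non-target universe needs an objective")
            targets = objective.objective_reaction_ids
            pool = [em for em in ems if not (em.support & targets)]
        else:
            raise ValueError(f"unknown universe {universe!r}")
    else:
        pool = list(universe)
    for cs in cutsets:
        cs.unaffected_em_count = sum(
            1 for em in pool if not cs.hits(em.support)
        )
    return cutsets


def fragility(cutsets: list[CutSet]) -> FragilityReport:
    """Fragility coefficient per reaction: mean reciprocal cut-set size."""
    if not cutsets:
        raise ValueError("fragility needs at least one cut set")
    sizes: dict[str, list[Fraction]] = {}
    for cs in cutsets:
        for rid in cs.reaction_ids:
            sizes.setdefault(rid, []).append(Fraction(1, cs.size))
    return FragilityReport(
        fc={rid: sum(vals) / len(vals) for rid, vals in sorted(sizes.items())}
    )
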