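"""Flux-balance reference states and knockout (cut-set) simulations.

The structural analysis says *which* reaction sets block pigment formation;
this module quantifies what each blockage does to the rest of the network.
Because measured fluxes for the subnetwork are unavailable, a plausible
*reference state* is constructed instead: product-formation rates derived
from tissue concentrations (assuming rate proportional to concentration,
mg/kg divided by molar mass giving mmol/kg/h up to a common constant that
cancels in ratios), a lignin drain tied to biomass growth, and range
constraints from other species.  Among all feasible steady states the
solver picks the L1-minimal total flux, refined lexicographically in
reaction order, so the state is fully deterministic.

Knockout states force the cut reactions to zero while holding the boundary
input fluxes at their reference values (the surrounding metabolism is
assumed undisturbed).  Results are reported as flux ratios
blocked/reference per reaction, averaged over the end reactions of each
product class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .elementary_modes import ElementaryMode, ProductClassMap
from .network import MetabolicNetwork, Reaction, as_fraction
from .cutsets import CutSet

__all__ = [
    "LigninSpec",
    "FluxConstraint",
    "FluxState",
    "RatioReport",
    "InfeasibleError",
    "convert_concentration",
    "split_class_total",
    "lignin_growth_flux",
    "lignin_pseudo_reaction",
    "solve_reference_state",
    "simulate_cut_state",
    "max_flux",
    "ratio_report",
    "parse_constraint_file",
]

LP_TOL = 1e-9

FIXED_VALUE = "fixed-value"
RANGE = "range"
FIXED_INPUT = "fixed-input"


class InfeasibleError(RuntimeError):
    pass


@dataclass
class LigninSpec:
    """Lignin composition and its coupling to biomass growth.

    The lignin macromolecule is assembled from the three monolignols in a
    fixed monomer ratio; with lignin at ``biomass_fraction`` of total
    biomass and specific growth rate ``growth_rate_mu`` (1/h), lignin
    synthesis must run at biomass_fraction * mu (1/h).
    """

    monomer_coefficients: dict[str, Fraction] = field(
        default_factory=lambda: {
            "CONIFERYL-ALCOHOL": Fraction(370),
            "SINAPYL-ALCOHOL": Fraction(238),
            "COUMARYL-ALCOHOL": Fraction(60),
        }
    )
    biomass_fraction: Fraction = Fraction(15, 100)
    growth_rate_mu: Fraction = Fraction(18, 100)

    def __post_init__(self) -> None:
        self.monomer_coefficients = {
            k: as_fraction(v) for k, v in self.monomer_coefficients.items()
        }
        self.biomass_fraction = as_fraction(self.biomass_fraction)
        self.growth_rate_mu = as_fraction(self.growth_rate_mu)
        if any(v <= 0 for v in self.monomer_coefficients.values()):
            raise ValueError("monomer coefficients must be positive")
        if not 0 <= self.biomass_fraction < 1:
            raise ValueError("biomass fraction must lie in [0, 1)")
        if self.growth_rate_mu < 0:
            raise ValueError("growth rate must be non-negative")


def lignin_growth_flux(spec: LigninSpec) -> Fraction:
    """Growth contribution of lignin synthesis: fraction * mu (1/h)."""
    return spec.biomass_fraction * spec.growth_rate_mu


def lignin_pseudo_reaction(spec: LigninSpec, rid: str = "LIGNIN-SYNTH") -> Reaction:
    """Drain reaction consuming the monolignols in the composition ratio."""
    return Reaction(
        id=rid,
        stoichiometry={cid: -coef for cid, coef in spec.monomer_coefficients.items()},
        reversible=False,
    )


def convert_concentration(mg_per_kg, molar_mass) -> Fraction:
    """mg/kg tissue concentration -> mmol/kg (read as mmol/kg/h rate).

    Rates are assumed proportional to concentrations; the unknown
    proportionality constant cancels in all reported flux ratios, so the
    plain quotient is used directly as a rate.
    """
    mg_per_kg = as_fraction(mg_per_kg)
    molar_mass = as_fraction(molar_mass)
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if mg_per_kg < 0:
        raise ValueError("concentration must be non-negative")
    return mg_per_kg / molar_mass


def split_class_total(total_mg_per_kg, molar_masses) -> list[Fraction]:
    """Convert a class-total concentration and split it over members.

    Used for compound classes measured only in aggregate: the total is
    converted with the arithmetic mean molar mass of the members and the
    resulting rate divided equally among them.
    """
    masses = [as_fraction(m) for m in molar_masses]
    if not masses:
        raise ValueError("need at least one molar mass")
    mean_mass = sum(masses) / len(masses)
    each = convert_concentration(total_mg_per_kg, mean_mass) / len(masses)
    return [each] * len(masses)


@dataclass
class FluxConstraint:
    """Bounds on one reaction rate in mmol/kg/h.

    provenance records how the bound arose: a measured fixed value
    (min == max), a literature range, or a boundary input pinned to its
    reference rate.
    """

    reaction_id: str
    min: Fraction
    max: Fraction
    provenance: str = RANGE

    def __post_init__(self) -> None:
        self.min = as_fraction(self.min)
        self.max = as_fraction(self.max)
        if self.min > self.max:
            raise ValueError(
                f"constraint on {self.reaction_id}: min {self.min} > max {self.max}"
            )
        if self.provenance == FIXED_VALUE and self.min != self.max:
            raise ValueError(
                f"fixed-value constraint on {self.reaction_id} must have min == max"
            )

    @classmethod
    def fixed(cls, reaction_id: str, value, provenance: str = FIXED_VALUE):
        v = as_fraction(value)
        return cls(reaction_id, v, v, provenance)


@dataclass
class FluxState:
    """A deterministic feasible flux vector."""

    rates: dict[str, float]
    kind: str = "reference"
    residual_norm: float = 0.0
    relaxed: bool = False

    def rate(self, rid: str) -> float:
        return self.rates[rid]


def parse_constraint_file(text: str) -> list[FluxConstraint]:
    """Parse a constraint file: ``<reaction id> <min> <max>`` per line,
    ``#`` comments; a single value column is read as a fixed value."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) == 2:
            out.append(FluxConstraint.fixed(tokens[0], tokens[1]))
        elif len(tokens) == 3:
            out.append(
                FluxConstraint(tokens[0], as_fraction(tokens[1]), as_fraction(tokens[2]))
            )
        else:
            raise ValueError(f"constraint line {lineno}: expected 2 or 3 columns")
    return out


def _assemble(network: MetabolicNetwork, constraints) -> tuple[np.ndarray, list]:
    """Balance matrix and per-reaction bounds (None = unbounded)."""
    _, S = network.stoichiometric_array()
    bounds = []
    for r in network.reactions:
        bounds.append((0.0, None) if not r.reversible else (None, None))
    index = {r.id: i for i, r in enumerate(network.reactions)}
    for fc in constraints:
        if fc.reaction_id not in index:
            raise KeyError(f"constraint references unknown reaction {fc.reaction_id}")
        bounds[index[fc.reaction_id]] = (float(fc.min), float(fc.max))
    return S, bounds


def _l1_lexicographic_solve(
    network: MetabolicNetwork, S: np.ndarray, bounds: list
) -> dict[str, float] | None:
    """Deterministic feasible point: L1-minimal |v|, then lexicographic
    minimisation of each rate in reaction order.  Returns None if
    infeasible."""
    n = len(network.reactions)
    m = S.shape[0] if S.size else 0
    # variables [v, t], minimise sum t with -t <= v <= t
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros((m, n))]) if m else None
    b_eq = np.zeros(m) if m else None
    eye = np.eye(n)
    A_ub = np.vstack(
        [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
    )
    b_ub = np.zeros(2 * n)
    var_bounds = list(bounds) + [(0.0, None)] * n
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds,
        method="highs",
    )
    if not res.success:
        return None
    # cap total |v| at its optimum, then pin rates one by one
    cap = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub = np.vstack([A_ub, cap])
    b_ub = np.concatenate([b_ub, [res.fun + LP_TOL]])
    pinned = list(var_bounds)
    x = res.x
    for i in range(n):
        obj = np.zeros(2 * n)
        obj[i] = 1.0
        res_i = linprog(
            obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=pinned,
            method="highs",
        )
        if not res_i.success:  # numerical corner: keep previous solution
            break
        x = res_i.x
        z = x[i]
        lo, hi = pinned[i]
        lo = z if lo is None else max(lo, z - LP_TOL)
        hi = z if hi is None else min(hi, z + LP_TOL)
        pinned[i] = (min(lo, hi), max(lo, hi))
    rates = {r.id: float(x[i]) for i, r in enumerate(network.reactions)}
    # snap numerical dust to zero
    for rid, v in rates.items():
        if abs(v) < LP_TOL:
            rates[rid] = 0.0
    return rates


def solve_reference_state(
    network: MetabolicNetwork, constraints: list[FluxConstraint]
) -> FluxState:
    """Deterministic feasible reference state under the given constraints.

    Feasibility means S_int v = 0 with all bounds satisfied; among feasible
    states the L1-minimal one (ties broken lexicographically in reaction
    order) is returned.  Raises :class:`InfeasibleError` listing the active
    constraints when the system has no solution.
    """
    S, bounds = _assemble(network, constraints)
    rates = _l1_lexicographic_solve(network, S, bounds)
    if rates is None:
        detail = "; ".join(
            f"{fc.reaction_id} in [{float(fc.min):g}, {float(fc.max):g}] ({fc.provenance})"
            for fc in constraints
        )
        raise InfeasibleError(
            "no feasible flux state; check for mutually contradictory bounds "
            f"among: {detail}"
        )
    v = np.array([rates[r.id] for r in network.reactions])
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    return FluxState(rates=rates, kind="reference", residual_norm=residual)


def fixed_inputs_from_reference(
    reference: FluxState, input_reaction_ids
) -> list[FluxConstraint]:
    """Pin the boundary input reactions at their reference rates."""
    return [
        FluxConstraint.fixed(rid, as_fraction(reference.rates[rid]), FIXED_INPUT)
        for rid in input_reaction_ids
    ]


def simulate_cut_state(
    network: MetabolicNetwork,
    reference: FluxState,
    cutset: CutSet,
    fixed_inputs: list[FluxConstraint],
    constraints: list[FluxConstraint] = (),
) -> FluxState:
    """Feasible state with the cut reactions forced to zero.

    The original constraints stay active and the input reactions stay at
    their reference values, except that a fixed input inside the cut set is
    dropped (with a warning) since the cut wins.  If the system is
    infeasible, range-type constraints are relaxed (flagged on the state);
    fixed inputs are never relaxed.
    """
    cut = set(cutset.reaction_ids)
    unknown = cut - set(network.reaction_ids)
    if unknown:
        raise KeyError(f"cut reactions not in network: {sorted(unknown)}")
    kept_inputs = []
    for fc in fixed_inputs:
        if fc.reaction_id in cut:
            warnings.warn(
                f"fixed input {fc.reaction_id} is inside the cut set; "
                "the knockout takes precedence"
            )
        else:
            kept_inputs.append(fc)
    zero_cuts = [FluxConstraint.fixed(rid, 0) for rid in sorted(cut)]

    def attempt(active_constraints):
        merged = list(active_constraints) + kept_inputs + zero_cuts
        S, bounds = _assemble(network, merged)
        return _l1_lexicographic_solve(network, S, bounds), S

    rates, S = attempt(constraints)
    relaxed = False
    if rates is None:
        rates, S = attempt([fc for fc in constraints if fc.provenance != RANGE])
        relaxed = True
    if rates is None:
        raise InfeasibleError(
            f"cut set {sorted(cut)} infeasible even after relaxing range "
            "constraints (fixed inputs kept)"
        )
    v = np.array([rates[r.id] for r in network.reactions])
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    return FluxState(
        rates=rates,
        kind="blocked:" + ",".join(sorted(cut)),
        residual_norm=residual,
        relaxed=relaxed,
    )


def max_flux(
    network: MetabolicNetwork,
    reaction_id: str,
    constraints: list[FluxConstraint] = (),
) -> float:
    """LP-maximal steady-state flux through one reaction under the bounds."""
    S, bounds = _assemble(network, constraints)
    n = len(network.reactions)
    c = np.zeros(n)
    c[network.reaction_ids.index(reaction_id)] = -1.0
    res = linprog(
        c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise InfeasibleError(f"maximising {reaction_id}: {res.message}")
    return float(-res.fun)


@dataclass
class RatioReport:
    """Blocked/reference flux ratios, per reaction and per product class.

    A ratio is undefined (None) where the reference rate is zero; undefined
    ratios are excluded from class averages rather than counted as zero.
    """

    per_reaction_ratio: dict[str, float | None]
    per_class_average: dict[str, float | None]
    end_reactions: dict[str, list[str]] = field(default_factory=dict)


def end_reactions_by_class(
    network: MetabolicNetwork,
    class_map: ProductClassMap,
    ems: list[ElementaryMode],
) -> dict[str, list[str]]:
    """End reactions of each class: reactions that directly produce one of
    the class's external compounds within some mode that net-produces it."""
    out: dict[str, list[str]] = {cls: [] for cls in class_map.classes}
    for cls, members in class_map.classes.items():
        found: set[str] = set()
        for em in ems:
            produced = em.produced_externals & members
            for cid in produced:
                for rid in em.support:
                    if network.reaction(rid).stoichiometry.get(cid, 0) > 0:
                        found.add(rid)
        out[cls] = sorted(found)
    return out


def ratio_report(
    blocked: FluxState,
    reference: FluxState,
    class_map: ProductClassMap,
    ems: list[ElementaryMode],
    network: MetabolicNetwork,
    tol: float = LP_TOL,
) -> RatioReport:
    """Normalise a knockout state against the reference state."""
    ratios: dict[str, float | None] = {}
    for rid, ref_rate in reference.rates.items():
        if abs(ref_rate) <= tol:
            ratios[rid] = None
        else:
            ratios[rid] = blocked.rates[rid] / ref_rate
    ends = end_reactions_by_class(network, class_map, ems)
    averages: dict[str, float | None] = {}
    for cls, rids in ends.items():
        defined = [ratios[rid] for rid in rids if ratios.get(rid) is not None]
        averages[cls] = sum(defined) / len(defined) if defined else None
    return RatioReport(
        per_reaction_ratio=ratios, per_class_average=averages, end_reactions=ends
    )
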