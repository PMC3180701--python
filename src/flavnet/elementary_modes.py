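"""Exact enumeration of elementary (flux) modes.

An elementary mode (EM) is a flux vector v with S_int v = 0, v_r >= 0 for
every irreversible reaction r, whose support (set of active reactions) is
minimal: no other steady-state, sign-feasible vector uses a proper subset
of its reactions.  Any feasible steady-state flux distribution is a
non-negative combination of EMs, so the EM set is a complete catalogue of
the network's minimal routes.

Enumeration follows the classical tableau (double-description) scheme with
exact rational arithmetic: reversible reactions are split into forward and
backward columns, the extreme rays of the pointed cone
{v >= 0, S v = 0} are built by pairwise combination while eliminating one
internal metabolite at a time, and the split columns are recombined
afterwards.  Futile two-cycles from the split (forward+backward of the same
reaction) are excluded during generation, which also guarantees
support-minimality of the recombined modes.  Complexity is combinatorial in
general; the intended scale is extracted subnetworks of a few hundred
reactions, not genome-scale networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

from .network import MetabolicNetwork

__all__ = [
    "ElementaryMode",
    "ProductClassMap",
    "OTHERS",
    "enumerate_ems",
    "classify_ems",
    "participation",
]

OTHERS = "others"


@dataclass(frozen=True)
class ElementaryMode:
    """One elementary mode in canonical form.

    Coefficients are coprime integers (as Fractions); for modes whose
    support is entirely reversible the overall sign is fixed by making the
    first nonzero coefficient (in network reaction order) positive.
    """

    coefficients: tuple[tuple[str, Fraction], ...]
    support: frozenset[str]
    net_external_production: tuple[tuple[str, Fraction], ...] = ()
    class_label: str | None = None

    def coefficient(self, rid: str) -> Fraction:
        return dict(self.coefficients).get(rid, Fraction(0))

    @property
    def coefficients_dict(self) -> dict[str, Fraction]:
        return dict(self.coefficients)

    @property
    def production_dict(self) -> dict[str, Fraction]:
        return dict(self.net_external_production)

    @property
    def produced_externals(self) -> frozenset[str]:
        return frozenset(c for c, v in self.net_external_production if v > 0)

    def relabel(self, label: str) -> "ElementaryMode":
        return ElementaryMode(
            self.coefficients,
            self.support,
            self.net_external_production,
            label,
        )


def enumerate_ems(network: MetabolicNetwork) -> list[ElementaryMode]:
    """Enumerate all elementary modes of the network, exactly.

    Returns canonical modes sorted by (support size, support ids).  A
    network with no internal compounds yields one single-reaction mode per
    reaction; an empty network yields an empty list.
    """
    reactions = network.reactions
    if not reactions:
        return []
    # split reversible reactions into forward/backward columns
    cols: list[tuple[str, int]] = []
    for r in reactions:
        cols.append((r.id, +1))
        if r.reversible:
            cols.append((r.id, -1))
    pair_of: dict[str, tuple[int, int]] = {}
    for j, (rid, sign) in enumerate(cols):
        if sign == -1:
            pair_of[rid] = (j - 1, j)

    internal_rows, S = network.stoichiometric_matrix()
    rxn_col = {r.id: j for j, r in enumerate(reactions)}
    m, n = len(internal_rows), len(cols)

    # tableau rows: (flux coefficients over split columns, metabolite residuals)
    tableau: list[tuple[list[Fraction], list[Fraction]]] = []
    for j, (rid, sign) in enumerate(cols):
        coeffs = [Fraction(0)] * n
        coeffs[j] = Fraction(1)
        resid = [S[i][rxn_col[rid]] * sign for i in range(m)]
        tableau.append((coeffs, resid))

    def support_of(coeffs: list[Fraction]) -> frozenset[int]:
        return frozenset(j for j, c in enumerate(coeffs) if c != 0)

    def has_split_pair(sup: frozenset[int]) -> bool:
        return any(a in sup and b in sup for a, b in pair_of.values())

    remaining = list(range(m))
    while remaining:
        # cheapest metabolite first: fewest pairwise combinations
        def cost(i: int) -> tuple[int, int]:
            pos = sum(1 for _, res in tableau if res[i] > 0)
            neg = sum(1 for _, res in tableau if res[i] < 0)
            return (pos * neg, i)

        i = min(remaining, key=cost)
        remaining.remove(i)

        keep = [row for row in tableau if row[1][i] == 0]
        pos = [row for row in tableau if row[1][i] > 0]
        neg = [row for row in tableau if row[1][i] < 0]
        supports = [support_of(c) for c, _ in tableau]
        new_rows: list[tuple[list[Fraction], list[Fraction]]] = []
        for pc, pr in pos:
            psup = support_of(pc)
            for nc, nr in neg:
                nsup = support_of(nc)
                union = psup | nsup
                if has_split_pair(union):
                    continue
                # candidate is elementary iff no other current ray's
                # support fits inside the union (classical minimality test)
                minimal = True
                for other_sup in supports:
                    if other_sup <= union and other_sup not in (psup, nsup):
                        minimal = False
                        break
                if not minimal:
                    continue
                a, b = pr[i], -nr[i]  # a>0, b>0
                coeffs = [b * pc[j] + a * nc[j] for j in range(n)]
                resid = [b * pr[j] + a * nr[j] for j in range(m)]
                _normalise(coeffs, resid)
                new_rows.append((coeffs, resid))
        tableau = keep + _drop_duplicates(new_rows)

    # recombine split columns and canonicalise
    order = [r.id for r in reactions]
    reversible = {r.id for r in reactions if r.reversible}
    ext_ids = network.external_compound_ids
    _, S_ext = network.stoichiometric_matrix(ext_ids)

    seen: set[tuple] = set()
    modes: list[ElementaryMode] = []
    for coeffs, _ in tableau:
        v: dict[str, Fraction] = {}
        for j, (rid, sign) in enumerate(cols):
            if coeffs[j] != 0:
                v[rid] = v.get(rid, Fraction(0)) + sign * coeffs[j]
        v = {rid: c for rid, c in v.items() if c != 0}
        if not v:
            continue
        v = _canonical(v, order, reversible)
        key = tuple(sorted(v.items()))
        if key in seen:
            continue
        seen.add(key)
        production = []
        for cid, row in zip(ext_ids, S_ext):
            total = sum(
                row[rxn_col[rid]] * c for rid, c in v.items()
            )
            if total != 0:
                production.append((cid, total))
        modes.append(
            ElementaryMode(
                coefficients=tuple(sorted(v.items())),
                support=frozenset(v),
                net_external_production=tuple(sorted(production)),
            )
        )
    modes.sort(key=lambda e: (len(e.support), tuple(sorted(e.support))))
    return modes


def _normalise(coeffs: list[Fraction], resid: list[Fraction]) -> None:
    """Scale a tableau row to coprime integers (in place)."""
    denom = 1
    for x in coeffs:
        if x != 0:
            denom = denom * x.denominator // gcd(denom, x.denominator)
    num = 0
    for x in coeffs:
        if x != 0:
            num = gcd(num, abs(int(x * denom)))
    if num:
        scale = Fraction(denom, num)
        for j in range(len(coeffs)):
            coeffs[j] *= scale
        for j in range(len(resid)):
            resid[j] *= scale


def _drop_duplicates(
    rows: list[tuple[list[Fraction], list[Fraction]]]
) -> list[tuple[list[Fraction], list[Fraction]]]:
    out, seen = [], set()
    for coeffs, resid in rows:
        key = tuple(coeffs)
        if key not in seen:
            seen.add(key)
            out.append((coeffs, resid))
    return out


def _canonical(
    v: dict[str, Fraction], order: list[str], reversible: set[str]
) -> dict[str, Fraction]:
    denom = 1
    for x in v.values():
        denom = denom * x.denominator // gcd(denom, x.denominator)
    num = 0
    for x in v.values():
        num = gcd(num, abs(int(x * denom)))
    scale = Fraction(denom, num)
    v = {rid: c * scale for rid, c in v.items()}
    if all(rid in reversible for rid in v):
        first = next(rid for rid in order if rid in v)
        if v[first] < 0:
            v = {rid: -c for rid, c in v.items()}
    return v


@dataclass
class ProductClassMap:
    """Grouping of external product compounds into named classes.

    ``classes`` maps class name -> compound ids; a compound belongs to at
    most one class.  ``priority`` orders classes for labelling EMs that
    produce compounds of several classes (pigment classes outrank other
    flavonoid classes, which outrank non-flavonoid groups); anything
    unmapped falls into ``"others"``.
    """

    classes: dict[str, frozenset[str]]
    priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.classes = {k: frozenset(v) for k, v in self.classes.items()}
        seen: dict[str, str] = {}
        for cls, members in self.classes.items():
            for cid in members:
                if cid in seen:
                    raise ValueError(
                        f"compound {cid} in two classes: {seen[cid]}, {cls}"
                    )
                seen[cid] = cls
        if not self.priority:
            self.priority = list(self.classes)
        missing = set(self.classes) - set(self.priority)
        if missing:
            self.priority = self.priority + sorted(missing)

    def class_of(self, compound_id: str) -> str | None:
        for cls, members in self.classes.items():
            if compound_id in members:
                return cls
        return None

    @property
    def class_names(self) -> list[str]:
        return list(self.priority) + [OTHERS]


def classify_ems(
    ems: list[ElementaryMode], class_map: ProductClassMap
) -> list[ElementaryMode]:
    """Label each EM by the class of its net-produced external compounds.

    Futile cycles (no net external production) and producers of unmapped
    compounds get ``"others"``.  An EM producing compounds of several
    classes is labelled by the highest-priority class and a warning is
    emitted, since well-curated class maps should not overlap on terminal
    products.
    """
    out = []
    rank = {cls: i for i, cls in enumerate(class_map.priority)}
    for em in ems:
        produced_classes = {
            class_map.class_of(cid) or OTHERS for cid in em.produced_externals
        }
        named = sorted(
            (c for c in produced_classes if c != OTHERS),
            key=lambda c: rank.get(c, len(rank)),
        )
        if not em.produced_externals or not named:
            label = OTHERS
        else:
            label = named[0]
            if len(named) > 1:
                warnings.warn(
                    f"EM with support {sorted(em.support)} produces several "
                    f"classes {named}; labelled {label}"
                )
        out.append(em.relabel(label))
    return out


def participation(
    ems: list[ElementaryMode], network: MetabolicNetwork | None = None
) -> dict[str, int]:
    """Count, per reaction, the number of EMs whose support contains it.

    With a network given, reactions appearing in no EM are reported as 0.
    """
    counts: dict[str, int] = (
        {rid: 0 for rid in network.reaction_ids} if network is not None else {}
    )
    for em in ems:
        for rid in em.support:
            counts[rid] = counts.get(rid, 0) + 1
    return counts
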