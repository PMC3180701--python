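"""Reading and writing metabolic networks.

Two formats are supported:

* a tab/space-delimited flat-file pair (one file of reactions, one of
  metabolites) in the dialect used by AraCyc-derived CellNetAnalyzer
  projects.  Each reaction row is::

      <reaction id> <equation> | <default> <min> <max> <obj> <x> <y> <map> <box>

  with ``#`` in the default slot meaning "unknown".  Equations use ``-->``
  (or ``->``/unicode arrow) for irreversible and ``=``/``<=>``/``<->`` for
  reversible reactions, with terms joined by `` + `` and optional rational
  or decimal coefficients.  Metabolite rows are ``<id> <full name>``.
* SBML, via python-libsbml.  External compounds are recognised from the
  species boundary-condition flag, from an external-looking compartment id,
  or from an explicit id list, because supplementary files in the wild are
  not consistent about the encoding.
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path

import libsbml

from .network import (
    EXTERNAL,
    INTERNAL,
    Compound,
    MetabolicNetwork,
    Reaction,
    ValidationError,
    as_fraction,
)

__all__ = [
    "FlatFileParseError",
    "SBMLError",
    "parse_flatfiles",
    "write_flatfiles",
    "read_sbml",
    "write_sbml",
    "parse_equation",
    "format_equation",
]


class FlatFileParseError(ValueError):
    """A malformed row in the flat-file dialect (reports the line number)."""


class SBMLError(IOError):
    """Unreadable or invalid SBML input."""


_IRREVERSIBLE_ARROWS = ("-->", "->", "→", "=>")
_REVERSIBLE_ARROWS = ("<==>", "<=>", "<->", "↔")
_COEF_RE = re.compile(r"^(\d+(?:\.\d+)?|\d+/\d+)$")


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse a reaction equation into (stoichiometry, reversible).

    Accepts ``A + 2 B --> C`` style equations.  A bare ``=`` separator
    denotes reversibility.  Coefficients may be integers, decimals
    (converted exactly) or ``p/q`` fractions; a missing coefficient is 1.
    """
    text = text.strip()
    reversible = None
    lhs = rhs = None
    for arrow in _REVERSIBLE_ARROWS:
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            reversible = True
            break
    if reversible is None:
        for arrow in _IRREVERSIBLE_ARROWS:
            if arrow in text:
                lhs, rhs = text.split(arrow, 1)
                reversible = False
                break
    if reversible is None and re.search(r"(?<![<>=])=(?![<>=])", text):
        lhs, rhs = re.split(r"(?<![<>=])=(?![<>=])", text, maxsplit=1)
        reversible = True
    if reversible is None:
        raise ValueError(f"no reaction arrow found in equation {text!r}")

    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s+\+\s+", side):
            tokens = term.split()
            if not tokens:
                continue
            if len(tokens) >= 2 and _COEF_RE.match(tokens[0]):
                coef = as_fraction(tokens[0])
                cid = " ".join(tokens[1:])
            else:
                coef = Fraction(1)
                cid = " ".join(tokens)
            stoich[cid] = stoich.get(cid, Fraction(0)) + sign * coef

    add_side(lhs, -1)
    add_side(rhs, +1)
    stoich = {c: v for c, v in stoich.items() if v != 0}
    if not stoich:
        raise ValueError(f"empty equation {text!r}")
    return stoich, reversible


def format_equation(reaction: Reaction) -> str:
    def side(items: list[tuple[str, Fraction]]) -> str:
        parts = []
        for cid, coef in items:
            coef = abs(coef)
            parts.append(cid if coef == 1 else f"{coef} {cid}")
        return " + ".join(parts)

    subs = [(c, v) for c, v in reaction.stoichiometry.items() if v < 0]
    prods = [(c, v) for c, v in reaction.stoichiometry.items() if v > 0]
    arrow = "=" if reaction.reversible else "-->"
    return f"{side(subs)} {arrow} {side(prods)}"


def parse_flatfiles(
    reactions_text: str,
    metabolites_text: str,
    name: str = "",
    external_ids: set[str] | None = None,
    classify_externals: bool = True,
) -> MetabolicNetwork:
    """Build a network from the reactions/metabolites flat-file pair.

    Compound roles default to the preliminary classification (a compound
    appearing only as substrate or only as product across all reactions is
    external) unless ``classify_externals`` is off; ``external_ids`` forces
    additional compounds external.  Well-formed rows after the ``|``
    separator carry ``<default> <min> <max> ...``; the default is None when
    given as ``#``, and min/max are stored as bounds.
    """
    net = MetabolicNetwork(name=name)
    for lineno, raw in enumerate(metabolites_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split(None, 1)
        cid = tokens[0]
        cname = tokens[1].strip() if len(tokens) > 1 else cid
        if cid in net.compounds:
            raise FlatFileParseError(
                f"metabolites line {lineno}: duplicate compound id {cid!r}"
            )
        net.add_compound(Compound(id=cid, name=cname))

    for lineno, raw in enumerate(reactions_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "|" not in line:
            raise FlatFileParseError(
                f"reactions line {lineno}: missing '|' separator"
            )
        head, tail = line.split("|", 1)
        head_tokens = head.strip().split(None, 1)
        if len(head_tokens) < 2:
            raise FlatFileParseError(
                f"reactions line {lineno}: expected '<id> <equation>'"
            )
        rid, equation = head_tokens
        try:
            stoich, reversible = parse_equation(equation)
        except ValueError as exc:
            raise FlatFileParseError(f"reactions line {lineno}: {exc}") from exc
        params = tail.split()
        default = None
        bounds = None
        if params:
            if params[0] != "#":
                default = as_fraction(params[0])
            if len(params) >= 3:
                try:
                    bounds = (as_fraction(params[1]), as_fraction(params[2]))
                except (ValueError, ZeroDivisionError) as exc:
                    raise FlatFileParseError(
                        f"reactions line {lineno}: bad bounds {params[1:3]}"
                    ) from exc
        missing = sorted(set(stoich) - set(net.compounds))
        if missing:
            raise ValidationError(
                f"reactions line {lineno}: reaction {rid} references "
                f"undeclared metabolites: {', '.join(missing)}"
            )
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                bounds=bounds,
                default_rate=default,
            )
        )

    if classify_externals:
        from .extraction import preliminary_classification

        net.set_roles(preliminary_classification(net))
    if external_ids:
        for cid in external_ids:
            if cid in net.compounds:
                net.compounds[cid].role = EXTERNAL
    return net


def write_flatfiles(net: MetabolicNetwork) -> tuple[str, str]:
    """Serialise back to the (reactions_text, metabolites_text) pair."""
    met_lines = [f"{c.id}\t{c.name or c.id}" for c in net.compounds.values()]
    rxn_lines = []
    for r in net.reactions:
        default = "#" if r.default_rate is None else str(r.default_rate)
        lo, hi = r.bounds if r.bounds is not None else ("0", "100")
        rxn_lines.append(
            f"{r.id} {format_equation(r)} | {default} {lo} {hi} 0 0 0 1 1"
        )
    return "\n".join(rxn_lines) + "\n", "\n".join(met_lines) + "\n"


_EXTERNAL_COMPARTMENTS = {"external", "ext", "e", "extracellular", "boundary", "out"}


def read_sbml(
    path: str | Path, external_ids: set[str] | None = None
) -> MetabolicNetwork:
    """Read an SBML file (Level 2 or 3) into a MetabolicNetwork.

    A species is external when its boundaryCondition flag is set, when it
    lives in an external-looking compartment, or when listed in
    ``external_ids``.  Stoichiometries are recovered as exact rationals via
    ``Fraction(value).limit_denominator(10**9)`` so that coefficients
    written from rationals survive the round trip bit-exactly.
    """
    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLError(f"invalid SBML in {path}: {msgs[:3]}")
    model = doc.getModel()
    if model is None:
        raise SBMLError(f"no model element in {path}")

    net = MetabolicNetwork(name=model.getId() or model.getName() or str(path))
    external_ids = external_ids or set()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if not sp.getId():
            raise ValidationError(f"species #{i} in {path} has no id")
        sid = _decode_sbml_id(sp.getId())
        compartment = (sp.getCompartment() or "").lower()
        external = (
            sp.getBoundaryCondition()
            or compartment in _EXTERNAL_COMPARTMENTS
            or sid in external_ids
        )
        net.add_compound(
            Compound(
                id=sid,
                name=sp.getName() or sid,
                role=EXTERNAL if external else INTERNAL,
            )
        )

    def frac(value: float) -> Fraction:
        return Fraction(value).limit_denominator(10**9)

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        stoich: dict[str, Fraction] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            cid = _decode_sbml_id(ref.getSpecies())
            stoich[cid] = stoich.get(cid, Fraction(0)) - frac(
                ref.getStoichiometry()
            )
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            cid = _decode_sbml_id(ref.getSpecies())
            stoich[cid] = stoich.get(cid, Fraction(0)) + frac(
                ref.getStoichiometry()
            )
        stoich = {c: v for c, v in stoich.items() if v != 0}
        net.add_reaction(
            Reaction(
                id=_decode_sbml_id(rxn.getId()),
                stoichiometry=stoich,
                reversible=rxn.getReversible(),
                gene_label=rxn.getName() or None,
            )
        )
    return net


def write_sbml(net: MetabolicNetwork, path: str | Path) -> None:
    """Write SBML Level 3 Version 1 with boundary-condition flags."""
    ns = libsbml.SBMLNamespaces(3, 1)
    doc = libsbml.SBMLDocument(ns)
    model = doc.createModel()
    model.setId(_sbml_id(net.name) or "network")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for cpd in net.compounds.values():
        sp = model.createSpecies()
        sp.setId(_sbml_id(cpd.id))
        sp.setName(cpd.name or cpd.id)
        sp.setCompartment("c")
        sp.setBoundaryCondition(cpd.is_external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
    for rxn in net.reactions:
        sr = model.createReaction()
        sr.setId(_sbml_id(rxn.id))
        if rxn.gene_label:
            sr.setName(rxn.gene_label)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for cid, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sbml_id(cid))
            ref.setStoichiometry(float(abs(coef)))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_ESCAPE_RE = re.compile(r"__(\d+)__")


def _sbml_id(raw: str) -> str:
    """Escape an id into the SBML SId grammar, invertibly.

    AraCyc ids contain dashes and may start with digits
    (``5734-TETRAHYDROXYFLAVONE``), which SIds forbid.  Valid ids pass
    through untouched; otherwise each offending character becomes
    ``__<codepoint>__`` and a digit-leading id gains a ``_n_`` prefix, both
    undone on read.
    """
    if _SID_RE.match(raw):
        return raw
    out = re.sub(r"[^A-Za-z0-9_]", lambda m: f"__{ord(m.group(0))}__", raw)
    if out and out[0].isdigit():
        out = "_n_" + out
    return out


def _decode_sbml_id(sid: str) -> str:
    if sid.startswith("_n_"):
        sid = sid[3:]
    return _ESCAPE_RE.sub(lambda m: chr(int(m.group(1))), sid)
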