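"""Packaged reference tables.

Small plain-text fixtures typed from the published analysis of the
flavonoid subnetwork: the 22x12 cut-set membership matrix with gene
annotations, its printed fragility row, the preliminary flux constraints,
the constant boundary input fluxes, and a (partial) product-class
curation.  They make the fragility, constraint and reporting machinery
fully testable without the supplementary network model.

The supplementary SBML model itself (``AC8_subnet.sbml``) is not packaged;
:func:`find_subnet_sbml` locates it when the user has placed a copy next
to the repository, which unlocks the full-replication checks.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from importlib import resources
from pathlib import Path

from .cutsets import CutSet
from .elementary_modes import ProductClassMap
from .fba import FluxConstraint
from .network import as_fraction

__all__ = [
    "TABLE3_REACTIONS",
    "load_mcs_table",
    "load_mcs_cutsets",
    "load_published_fc",
    "load_preliminary_constraints",
    "load_input_fluxes",
    "load_product_classes",
    "find_subnet_sbml",
]

#: Candidate-reaction columns of the cut-set table, in printed order.
TABLE3_REACTIONS = [
    "N-3-D-RXN",
    "LEUCPEL-RXN",
    "D-4-R-RXN",
    "RXN-525",
    "APIGNAR-RXN",
    "RXN-600",
    "RXN-602",
    "RXN-7652",
    "PELUDP-RXN",
    "RXN1F-775",
    "RXN-7775",
    "N-C-S-RXN",
]

#: The two reactions directly forming the pigment glucosides.
OBJECTIVE_REACTIONS = frozenset({"PELUDP-RXN", "RXN1F-775"})


def _rows(filename: str) -> list[dict[str, str]]:
    text = (
        resources.files("flavnet.data").joinpath(filename).read_text(encoding="utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def load_mcs_table() -> list[dict[str, str]]:
    """Raw rows of the published cut-set membership matrix."""
    return _rows("table3_mcs.tsv")


def load_mcs_cutsets() -> list[CutSet]:
    """The 22 published cut sets with unaffected counts and gene labels."""
    cuts = []
    for row in load_mcs_table():
        members = frozenset(r for r in TABLE3_REACTIONS if row[r] == "1")
        if len(members) != int(row["total"]):
            raise ValueError(f"row {row['mcs']}: membership != printed size")
        cuts.append(
            CutSet(
                reaction_ids=members,
                unaffected_em_count=int(row["unaffected"]),
                gene_labels=[g.strip() for g in row["genes"].split(",")],
            )
        )
    return cuts


def load_published_fc() -> dict[str, float]:
    """The printed per-reaction fragility row (2-decimal values)."""
    return {row["reaction"]: float(row["fc"]) for row in _rows("table3_fc.tsv")}


def load_preliminary_constraints(
    include_ranges: bool = True,
) -> list[FluxConstraint]:
    """Preliminary reference-state constraints (rows with reaction ids)."""
    out = []
    for row in _rows("table1_constraints.tsv"):
        if not row["reaction_id"]:
            continue
        if row["provenance"] == "range" and not include_ranges:
            continue
        out.append(
            FluxConstraint(
                reaction_id=row["reaction_id"],
                min=as_fraction(row["min"]),
                max=as_fraction(row["max"]),
                provenance=row["provenance"],
            )
        )
    return out


def load_constraint_rows() -> list[dict[str, str]]:
    """All constraint rows including those without a printed reaction id."""
    return _rows("table1_constraints.tsv")


def load_input_fluxes() -> dict[str, Fraction]:
    """Constant boundary input fluxes (mmol/kg/h)."""
    return {
        row["reaction_id"]: as_fraction(row["rate"])
        for row in _rows("table2_inputs.tsv")
    }


def load_product_classes() -> ProductClassMap:
    """Partial product-class curation keyed by database compound id."""
    classes: dict[str, set[str]] = {}
    for row in _rows("product_classes.tsv"):
        classes.setdefault(row["class"], set()).add(row["compound_id"])
    priority = [
        "anthocyanins",
        "flavanols",
        "flavanones",
        "flavones",
        "flavonols1",
        "flavonols2",
        "leucoanthocyanidins",
        "proanthocyanidins",
        "lignin",
        "benzenoids",
        "amides",
        "coumarins",
    ]
    return ProductClassMap(
        classes={k: frozenset(v) for k, v in classes.items()},
        priority=[p for p in priority if p in classes],
    )


def find_subnet_sbml() -> Path | None:
    """Locate a user-supplied copy of the supplementary subnetwork SBML.

    Searched (in order): the current directory, the repository root above
    this package, and their ``data/`` subdirectories.  Returns None when
    absent.
    """
    here = Path(__file__).resolve()
    candidates = [Path.cwd(), *here.parents[:4]]
    for base in candidates:
        for rel in ("AC8_subnet.sbml", "data/AC8_subnet.sbml"):
            p = base / rel
            if p.is_file():
                return p
    return None
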