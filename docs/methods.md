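# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `flavnet`.

## Network model

A metabolic network is a hypergraph of compounds (nodes) and reactions
(hyperedges). Internal compounds carry a steady-state mass balance; an
external compound is treated as a buffered reservoir exempt from
balancing. All stoichiometric coefficients are stored as exact
`fractions.Fraction` values. Decimal coefficients in flat files are
converted digit-exactly ("0.15" → 3/20); SBML stoichiometries, which the
format stores as doubles, are recovered with
`Fraction(x).limit_denominator(1e9)`, which inverts the double rounding of
any rational with denominator below 10⁹ and therefore makes the SBML
round trip exact for every coefficient the package itself writes.

Reaction directionality in the flat-file dialect: `-->`/`->` (or the
unicode arrow) is irreversible, `=`/`<=>`/`<->` reversible. External
status on SBML read comes from the species boundary-condition flag, an
external-looking compartment id, or an explicit id list; this triple
sniffing is deliberate because supplementary models in the wild are not
consistent about the encoding.

## Coherent subnetwork extraction

Exhaustive pathway analysis is infeasible at genome scale, so analysis
operates on a subnetwork that is *self-contained* (all boundary nodes are
plausible reservoirs) and *complete* (internal nodes keep every incident
reaction of the full network — the coherence criterion). The extraction
heuristic grows a prototype from seed reactions to a fixed point:
compounds that are internal in the full network but under-connected in
the prototype either get all their full-network reactions pulled in
(traceback, breadth-first, sorted order for determinism), or are
reclassified external when the hub rule fires.

The hub rule makes "C_f ≫ C_s" operational: a compound is reclassified
external when C_f ≥ `hub_ratio`·C_s **and** C_f ≥
`hub_min_connectivity`. Defaults are 3 and 10. The source material for
this procedure gives no numeric threshold, only examples of carrier-type
hub compounds; both knobs are therefore explicit configuration, and the
curated buffered list (carriers, nucleoside phosphates, amino acids,
nutrients) is a plain config input rather than anything auto-derived —
the list is curation, not computation. Termination is not guaranteed in
general; a growth guard aborts when a still-growing subnetwork exceeds a
configurable fraction (default 0.8) of the full network.

## Elementary-mode enumeration

The classical tableau/double-description scheme with exact rational
arithmetic: reversible reactions are split into forward/backward columns,
making the flux cone pointed; internal metabolites are eliminated one at a
time (cheapest first — fewest positive×negative combinations); at each
step new rays are produced by pairwise combination of rays with opposite
residual signs, kept only if no other current ray's support fits inside
the candidate's support (the classical elementarity test). Candidates
containing both directions of a split reaction are rejected during
generation, which excludes the futile two-cycles and everything above
them. Canonical form: coprime integer coefficients; for modes whose
support is entirely reversible, the first nonzero coefficient in network
reaction order is made positive, and the two sign images are deduplicated.

Correctness is cross-checked in the test suite against an independent
brute-force oracle (a support subset carries an elementary mode iff the
balance matrix restricted to it has a 1-dimensional nullspace with a
full-support, sign-feasible generator) on 100 seeded random networks of
up to 12 reactions, a size chosen so the exponential oracle still runs in
about a second while covering reversible splits, cycles and disconnected
cases.

EM classification labels a mode by the product class of its net-produced
external compounds (terminal-product convention: only net production
counts, not intermediates). Futile cycles and producers of unmapped
compounds fall to `others`. A mode producing compounds of several classes
is labelled by a documented priority order (pigment classes first, then
other flavonoid classes, then non-flavonoid groups) with a warning — a
well-curated class map should not trigger it.

## Minimal cut sets and fragility

MCSs for a set of objective reactions are computed as the minimal hitting
sets of the supports of the objective-containing modes, by Berge-style
incremental dualisation (fold in one support at a time, extend the
partial hitting sets that miss it, prune supersets). At the intended
instance sizes (tens of target modes, ≤ 15 candidate reactions) this is
exact and instantaneous. The candidate set is an explicit parameter:
restricting candidates to the pathway's own reactions reproduces the
published 22-row table; leaving it free defaults to the union of target
supports. Reactions sharing an enzyme/gene are cut targets independently;
gene labels are reporting metadata only.

The fragility coefficient fc(r) is the mean of 1/|C| over cut sets C
containing r, kept as an exact rational and rounded to two decimals only
for table-style reporting.

The unaffected-mode count per cut set takes an explicit universe
parameter (default: all modes, or all non-target modes). The published
table's "Unaffected" column implies a 141+24-mode universe that does not
match the 156 flavonoid modes stated elsewhere in the same source; the
package does not force agreement with either convention — the packaged
fixture carries the printed counts verbatim, and freshly computed counts
state their universe.

## Reference state and knockout simulation

Measured fluxes for the subnetwork do not exist, so the reference state
is *representative*, not measured. Constraints:

- product-formation rates from tissue concentrations under the
  proportionality assumption rate ∝ concentration: mg/kg divided by molar
  mass (g/mol) gives mmol/kg, used directly as mmol/kg·h. The unknown
  proportionality constant cancels in all reported ratios (verified by a
  scale-invariance test).
- classes measured only in aggregate (the flavan-3-ols, 40.4 mg/kg) are
  converted with the members' mean molar mass and split equally.
- lignin couples the subnetwork to growth: monomer drain in the ratio
  370 coniferyl : 238 sinapyl : 60 coumaryl alcohol, running at
  biomass_fraction × μ = 0.15 × 0.18 h⁻¹ = 0.027 h⁻¹.
- literature ranges from other species enter as [0, max] bounds.

One packaged constraint row (kaempferol-3-glucoside, 97.7 mg/kg →
1.64E-01) is inconsistent with that compound's molar mass (≈ 448.4 g/mol
would give ≈ 0.218); it matches division by ≈ 595.7 instead. The fixture
carries the printed value verbatim, and the conversion tests exclude this
row.

Feasible states are selected deterministically: phase-1 feasibility, then
L1-minimal total flux (variables split as v ≤ t, −v ≤ t, minimise Σt),
then lexicographic minimisation of each rate in network reaction order
with the L1 optimum held as a cap. All LPs use scipy's HiGHS; tolerance
1e-9, with sub-tolerance rates snapped to zero. Because the original
analysis used an unspecified feasible state from a black-box tool, only
ratio-level and qualitative agreement is expected, never absolute rates —
exact knockout bar heights are not reproducible from the published
description and are not asserted anywhere.

Knockout states force the cut reactions to exactly zero while holding the
boundary input fluxes at reference values (the surrounding metabolism is
assumed undisturbed). A fixed input that is itself in the cut set is
dropped with a warning — the knockout wins. If the system is infeasible,
range-type constraints are relaxed and the state flagged; fixed inputs
are never relaxed, and persistent infeasibility raises an error naming
the cut set. Such infeasibility is a real prediction, not a failure mode:
in the miniature fixture, blocking the isomerase while the synthase input
stays pinned leaves chalcone with no outlet, and the package reports
exactly that.

Ratios are blocked/reference per reaction; ratios with a zero reference
rate are *undefined* (not zero) and excluded from class averages, because
0/0 carries no information about the knockout. Class averages run over
the end reactions of a class — reactions directly producing one of the
class's external compounds inside a mode that net-produces it.

## Synthetic data

The generators produce instances whose answers are known by construction:

- linear chains (one mode) and layered branching networks (mode count =
  product of branch counts; cut sets for the sink = the sink or any full
  layer). Branch layers are kept irreversible so that the product formula
  is exact — reversible parallel branches would add two-reaction cycle
  modes.
- embedded-subnetwork instances: a planted branching subnet whose
  reactions carry hub cofactors, hubs also consumed by many outside
  reactions (degree 12 by default, comfortably above the hub rule's
  default thresholds to emulate carrier-like ubiquity), plus a disjoint
  decoy chain. With the generated config, extraction must recover the
  planted reaction set exactly.
- the miniature pigment pathway (12 reactions) with fully hand-enumerated
  modes and cut sets, documented in its docstring.
- small random sparse networks (1–2 substrates/products, coefficients 1–2,
  configurable reversible fraction) for oracle cross-checks.

All generators are deterministic given their seed. What the synthetic
networks do **not** emulate: realistic kinetics, genome-scale degree
distributions, compartmentation, and cofactor stoichiometry beyond the
hub construction — so passing tests demonstrate algorithmic correctness
on known topologies, not biological fidelity of any particular model.

## Packaged fixtures and replication scope

The published 22×12 cut-set membership matrix (with sizes, unaffected
counts and gene labels), the printed fragility row, the preliminary
constraint table, the constant input-flux table and a partial
product-class curation ship as plain-text fixtures. They make the
fragility, constraint and reporting machinery fully testable offline. The
supplementary subnetwork SBML model itself is not redistributable here;
when a copy of `AC8_subnet.sbml` is placed beside the repository, the
full replication tests (180 compounds / 164 reactions, 359 modes, 24
pigment modes, trunk participation 156, recovery of the 22 cut sets, and
qualitative knockout patterns) activate automatically.

## Known limitations

- EM enumeration is exponential in the worst case; the implementation
  targets extracted subnetworks (hundreds of reactions with few modes),
  not genome-scale models.
- Exact replication of the published 180/164 extraction from the full
  database is impossible without the original curated buffered list,
  which was never printed in full.
- The lexicographic refinement solves one LP per reaction; for very large
  networks a cheaper deterministic rule would be preferable.
- The packaged product-class map covers only compounds whose database ids
  appear in the printed tables; users replicating against the full model
  should extend it.
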