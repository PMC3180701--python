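"""Generators for networks with known pathway-analysis answers.

Every generator returns, besides the network, a :class:`PlantedAnswer`
describing ground truth (elementary-mode count, target supports, minimal
cut sets, planted subnetwork) constructed *by design* of the topology, so
enumeration code can be checked against it without any reference data.

The mini two-branch pigment fixture mirrors, at toy scale, the structure of
the anthocyanin branch of flavonoid metabolism: a shared early trunk
(chalcone synthase / chalcone isomerase / flavanone 3-hydroxylase
analogues), one route to the pelargonidin-type pigment, two parallel
hydroxylation routes feeding the cyanidin-type pigment, a flavonol side
branch, and two independent non-pigment branches (a flavanone and a
benzenoid) that knockouts should leave untouched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

from .cutsets import ObjectiveSpec
from .elementary_modes import ProductClassMap
from .extraction import ExtractionConfig
from .network import Compound, EXTERNAL, INTERNAL, MetabolicNetwork, Reaction

__all__ = [
    "GeneratorSpec",
    "PlantedAnswer",
    "gen_linear_chain",
    "gen_branching",
    "gen_random_network",
    "gen_full_with_embedded_subnet",
    "make_mini_abp_fixture",
]


@dataclass
class GeneratorSpec:
    seed: int = 0
    layers: list[int] = field(default_factory=lambda: [2, 3])
    n_hub_compounds: int = 2
    hub_degree: int = 12
    reversible_fraction: float = 0.0
    decoy_component_size: int = 3

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.layers):
            raise ValueError("branch counts must be >= 1")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be a probability")


@dataclass
class PlantedAnswer:
    em_count: int
    planted_subnet_reaction_ids: frozenset[str] = frozenset()
    planted_mcs: list[frozenset[str]] = field(default_factory=list)
    target_em_supports: list[frozenset[str]] = field(default_factory=list)
    objective: ObjectiveSpec | None = None
    em_supports: list[frozenset[str]] = field(default_factory=list)
    class_counts: dict[str, int] = field(default_factory=dict)


def _ext(cid: str, name: str = "") -> Compound:
    return Compound(id=cid, name=name or cid, role=EXTERNAL)


def _int(cid: str, name: str = "") -> Compound:
    return Compound(id=cid, name=name or cid, role=INTERNAL)


def gen_linear_chain(k: int, seed: int = 0) -> tuple[MetabolicNetwork, PlantedAnswer]:
    """Irreversible chain EXT -> X1 -> ... -> X(k-1) -> EXT; exactly one EM."""
    if k < 1:
        raise ValueError("chain length must be >= 1")
    net = MetabolicNetwork(name=f"chain-{k}")
    net.add_compound(_ext("X0"))
    for i in range(1, k):
        net.add_compound(_int(f"X{i}"))
    net.add_compound(_ext(f"X{k}"))
    for i in range(1, k + 1):
        net.add_reaction(
            Reaction(id=f"R{i}", stoichiometry={f"X{i-1}": -1, f"X{i}": 1})
        )
    answer = PlantedAnswer(
        em_count=1,
        em_supports=[frozenset(net.reaction_ids)],
        planted_subnet_reaction_ids=frozenset(net.reaction_ids),
    )
    return net, answer


def gen_branching(spec: GeneratorSpec) -> tuple[MetabolicNetwork, PlantedAnswer]:
    """Layered parallel-route network: EM count is the product of branch
    counts, mirroring how parallel hydroxylation routes multiply the number
    of pigment-forming modes.

    Layer i offers ``layers[i]`` parallel single reactions from node L(i-1)
    to node L(i); a single sink reaction drains the last node.  For the
    sink objective the minimal cut sets are the sink itself and each full
    layer.
    """
    layers = spec.layers
    net = MetabolicNetwork(name="branching-" + "x".join(map(str, layers)))
    net.add_compound(_ext("L0"))
    for i in range(1, len(layers) + 1):
        net.add_compound(_int(f"L{i}"))
    net.add_compound(_ext("SNK"))
    layer_ids: list[list[str]] = []
    for i, b in enumerate(layers, start=1):
        ids = []
        for j in range(b):
            rid = f"B{i}_{j}"
            net.add_reaction(
                Reaction(id=rid, stoichiometry={f"L{i-1}": -1, f"L{i}": 1})
            )
            ids.append(rid)
        layer_ids.append(ids)
    net.add_reaction(
        Reaction(id="SINK", stoichiometry={f"L{len(layers)}": -1, "SNK": 1})
    )

    em_count = 1
    for b in layers:
        em_count *= b
    supports = [frozenset()]
    for ids in layer_ids:
        supports = [s | {rid} for s in supports for rid in ids]
    supports = [s | {"SINK"} for s in supports]
    mcs = [frozenset({"SINK"})] + [frozenset(ids) for ids in layer_ids]
    answer = PlantedAnswer(
        em_count=em_count,
        em_supports=supports,
        target_em_supports=supports,
        planted_mcs=sorted(mcs, key=lambda s: (len(s), tuple(sorted(s)))),
        objective=ObjectiveSpec(objective_reaction_ids=frozenset({"SINK"})),
        planted_subnet_reaction_ids=frozenset(net.reaction_ids),
    )
    return net, answer


def gen_random_network(
    n_reactions: int,
    seed: int,
    reversible_fraction: float = 0.3,
    external_fraction: float = 0.4,
) -> MetabolicNetwork:
    """Small random sparse network for oracle cross-checks.

    No planted answer: intended for property tests where an independent
    brute-force enumeration provides the expected result.
    """
    rng = random.Random(seed)
    n_compounds = max(3, n_reactions + rng.randint(-2, 2))
    net = MetabolicNetwork(name=f"random-{n_reactions}-{seed}")
    cids = [f"C{i}" for i in range(n_compounds)]
    n_external = max(2, int(external_fraction * n_compounds))
    external = set(rng.sample(cids, n_external))
    for cid in cids:
        net.add_compound(
            Compound(id=cid, role=EXTERNAL if cid in external else INTERNAL)
        )
    for i in range(n_reactions):
        n_sub = min(rng.choice([1, 1, 2]), n_compounds - 1)
        subs = rng.sample(cids, n_sub)
        rest = [c for c in cids if c not in subs]
        n_prod = min(rng.choice([1, 1, 2]), len(rest))
        prods = rng.sample(rest, n_prod)
        stoich: dict[str, Fraction] = {}
        for c in subs:
            stoich[c] = Fraction(-rng.choice([1, 1, 2]))
        for c in prods:
            stoich[c] = Fraction(rng.choice([1, 1, 2]))
        net.add_reaction(
            Reaction(
                id=f"R{i}",
                stoichiometry=stoich,
                reversible=rng.random() < reversible_fraction,
            )
        )
    # compounds the sampler never used are boundary by convention
    for cid in cids:
        if not net.reactions_of(cid):
            net.compounds[cid].role = EXTERNAL
    return net


def gen_full_with_embedded_subnet(
    spec: GeneratorSpec,
) -> tuple[MetabolicNetwork, MetabolicNetwork, ExtractionConfig]:
    """Full network = planted branching subnet + buffered hubs + decoy.

    Hub compounds emulate ubiquitous carriers: each is attached as a
    cofactor to one planted reaction and to ``hub_degree`` reactions
    outside the subnet, so the hub's full-network connectivity dwarfs its
    subnetwork connectivity.  A disjoint decoy chain must never be pulled
    in.  With the returned config (buffered list = hubs, seed = the sink
    reaction) extraction recovers the planted reaction set exactly.
    """
    rng = random.Random(spec.seed)
    planted, _ = gen_branching(spec)
    full = MetabolicNetwork(name="full-embedded")
    for cpd in planted.compounds.values():
        full.add_compound(Compound(id=cpd.id, name=cpd.name, role=cpd.role))

    hub_ids = [f"HUB{i}" for i in range(spec.n_hub_compounds)]
    for hid in hub_ids:
        full.add_compound(_int(hid))
    planted_rxns = []
    attachable = [r for r in planted.reactions if r.id != "SINK"]
    for r in planted.reactions:
        stoich = dict(r.stoichiometry)
        planted_rxns.append((r.id, stoich, r.reversible))
    # attach each hub as cofactor of one random planted reaction
    for hid in hub_ids:
        rid, stoich, _ = planted_rxns[rng.randrange(len(planted_rxns))]
        stoich[hid] = stoich.get(hid, Fraction(0)) + Fraction(-1)
    for rid, stoich, rev in planted_rxns:
        full.add_reaction(Reaction(id=rid, stoichiometry=stoich, reversible=rev))

    # hub-consuming reactions outside the subnet
    counter = 0
    for hid in hub_ids:
        for j in range(spec.hub_degree):
            partner = f"OUT{counter}"
            counter += 1
            full.add_compound(_ext(partner))
            full.add_reaction(
                Reaction(
                    id=f"HR_{hid}_{j}",
                    stoichiometry={hid: Fraction(-1), partner: Fraction(1)},
                )
            )
    # hubs need a producer too, or preliminary classification calls them external
    for hid in hub_ids:
        src = f"HSRC_{hid}"
        full.add_compound(_ext(src))
        full.add_reaction(
            Reaction(
                id=f"HP_{hid}",
                stoichiometry={src: Fraction(-1), hid: Fraction(1)},
            )
        )

    # disjoint decoy chain
    if spec.decoy_component_size > 0:
        decoy, _ = gen_linear_chain(spec.decoy_component_size)
        for cpd in decoy.compounds.values():
            full.add_compound(Compound(id=f"D_{cpd.id}", role=cpd.role))
        for r in decoy.reactions:
            full.add_reaction(
                Reaction(
                    id=f"D_{r.id}",
                    stoichiometry={f"D_{c}": v for c, v in r.stoichiometry.items()},
                )
            )

    planted_net = full.subnetwork(
        [rid for rid, _, _ in planted_rxns], name="planted"
    )
    for cid, cpd in planted_net.compounds.items():
        cpd.role = EXTERNAL if (cid in hub_ids or cid in ("L0", "SNK")) else INTERNAL
    config = ExtractionConfig(
        buffered_list=frozenset(hub_ids),
        seed_reaction_ids=frozenset({"SINK"}),
    )
    return full, planted_net, config


def make_mini_abp_fixture() -> tuple[
    MetabolicNetwork, PlantedAnswer, ProductClassMap
]:
    """Hand-enumerated miniature of the pigment pathway.

    Topology (all irreversible)::

        SUB-PHE -CHS-> CHALCONE -CHI-> NARINGENIN -F3H-> DHK
        DHK -F3PH-A-> DHQ        (parallel hydroxylation route 1)
        DHK -F3PH-B-> DHQ        (parallel hydroxylation route 2)
        DHK -DFR-PG-> PELARGONIDIN -UGT-PG-> PG-3-GLUCOSIDE   (objective)
        DHQ -DFR-CY-> CYANIDIN   -UGT-CY-> CY-3-GLUCOSIDE     (objective)
        DHK -FLS-> KAEMPFEROL    (flavonol side branch)
        SUB-LIQ -LIQ-> LIQUIRITIGENIN   (independent flavanone branch)
        SUB-BENZ -BENZ-> BENZALDEHYDE   (independent benzenoid branch)

    Hand enumeration gives 6 elementary modes (1 pelargonidin, 2 cyanidin,
    1 flavonol, 1 flavanone, 1 benzenoid) and, for the two glucosylation
    objectives, 9 minimal cut sets: the early singletons {CHS}, {CHI},
    {F3H}, the four late pairs pairing a pelargonidin-branch with a
    cyanidin-branch reaction, and two triples that must block both
    hydroxylation routes plus the pelargonidin branch.  Blocking the
    pelargonidin branch alone is NOT a cut: the cyanidin routes remain.
    """
    net = MetabolicNetwork(name="mini-abp")
    for cid in ("SUB-PHE", "SUB-LIQ", "SUB-BENZ"):
        net.add_compound(_ext(cid))
    for cid in ("CHALCONE", "NARINGENIN", "DHK", "DHQ", "PELARGONIDIN", "CYANIDIN"):
        net.add_compound(_int(cid))
    for cid in (
        "PG-3-GLUCOSIDE",
        "CY-3-GLUCOSIDE",
        "KAEMPFEROL",
        "LIQUIRITIGENIN",
        "BENZALDEHYDE",
    ):
        net.add_compound(_ext(cid))

    steps = [
        ("CHS", "SUB-PHE", "CHALCONE", "CHS"),
        ("CHI", "CHALCONE", "NARINGENIN", "CHI"),
        ("F3H", "NARINGENIN", "DHK", "F3H"),
        ("F3PH-A", "DHK", "DHQ", "F3'H(i)"),
        ("F3PH-B", "DHK", "DHQ", "F3'H(ii)"),
        ("DFR-PG", "DHK", "PELARGONIDIN", "DFR(pg)"),
        ("DFR-CY", "DHQ", "CYANIDIN", "DFR(cy)"),
        ("UGT-PG", "PELARGONIDIN", "PG-3-GLUCOSIDE", "3-UGT(pg)"),
        ("UGT-CY", "CYANIDIN", "CY-3-GLUCOSIDE", "3-UGT(cy)"),
        ("FLS", "DHK", "KAEMPFEROL", "FLS"),
        ("LIQ", "SUB-LIQ", "LIQUIRITIGENIN", "CHS/CHR"),
        ("BENZ", "SUB-BENZ", "BENZALDEHYDE", "BA2H"),
    ]
    for rid, sub, prod, gene in steps:
        net.add_reaction(
            Reaction(
                id=rid, stoichiometry={sub: -1, prod: 1}, gene_label=gene
            )
        )

    trunk = {"CHS", "CHI", "F3H"}
    em_supports = [
        frozenset(trunk | {"DFR-PG", "UGT-PG"}),
        frozenset(trunk | {"F3PH-A", "DFR-CY", "UGT-CY"}),
        frozenset(trunk | {"F3PH-B", "DFR-CY", "UGT-CY"}),
        frozenset(trunk | {"FLS"}),
        frozenset({"LIQ"}),
        frozenset({"BENZ"}),
    ]
    planted_mcs = [
        frozenset({"CHS"}),
        frozenset({"CHI"}),
        frozenset({"F3H"}),
        frozenset({"DFR-PG", "DFR-CY"}),
        frozenset({"DFR-PG", "UGT-CY"}),
        frozenset({"UGT-PG", "DFR-CY"}),
        frozenset({"UGT-PG", "UGT-CY"}),
        frozenset({"F3PH-A", "F3PH-B", "DFR-PG"}),
        frozenset({"F3PH-A", "F3PH-B", "UGT-PG"}),
    ]
    objective = ObjectiveSpec(
        objective_reaction_ids=frozenset({"UGT-PG", "UGT-CY"})
    )
    answer = PlantedAnswer(
        em_count=6,
        em_supports=em_supports,
        target_em_supports=em_supports[:3],
        planted_mcs=sorted(planted_mcs, key=lambda s: (len(s), tuple(sorted(s)))),
        objective=objective,
        planted_subnet_reaction_ids=frozenset(net.reaction_ids),
        class_counts={
            "anthocyanins": 3,
            "flavonols": 1,
            "flavanones": 1,
            "benzenoids": 1,
        },
    )
    class_map = ProductClassMap(
        classes={
            "anthocyanins": frozenset({"PG-3-GLUCOSIDE", "CY-3-GLUCOSIDE"}),
            "flavonols": frozenset({"KAEMPFEROL"}),
            "flavanones": frozenset({"LIQUIRITIGENIN"}),
            "benzenoids": frozenset({"BENZALDEHYDE"}),
        },
        priority=["anthocyanins", "flavonols", "flavanones", "benzenoids"],
    )
    return net, answer, class_map
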