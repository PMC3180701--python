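import random
from collections import Counter
from fractions import Fraction

import pytest

from flavnet.elementary_modes import (
    OTHERS,
    ProductClassMap,
    classify_ems,
    enumerate_ems,
    participation,
)
from flavnet.network import Compound, MetabolicNetwork, Reaction
from flavnet.synthetic import (
    GeneratorSpec,
    gen_branching,
    gen_linear_chain,
    gen_random_network,
)
from .oracles import brute_force_ems


def canonical_set(ems):
    return {em.coefficients for em in ems}


class TestEnumeration:
    def test_chain_has_single_mode(self):
        net, answer = gen_linear_chain(3)
        ems = enumerate_ems(net)
        assert len(ems) == 1
        assert ems[0].support == frozenset({"R1", "R2", "R3"})

    def test_diamond_has_two_modes(self, diamond):
        ems = enumerate_ems(diamond)
        assert len(ems) == 2
        assert {frozenset({"r1", "r2", "r4"}), frozenset({"r1", "r3", "r4"})} == {
            em.support for em in ems
        }

    def test_empty_network(self):
        assert enumerate_ems(MetabolicNetwork()) == []

    def test_no_internal_compounds_gives_single_reaction_modes(self):
        net = MetabolicNetwork()
        net.add_compound(Compound("A", role="external"))
        net.add_compound(Compound("B", role="external"))
        net.add_reaction(Reaction("r1", {"A": -1, "B": 1}))
        net.add_reaction(Reaction("r2", {"A": -1, "B": 1}, reversible=True))
        ems = enumerate_ems(net)
        assert sorted((em.support for em in ems), key=sorted) == [
            frozenset({"r1"}),
            frozenset({"r2"}),
        ]

    def test_reversible_split_produces_no_futile_two_cycle(self):
        net = MetabolicNetwork()
        net.add_compound(Compound("A", role="external"))
        net.add_compound(Compound("B"))
        net.add_compound(Compound("C", role="external"))
        net.add_reaction(Reaction("r1", {"A": -1, "B": 1}, reversible=True))
        net.add_reaction(Reaction("r2", {"B": -1, "C": 1}, reversible=True))
        ems = enumerate_ems(net)
        assert len(ems) == 1
        assert ems[0].support == frozenset({"r1", "r2"})

    def test_steady_state_residual_exactly_zero(self, mini_abp):
        net, _, _ = mini_abp
        rows, S = net.stoichiometric_matrix()
        for em in enumerate_ems(net):
            v = em.coefficients_dict
            for row, cid in zip(S, rows):
                residual = sum(
                    coef * v.get(r.id, Fraction(0))
                    for coef, r in zip(row, net.reactions)
                )
                assert residual == 0, cid

    def test_mini_abp_matches_hand_enumeration(self, mini_abp):
        net, answer, _ = mini_abp
        ems = enumerate_ems(net)
        assert len(ems) == answer.em_count
        assert {em.support for em in ems} == set(answer.em_supports)

    def test_branching_count_is_product_of_layers(self):
        for layers in ([2], [2, 3], [1, 1, 1], [3, 2, 2]):
            net, answer = gen_branching(GeneratorSpec(layers=list(layers)))
            assert len(enumerate_ems(net)) == answer.em_count

    def test_supports_form_antichain(self):
        for seed in range(10):
            ems = enumerate_ems(gen_random_network(9, seed))
            sups = [em.support for em in ems]
            for i, a in enumerate(sups):
                for b in sups[i + 1 :]:
                    assert not (a < b or b < a)

    def test_matches_brute_force_oracle_on_random_networks(self):
        rng = random.Random(2024)
        for _ in range(40):
            seed = rng.randrange(100_000)
            n = rng.randint(4, 10)
            net = gen_random_network(n, seed)
            assert canonical_set(enumerate_ems(net)) == brute_force_ems(net), (
                seed,
                n,
            )

    def test_irreversible_coefficients_nonnegative(self):
        for seed in range(10):
            net = gen_random_network(8, seed, reversible_fraction=0.5)
            for em in enumerate_ems(net):
                for r in net.reactions:
                    if not r.reversible:
                        assert em.coefficient(r.id) >= 0


class TestClassification:
    def test_mini_abp_class_counts(self, mini_abp):
        net, answer, class_map = mini_abp
        labeled = classify_ems(enumerate_ems(net), class_map)
        counts = Counter(em.class_label for em in labeled)
        assert counts == Counter(answer.class_counts)

    def test_futile_cycle_labelled_others(self):
        net = MetabolicNetwork()
        net.add_compound(Compound("A"))
        net.add_compound(Compound("B"))
        net.add_reaction(Reaction("f", {"A": -1, "B": 1}))
        net.add_reaction(Reaction("b", {"B": -1, "A": 1}))
        ems = enumerate_ems(net)
        assert len(ems) == 1  # the two-reaction cycle
        labeled = classify_ems(ems, ProductClassMap(classes={}))
        assert labeled[0].class_label == OTHERS

    def test_unmapped_product_falls_to_others(self, chain3):
        ems = enumerate_ems(chain3)
        labeled = classify_ems(ems, ProductClassMap(classes={"x": frozenset({"Z"})}))
        assert labeled[0].class_label == OTHERS

    def test_mixed_class_resolved_by_priority_with_warning(self):
        net = MetabolicNetwork()
        net.add_compound(Compound("S", role="external"))
        net.add_compound(Compound("M"))
        net.add_compound(Compound("P1", role="external"))
        net.add_compound(Compound("P2", role="external"))
        net.add_reaction(Reaction("up", {"S": -1, "M": 1}))
        net.add_reaction(Reaction("down", {"M": -1, "P1": 1, "P2": 1}))
        class_map = ProductClassMap(
            classes={
                "anthocyanins": frozenset({"P1"}),
                "flavones": frozenset({"P2"}),
            },
            priority=["anthocyanins", "flavones"],
        )
        with pytest.warns(UserWarning, match="several"):
            labeled = classify_ems(enumerate_ems(net), class_map)
        assert labeled[0].class_label == "anthocyanins"

    def test_compound_in_two_classes_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            ProductClassMap(
                classes={"a": frozenset({"X"}), "b": frozenset({"X"})}
            )


class TestParticipation:
    def test_chain_every_reaction_once(self):
        net, _ = gen_linear_chain(4)
        counts = participation(enumerate_ems(net), net)
        assert counts == {rid: 1 for rid in net.reaction_ids}

    def test_reaction_in_no_mode_counts_zero(self, mini_abp):
        net, _, _ = mini_abp
        # orphan the benzenoid branch by removing its mode's other reaction
        counts = participation(
            [em for em in enumerate_ems(net) if "BENZ" not in em.support], net
        )
        assert counts["BENZ"] == 0

    def test_totals_identity(self):
        for seed in range(10):
            net = gen_random_network(9, seed)
            ems = enumerate_ems(net)
            counts = participation(ems, net)
            assert sum(counts.values()) == sum(len(em.support) for em in ems)

    def test_mini_abp_trunk_carries_all_flavonoid_modes(self, mini_abp):
        net, answer, _ = mini_abp
        counts = participation(enumerate_ems(net), net)
        # trunk (CHS/CHI analogues) sits in every flavonoid-producing mode
        assert counts["CHS"] == counts["CHI"] == 4
        # the two glucosylation objectives jointly cover the 3 pigment modes
        assert counts["UGT-PG"] + counts["UGT-CY"] == 3
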