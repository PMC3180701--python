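import warnings
from fractions import Fraction

import pytest

from flavnet.cutsets import CutSet, enumerate_mcs, select_target_ems
from flavnet.elementary_modes import classify_ems, enumerate_ems
from flavnet.fba import (
    FluxConstraint,
    InfeasibleError,
    LigninSpec,
    convert_concentration,
    fixed_inputs_from_reference,
    lignin_growth_flux,
    lignin_pseudo_reaction,
    max_flux,
    parse_constraint_file,
    ratio_report,
    simulate_cut_state,
    solve_reference_state,
    split_class_total,
)
from flavnet.network import Compound, MetabolicNetwork, Reaction


MINI_CONSTRAINTS = [
    FluxConstraint.fixed("UGT-CY", "6.43e-2"),
    FluxConstraint.fixed("UGT-PG", "3.0e-2"),
    FluxConstraint.fixed("FLS", "8.03e-2"),
    FluxConstraint.fixed("LIQ", "1.0e-2"),
    FluxConstraint.fixed("BENZ", "2.0e-2"),
]
MINI_INPUTS = ["CHS", "LIQ", "BENZ"]


@pytest.fixture(scope="module")
def mini_reference(mini_abp):
    net, _, _ = mini_abp
    return solve_reference_state(net, MINI_CONSTRAINTS)


class TestConversions:
    @pytest.mark.parametrize(
        "mg,mass,expected",
        [
            ("28.9", "449.4", 0.0643),  # cyanidin 3-glucoside
            ("37.3", "464.4", 0.0803),  # quercetin-3-glucoside
            ("1.4", "595.5", 0.00235),  # cyanidin 3-p-coumaroylglucoside
        ],
    )
    def test_concentration_to_rate(self, mg, mass, expected):
        rate = float(convert_concentration(mg, mass))
        assert rate == pytest.approx(expected, abs=0.5 * 10 ** -len(str(expected).split(".")[1]))

    def test_zero_concentration(self):
        assert convert_concentration(0, 123.4) == 0

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            convert_concentration(1, 0)

    def test_class_total_split_equally(self):
        # flavan-3-ol class: 40.4 mg/kg over four compounds, mean molar mass
        rates = split_class_total("40.4", ["274.27", "290.27", "274.27", "290.27"])
        assert len(rates) == 4
        assert len(set(rates)) == 1
        assert float(rates[0]) == pytest.approx(0.0358, abs=5e-5)


class TestLignin:
    def test_growth_contribution(self):
        assert lignin_growth_flux(LigninSpec()) == Fraction(27, 1000)

    def test_zero_fraction(self):
        assert lignin_growth_flux(LigninSpec(biomass_fraction=0)) == 0

    def test_mu_passthrough_at_unit_fraction(self):
        spec = LigninSpec(biomass_fraction="0.999999", growth_rate_mu="0.3")
        assert lignin_growth_flux(spec) == Fraction(999999, 1000000) * Fraction(3, 10)

    def test_pseudo_reaction_monomer_ratio(self):
        rxn = lignin_pseudo_reaction(LigninSpec())
        s = rxn.stoichiometry
        assert s["CONIFERYL-ALCOHOL"] / s["SINAPYL-ALCOHOL"] == Fraction(370, 238)
        assert s["COUMARYL-ALCOHOL"] == Fraction(-60)
        assert all(v < 0 for v in s.values())


class TestReferenceState:
    def test_mini_abp_feasible_and_balanced(self, mini_abp, mini_reference):
        net, _, _ = mini_abp
        assert mini_reference.residual_norm < 1e-6
        # trunk carries the sum of its committed end products
        assert mini_reference.rates["CHS"] == pytest.approx(
            0.0643 + 0.03 + 0.0803, abs=1e-6
        )

    def test_contradictory_bounds_raise(self, chain3):
        bad = [FluxConstraint("r1", 2, 2), FluxConstraint("r2", 1, 1)]
        with pytest.raises(InfeasibleError):
            solve_reference_state(chain3, bad)

    def test_unconstrained_network_rests_at_zero(self, chain3):
        state = solve_reference_state(chain3, [])
        assert all(v == 0 for v in state.rates.values())

    def test_deterministic_repeat(self, mini_abp, mini_reference):
        net, _, _ = mini_abp
        again = solve_reference_state(net, MINI_CONSTRAINTS)
        assert again.rates == mini_reference.rates

    def test_unknown_constraint_reaction_raises(self, chain3):
        with pytest.raises(KeyError):
            solve_reference_state(chain3, [FluxConstraint("ghost", 0, 1)])


class TestCutStates:
    def test_empty_cut_reproduces_reference(self, mini_abp, mini_reference):
        net, _, _ = mini_abp
        fixed = fixed_inputs_from_reference(mini_reference, MINI_INPUTS)
        state = simulate_cut_state(
            net, mini_reference, CutSet(frozenset()), fixed, MINI_CONSTRAINTS
        )
        for rid, v in mini_reference.rates.items():
            assert state.rates[rid] == pytest.approx(v, abs=1e-6)

    def test_objective_pair_cut_zeroes_pigments_reroutes_to_flavonols(
        self, mini_abp, mini_reference
    ):
        net, answer, class_map = mini_abp
        fixed = fixed_inputs_from_reference(mini_reference, MINI_INPUTS)
        cut = CutSet(frozenset({"UGT-PG", "UGT-CY"}))
        state = simulate_cut_state(net, mini_reference, cut, fixed, [])
        assert state.rates["UGT-PG"] == 0 and state.rates["UGT-CY"] == 0
        ems = classify_ems(enumerate_ems(net), class_map)
        report = ratio_report(state, mini_reference, class_map, ems, net)
        assert report.per_class_average["anthocyanins"] == pytest.approx(0, abs=1e-6)
        assert report.per_class_average["flavonols"] >= 1
        assert report.per_class_average["benzenoids"] == pytest.approx(1, abs=1e-6)

    def test_early_cut_spares_independent_branches(self, mini_abp, mini_reference):
        net, _, class_map = mini_abp
        fixed = fixed_inputs_from_reference(mini_reference, MINI_INPUTS)
        cut = CutSet(frozenset({"CHS"}))
        with pytest.warns(UserWarning, match="inside the cut set"):
            state = simulate_cut_state(net, mini_reference, cut, fixed, [])
        ems = classify_ems(enumerate_ems(net), class_map)
        report = ratio_report(state, mini_reference, class_map, ems, net)
        assert report.per_class_average["anthocyanins"] == pytest.approx(0, abs=1e-6)
        assert report.per_class_average["flavonols"] == pytest.approx(0, abs=1e-6)
        # the chalcone-independent flavanone and benzenoid branches survive
        assert report.per_class_average["flavanones"] == pytest.approx(1, abs=1e-6)
        assert report.per_class_average["benzenoids"] == pytest.approx(1, abs=1e-6)

    def test_midtrunk_cut_with_pinned_upstream_input_is_infeasible(
        self, mini_abp, mini_reference
    ):
        # blocking the isomerase while the synthase input stays pinned
        # leaves chalcone with no outlet: correctly reported, not fudged
        net, _, _ = mini_abp
        fixed = fixed_inputs_from_reference(mini_reference, MINI_INPUTS)
        with pytest.raises(InfeasibleError, match="CHI"):
            simulate_cut_state(net, mini_reference, CutSet(frozenset({"CHI"})), fixed, [])

    def test_range_constraints_relaxed_when_conflicting(self, mini_abp, mini_reference):
        # cutting every outlet of the trunk forces zero trunk flux, which
        # conflicts with a minimum-uptake range: the range must yield
        net, _, _ = mini_abp
        conflicting = [FluxConstraint("CHS", "1.0e-2", "1", provenance="range")]
        cut = CutSet(frozenset({"UGT-PG", "UGT-CY", "FLS"}))
        state = simulate_cut_state(net, mini_reference, cut, [], conflicting)
        assert state.relaxed
        assert state.rates["CHS"] == 0
        assert state.rates["FLS"] == 0

    def test_every_mcs_blocks_all_objective_flux(self, mini_abp, mini_reference):
        net, answer, _ = mini_abp
        ems = enumerate_ems(net)
        targets = select_target_ems(ems, answer.objective, net)
        for cut in enumerate_mcs(targets, network=net):
            cut_constraints = [
                FluxConstraint.fixed(rid, 0) for rid in cut.reaction_ids
            ]
            for obj in answer.objective.objective_reaction_ids:
                assert max_flux(net, obj, cut_constraints) == pytest.approx(
                    0, abs=1e-9
                )


class TestRatioReport:
    def test_identity_when_blocked_equals_reference(self, mini_abp, mini_reference):
        net, _, class_map = mini_abp
        ems = classify_ems(enumerate_ems(net), class_map)
        report = ratio_report(mini_reference, mini_reference, class_map, ems, net)
        for v in report.per_class_average.values():
            assert v == pytest.approx(1.0)

    def test_zero_reference_rates_are_undefined_not_zero(self, mini_abp):
        net, _, class_map = mini_abp
        zero_constraints = [FluxConstraint.fixed(r, 0) for r in MINI_INPUTS]
        zero_ref = solve_reference_state(net, zero_constraints)
        ems = classify_ems(enumerate_ems(net), class_map)
        report = ratio_report(zero_ref, zero_ref, class_map, ems, net)
        assert report.per_reaction_ratio["CHS"] is None
        assert report.per_class_average["anthocyanins"] is None

    def test_scale_invariance_of_ratios(self, mini_abp):
        net, answer, class_map = mini_abp
        ems = classify_ems(enumerate_ems(net), class_map)
        cut = CutSet(frozenset({"UGT-PG", "UGT-CY"}))
        reports = []
        for scale in (1, 10):
            constraints = [
                FluxConstraint.fixed(fc.reaction_id, fc.min * scale)
                for fc in MINI_CONSTRAINTS
            ]
            ref = solve_reference_state(net, constraints)
            fixed = fixed_inputs_from_reference(ref, MINI_INPUTS)
            state = simulate_cut_state(net, ref, cut, fixed, [])
            reports.append(ratio_report(state, ref, class_map, ems, net))
        for cls in class_map.classes:
            a = reports[0].per_class_average[cls]
            b = reports[1].per_class_average[cls]
            assert a == pytest.approx(b, abs=1e-6)

    def test_hand_solved_four_reaction_network(self):
        # SRC -r1-> M, M -r2-> P1(ext), M -r3-> P2(ext); pin r2=2, r3=1;
        # cut r3: with r1 pinned at 3, all flux must exit via r2 -> ratio 3/2
        net = MetabolicNetwork()
        net.add_compound(Compound("SRC", role="external"))
        net.add_compound(Compound("M"))
        net.add_compound(Compound("P1", role="external"))
        net.add_compound(Compound("P2", role="external"))
        net.add_reaction(Reaction("r1", {"SRC": -1, "M": 1}))
        net.add_reaction(Reaction("r2", {"M": -1, "P1": 1}))
        net.add_reaction(Reaction("r3", {"M": -1, "P2": 1}))
        constraints = [FluxConstraint.fixed("r2", 2), FluxConstraint.fixed("r3", 1)]
        ref = solve_reference_state(net, constraints)
        assert ref.rates["r1"] == pytest.approx(3)
        fixed = fixed_inputs_from_reference(ref, ["r1"])
        state = simulate_cut_state(net, ref, CutSet(frozenset({"r3"})), fixed, [])
        ems = enumerate_ems(net)
        from flavnet.elementary_modes import ProductClassMap

        cmap = ProductClassMap(
            classes={"one": frozenset({"P1"}), "two": frozenset({"P2"})}
        )
        report = ratio_report(state, ref, cmap, classify_ems(ems, cmap), net)
        assert report.per_reaction_ratio["r2"] == pytest.approx(1.5)
        assert report.per_class_average["one"] == pytest.approx(1.5)
        assert report.per_class_average["two"] == pytest.approx(0.0)


def test_constraint_file_round_trip():
    text = """
    # preliminary constraints
    RXN1F-775 6.43e-2   # fixed
    RXN-8204 0 2.35e-3
    """
    parsed = parse_constraint_file(text)
    assert parsed[0].reaction_id == "RXN1F-775"
    assert parsed[0].min == parsed[0].max
    assert parsed[1].min == 0
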