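"""Scenario configurations: redox variants, uptake restriction, yield spaces."""

import math

import pytest

from coreflux.flux_core import FluxRange, fba, fva
from coreflux.network import MetabolicNetwork, MetaboliteRecord, ReactionRecord
from coreflux.scenarios import (
    ScenarioConfig,
    compare_to_mfa,
    load_preset,
    preset_names,
    redox_free_variant,
    restrict_uptake_fraction,
    run_scenario,
    yield_space,
)


@pytest.fixture
def redox_network():
    """Substrate splits between an NADH-producing and an NADH-consuming route.

    At steady state the two routes must run 1:1, capping the reduced product
    P at half the uptake; freeing the NAD/NADH balance doubles it.  The
    oxidized product B needs no net NADH and is redox-independent.
    """
    mets = [
        MetaboliteRecord("s_e", compartment="e"),
        MetaboliteRecord("a_c"), MetaboliteRecord("b_c"), MetaboliteRecord("p_c"),
        MetaboliteRecord("nad_c"), MetaboliteRecord("nadh_c"),
        MetaboliteRecord("nadp_c"), MetaboliteRecord("nadph_c"),
    ]
    rxns = [
        ReactionRecord("EX_S", {"s_e": -1.0}, -10.0, 0.0),
        ReactionRecord("UP", {"s_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
        ReactionRecord("OXID", {"a_c": -1.0, "nad_c": -1.0, "b_c": 1.0, "nadh_c": 1.0}, 0.0, 1000.0),
        ReactionRecord("REDU", {"a_c": -1.0, "nadh_c": -1.0, "p_c": 1.0, "nad_c": 1.0}, 0.0, 1000.0),
        ReactionRecord("PLAIN", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
        ReactionRecord("EX_B", {"b_c": -1.0}, 0.0, 1000.0),
        ReactionRecord("EX_P", {"p_c": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicNetwork(mets, rxns)


def test_empty_config_equals_plain_fva(branched_network):
    products = ["EX_S", "BIOMASS"]
    via_scenario = run_scenario(branched_network, ScenarioConfig(), products)
    plain = fva(branched_network, products)
    assert via_scenario == plain


class TestRedoxFree:
    def test_reduced_product_range_grows(self, redox_network):
        constrained = fva(redox_network, ["EX_P"])["EX_P"]
        free = fva(redox_free_variant(redox_network), ["EX_P"])["EX_P"]
        assert constrained.maximum == pytest.approx(5.0, abs=1e-6)
        assert free.maximum == pytest.approx(10.0, abs=1e-6)

    def test_oxidized_product_unchanged(self, redox_network):
        constrained = fva(redox_network, ["EX_B"])["EX_B"]
        free = fva(redox_free_variant(redox_network), ["EX_B"])["EX_B"]
        assert constrained.maximum == pytest.approx(free.maximum, abs=1e-6)

    def test_feasible_set_never_shrinks(self, redox_network):
        base = fva(redox_network)
        free = fva(redox_free_variant(redox_network), list(base))
        for rid in base:
            assert free[rid].minimum <= base[rid].minimum + 1e-6
            assert free[rid].maximum >= base[rid].maximum - 1e-6

    def test_missing_cofactors_listed(self, branched_network):
        with pytest.raises(KeyError, match="nad_c"):
            redox_free_variant(branched_network)

    def test_config_flag_routes_through_run_scenario(self, redox_network):
        ranges = run_scenario(redox_network, ScenarioConfig(redox_free=True), ["EX_P"])
        assert ranges["EX_P"].maximum == pytest.approx(10.0, abs=1e-6)


class TestUptakeRestriction:
    def test_tightened_nutrients_never_increase_biomass(self, branched_network):
        base = fba(branched_network).objective_value
        bounds = restrict_uptake_fraction(branched_network, ["EX_S"], fraction=0.8)
        restricted = fba(branched_network.with_bounds(bounds)).objective_value
        assert restricted <= base + 1e-9
        assert restricted == pytest.approx(0.8 * base, abs=1e-5)

    def test_bounds_are_fraction_of_max_uptake(self, branched_network):
        bounds = restrict_uptake_fraction(branched_network, ["EX_S"], fraction=0.8)
        lo, _ = bounds["EX_S"]
        assert lo == pytest.approx(-8.0, abs=1e-6)


class TestYieldSpace:
    @pytest.fixture
    def net(self, redox_network):
        # reuse the redox network with EX_P/EX_B as the two products and a
        # nominal biomass so the growth pin has a target
        rxns = list(redox_network.reactions) + [
            ReactionRecord("BIOMASS", {"a_c": -1.0}, 0.0, 1000.0)
        ]
        return MetabolicNetwork(redox_network.metabolites, rxns, "BIOMASS")

    def test_points_satisfy_yield_times_uptake_identity(self, net):
        config = ScenarioConfig(pinned_growth=2.0)
        points = yield_space(net, config, "EX_S", ["EX_P", "EX_B"], resolution=4)
        assert any(p.feasible for p in points)
        for point in points:
            if not point.feasible or point.degenerate:
                continue
            for pid, y in point.yields.items():
                assert y >= -1e-9

    def test_stoichiometric_forcing_single_route(self):
        # S -> A, 2 A -> P: every unit of P costs exactly 2 units of substrate
        mets = [MetaboliteRecord("s_e", compartment="e"), MetaboliteRecord("a_c"),
                MetaboliteRecord("p_c"), MetaboliteRecord("q_c")]
        rxns = [
            ReactionRecord("EX_S", {"s_e": -1.0}, -10.0, 0.0),
            ReactionRecord("UP", {"s_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            ReactionRecord("CONV", {"a_c": -2.0, "p_c": 1.0}, 0.0, 1000.0),
            ReactionRecord("EX_P", {"p_c": -1.0}, 0.0, 1000.0),
            ReactionRecord("SIDE", {"a_c": -1.0, "q_c": 1.0}, 0.0, 0.0),
            ReactionRecord("EX_Q", {"q_c": -1.0}, 0.0, 1000.0),
            ReactionRecord("BIOMASS", {"a_c": -1.0}, 0.0, 1000.0),
        ]
        net = MetabolicNetwork(mets, rxns, "BIOMASS")
        points = yield_space(net, ScenarioConfig(pinned_growth=0.0), "EX_S",
                             ["EX_P", "EX_Q"], resolution=3)
        for point in points:
            if not point.feasible or point.degenerate:
                continue
            assert point.yields["EX_P"] == pytest.approx(0.5, abs=1e-6)

    def test_requires_growth_pin(self, net):
        with pytest.raises(ValueError, match="pinned growth"):
            yield_space(net, ScenarioConfig(), "EX_S", ["EX_P", "EX_B"])


class TestMFAComparison:
    def test_inside_measurement_distance_zero(self):
        ranges = {"HK": FluxRange("HK", 1.0, 3.0)}
        [cmp] = compare_to_mfa(ranges, {"HK": 2.0})
        assert cmp.inside and cmp.distance == 0.0

    def test_outside_measurement_reports_gap(self):
        ranges = {"PC": FluxRange("PC", 1.0, 3.0)}
        [cmp] = compare_to_mfa(ranges, {"PC": 3.02})
        assert not cmp.inside
        assert cmp.distance == pytest.approx(0.02)

    def test_randomized_verdicts_match_naive_interval_checks(self):
        import numpy as np

        rng = np.random.default_rng(13)
        ranges = {}
        measured = {}
        for i in range(50):
            lo, hi = sorted(rng.uniform(-5, 5, size=2))
            ranges[f"r{i}"] = FluxRange(f"r{i}", lo, hi)
            measured[f"r{i}"] = float(rng.uniform(-6, 6))
        for cmp in compare_to_mfa(ranges, measured):
            fr = ranges[cmp.reaction_id]
            naive = fr.minimum - 1e-6 <= cmp.measured <= fr.maximum + 1e-6
            assert cmp.inside == naive

    def test_unmatched_reaction_listed_not_fatal(self):
        [cmp] = compare_to_mfa({}, {"GHOST": 1.0})
        assert cmp.range is None and math.isnan(cmp.distance)


class TestPresets:
    def test_all_presets_load(self):
        names = preset_names()
        assert {"acidogenic", "solventogenic", "co_gassing", "cell_recycle",
                "redox_free", "glycerol_cofeed"} <= set(names)
        for name in names:
            config = load_preset(name)
            assert config.phase in ("acidogenic", "solventogenic")

    def test_co_gassing_blocks_hydrogenase_and_feeds_butyrate(self):
        config = load_preset("co_gassing")
        assert "HYDA" in config.blocked_reactions
        assert config.nutrient_bounds["EX_but_e"][0] < 0
        assert config.pinned_growth == pytest.approx(0.47)

    def test_overrides_win(self):
        config = load_preset("co_gassing", {"pinned_growth": 0.52})
        assert config.pinned_growth == pytest.approx(0.52)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="acidogenic"):
            load_preset("nope")
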