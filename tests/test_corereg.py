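"""The core-set extraction procedure: bound contraction, attenuation,
hierarchical identification, and the sufficiency property."""

import pytest

from coreflux.corereg import (
    biomass_attenuation,
    corereg_run,
    identify_core_set,
    regulate_bounds,
    unregulated_ranges,
    verify_core_sufficiency,
)
from coreflux.expression import FoldChangeMap, build_fold_change_map
from coreflux.flux_core import FluxRange
from coreflux.synthetic import (
    FixtureSpec,
    PlantedRegulation,
    bottleneck_fixture,
    make_toy_network,
    plant_regulation,
)


class TestRegulateBounds:
    def test_forward_range_contracts_multiplicatively(self):
        ur = {"r": FluxRange("r", 0.0, 20.0)}
        reg = regulate_bounds(ur, FoldChangeMap({"r": 0.5}))
        assert (reg.regulated["r"].minimum, reg.regulated["r"].maximum) == (0.0, 10.0)
        assert reg.active == {"r"}

    def test_reversible_range_shrinks_both_directions(self):
        ur = {"r": FluxRange("r", -8.0, 20.0)}
        reg = regulate_bounds(ur, FoldChangeMap({"r": 0.5}))
        assert (reg.regulated["r"].minimum, reg.regulated["r"].maximum) == (-4.0, 10.0)

    def test_upregulation_leaves_bounds_untouched(self):
        ur = {"r": FluxRange("r", -8.0, 20.0)}
        reg = regulate_bounds(ur, FoldChangeMap({"r": 1.2}))
        assert reg.regulated["r"] == ur["r"]
        assert reg.active == frozenset()

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            FoldChangeMap({"r": -0.5})


class TestAttenuation:
    def test_neutral_map_gives_zero_change(self, branched_network):
        ur = unregulated_ranges(branched_network)
        reg = regulate_bounds(ur, FoldChangeMap({}))
        v_ur, v_r, rel = biomass_attenuation(branched_network, reg)
        assert v_ur == pytest.approx(v_r, abs=1e-6)
        assert rel == pytest.approx(0.0, abs=1e-6)

    def test_single_bottleneck_propagates_linearly(self, chain_network):
        # sole path to biomass contracted to 30% -> biomass drops by 70%
        ur = unregulated_ranges(chain_network)
        reg = regulate_bounds(ur, FoldChangeMap({"T_S": 0.3}))
        _, _, rel = biomass_attenuation(chain_network, reg)
        assert rel == pytest.approx(0.7, abs=1e-5)

    def test_nongrowing_model_is_an_error(self, chain_network):
        dead = chain_network.with_bounds({"EX_S": (0.0, 0.0)})
        ur = unregulated_ranges(dead)
        reg = regulate_bounds(ur, FoldChangeMap({}))
        with pytest.raises(ValueError, match="cannot grow"):
            biomass_attenuation(dead, reg)


class TestIdentifyCoreSet:
    def test_no_active_reactions_no_core(self, branched_network):
        ur = unregulated_ranges(branched_network)
        reg = regulate_bounds(ur, FoldChangeMap({}))
        _, v_r, _ = biomass_attenuation(branched_network, reg)
        core, _ = identify_core_set(branched_network, reg, v_r, 1)
        assert core.reactions == frozenset()

    def test_planted_bottleneck_is_the_core(self, chain_network):
        ur = unregulated_ranges(chain_network)
        reg = regulate_bounds(ur, FoldChangeMap({"T_S": 0.4}))
        _, v_r, _ = biomass_attenuation(chain_network, reg)
        core, achieved = identify_core_set(chain_network, reg, v_r, 1)
        assert core.reactions == {"T_S"}
        # the bottleneck's achieved maximum equals its imposed bound
        assert achieved["T_S"].maximum == pytest.approx(
            reg.regulated["T_S"].maximum, abs=1e-5
        )


class TestRun:
    def test_neutral_map_terminates_immediately(self, branched_network):
        result = corereg_run(branched_network, FoldChangeMap({}))
        assert result.terminated_reason == "attenuation_below_threshold"
        assert len(result.iterations) == 1
        assert result.iterations[0].core_set.reactions == frozenset()
        assert result.iterations[0].core_set.biomass_effect == "minimal"

    def test_two_sequential_bottlenecks_resolved_in_order(self):
        net = make_toy_network(FixtureSpec(n_branches=1, branch_length=1, trunk_length=2))
        # trunk: T_S -> R_Y1 -> R_Y2; R_Y1 is the tighter bottleneck
        c = FoldChangeMap({"R_Y1": 0.4, "T_S": 0.7})
        result = corereg_run(net, c)
        assert result.core_set(1).reactions == {"R_Y1"}
        assert result.core_set(2).reactions == {"T_S"}
        # with both neutralized the attenuation vanishes and iteration stops
        assert result.terminated_reason == "attenuation_below_threshold"

    def test_regulated_biomass_never_exceeds_unregulated(self):
        for seed in range(5):
            net, control, stress, _, _ = bottleneck_fixture(seed)
            c = build_fold_change_map(net, control, stress)
            result = corereg_run(net, c)
            for it in result.iterations:
                assert it.v_biomass_regulated <= it.v_biomass_unregulated + 1e-6

    def test_neutralizing_core_weakly_increases_biomass(self):
        net, control, stress, _, _ = bottleneck_fixture(2)
        c = build_fold_change_map(net, control, stress)
        result = corereg_run(net, c)
        biomasses = [it.v_biomass_regulated for it in result.iterations]
        assert all(b2 >= b1 - 1e-6 for b1, b2 in zip(biomasses, biomasses[1:]))

    def test_attenuation_matches_planted_fold(self):
        net, control, stress, target, fold = bottleneck_fixture(9)
        c = build_fold_change_map(net, control, stress)
        result = corereg_run(net, c)
        assert result.iterations[0].rel_change == pytest.approx(1.0 - fold, abs=1e-4)
        assert target in result.core_set(1).reactions

    def test_core_genes_collected_from_gprs(self):
        net, control, stress, target, _ = bottleneck_fixture(4)
        c = build_fold_change_map(net, control, stress)
        core = corereg_run(net, c).core_set(1)
        assert core.genes >= net.reaction(target).gpr.genes()


class TestSufficiency:
    def test_full_active_set_trivially_sufficient(self, chain_network):
        c = FoldChangeMap({"T_S": 0.5, "R_B1_1": 0.8})
        holds, dev = verify_core_sufficiency(chain_network, c, frozenset({"T_S", "R_B1_1"}))
        assert holds and dev <= 1e-6

    def test_reported_core_reproduces_full_regulation(self):
        net, control, stress, _, _ = bottleneck_fixture(6)
        c = build_fold_change_map(net, control, stress)
        result = corereg_run(net, c)
        holds, dev = verify_core_sufficiency(net, c, result.core_set(1))
        assert holds, f"max deviation {dev}"

    def test_missing_bottleneck_detected_with_positive_deviation(self, chain_network):
        c = FoldChangeMap({"T_S": 0.3})
        holds, dev = verify_core_sufficiency(chain_network, c, frozenset())
        assert not holds and dev > 1.0
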