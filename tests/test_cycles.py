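"""Thermodynamically infeasible cycle detection, classification, curation."""

import numpy as np
import pytest

from coreflux.cycles import (
    CurationAction,
    CycleVector,
    GibbsRecord,
    apply_actions,
    classify_cycle,
    close_exchanges,
    curate_until_closed,
    find_cycle_candidates,
    gibbs_restrict,
    null_space_cycles,
)
from coreflux.network import MetabolicNetwork, MetaboliteRecord, ReactionRecord
from coreflux.synthetic import random_loop_network


def _duplicate_pair_network():
    mets = [MetaboliteRecord(m) for m in ("s", "a", "b")]
    rxns = [
        ReactionRecord("EX_S", {"s": -1.0}, -10.0, 0.0),
        ReactionRecord("UP", {"s": -1.0, "a": 1.0}, 0.0, 1000.0),
        ReactionRecord("FWD", {"a": -1.0, "b": 1.0}, 0.0, 1000.0),
        ReactionRecord("REV", {"b": -1.0, "a": 1.0}, 0.0, 1000.0),
        ReactionRecord("EX_B", {"b": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicNetwork(mets, rxns)


class TestCandidates:
    def test_duplicate_pair_both_flagged(self):
        net = _duplicate_pair_network()
        assert find_cycle_candidates(net) == {"FWD", "REV"}

    def test_acyclic_chain_clean(self, chain_network):
        assert find_cycle_candidates(chain_network) == set()

    def test_three_reaction_motif_flags_exactly_the_loop(self, cycle_fixtures):
        assert find_cycle_candidates(cycle_fixtures["three_cycle"]) == {
            "ACLM", "RDMBO", "DMBO",
        }


class TestNullSpace:
    def test_duplicate_pair_single_vector(self):
        net = _duplicate_pair_network()
        vectors = null_space_cycles(net, {"FWD", "REV"})
        assert len(vectors) == 1
        coeffs = vectors[0].coefficients
        # both reactions run forward in this loop: v_FWD = v_REV
        assert coeffs == pytest.approx({"FWD": 1.0, "REV": 1.0})

    def test_seven_cycle_single_vector_support_seven(self, cycle_fixtures):
        net = cycle_fixtures["seven_cycle"]
        candidates = find_cycle_candidates(net)
        vectors = null_space_cycles(net, candidates)
        assert len(vectors) == 1
        assert len(vectors[0].support) == 7

    def test_full_rank_submatrix_gives_empty_list(self, chain_network):
        assert null_space_cycles(chain_network, {"T_S", "R_B1_1"}) == []

    def test_vectors_satisfy_steady_state(self):
        for seed in range(10):
            net, loop = random_loop_network(seed)
            candidates = find_cycle_candidates(net)
            for vec in null_space_cycles(net, candidates):
                v = vec.embed(net)
                assert np.max(np.abs(net.S @ v)) < 1e-8

    def test_scaled_vector_is_feasible_flux_of_closed_network(self, cycle_fixtures):
        net = close_exchanges(cycle_fixtures["three_cycle"])
        lb, ub = net.bounds_arrays()
        for vec in null_space_cycles(net, find_cycle_candidates(cycle_fixtures["three_cycle"])):
            v = vec.embed(net) * 10.0
            assert np.max(np.abs(net.S @ v)) < 1e-8
            assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


class TestClassification:
    def test_duplicate_written_in_both_directions_is_equivalent_pair(self):
        mets = [MetaboliteRecord(m) for m in ("a", "b", "nad", "nadh")]
        rxns = [
            ReactionRecord("PT1", {"a": -1.0, "nad": -1.0, "b": 1.0, "nadh": 1.0}, -1000, 1000),
            ReactionRecord("PT2", {"b": -1.0, "nadh": -1.0, "a": 1.0, "nad": 1.0}, -1000, 1000),
            ReactionRecord("EX_A", {"a": -1.0}, -10, 10),
            ReactionRecord("EX_B", {"b": -1.0}, -10, 10),
        ]
        net = MetabolicNetwork(mets, rxns)
        cycle = CycleVector({"PT1": 1.0, "PT2": 1.0})
        assert classify_cycle(cycle, net) == "equivalent_pair"

    def test_three_reaction_motif_is_multi(self, cycle_fixtures):
        net = cycle_fixtures["three_cycle"]
        vec = null_space_cycles(net, find_cycle_candidates(net))[0]
        assert classify_cycle(vec, net) == "multi_reaction"

    def test_cofactor_mismatch_is_not_equivalent(self):
        mets = [MetaboliteRecord(m) for m in ("a", "b", "nad", "nadh", "nadp", "nadph")]
        rxns = [
            ReactionRecord("DH_NAD", {"a": -1.0, "nad": -1.0, "b": 1.0, "nadh": 1.0}, -1000, 1000),
            ReactionRecord("DH_NADP", {"b": -1.0, "nadph": -1.0, "a": 1.0, "nadp": 1.0}, -1000, 1000),
        ]
        net = MetabolicNetwork(mets, rxns)
        pair = CycleVector({"DH_NAD": 1.0, "DH_NADP": 1.0})
        assert classify_cycle(pair, net) == "multi_reaction"


class TestGibbs:
    @pytest.fixture
    def net(self):
        mets = [MetaboliteRecord(m) for m in ("a", "b")]
        rxns = [ReactionRecord("R", {"a": -1.0, "b": 1.0}, -1000.0, 1000.0),
                ReactionRecord("EX_A", {"a": -1.0}, -10, 10),
                ReactionRecord("EX_B", {"b": -1.0}, -10, 10)]
        return MetabolicNetwork(mets, rxns)

    def test_strongly_negative_restricts_forward(self, net):
        actions = gibbs_restrict(net, [GibbsRecord("R", -10.0, 2.0)])
        assert [a.action for a in actions] == ["forward_only"]
        out = apply_actions(net, actions)
        assert out.reaction("R").lower_bound == 0.0

    def test_interval_reaching_threshold_means_no_action(self, net):
        assert gibbs_restrict(net, [GibbsRecord("R", -5.0, 3.0)]) == []

    def test_strongly_positive_restricts_reverse(self, net):
        actions = gibbs_restrict(net, [GibbsRecord("R", 6.0, 1.0)])
        assert [a.action for a in actions] == ["reverse_only"]
        out = apply_actions(net, actions)
        assert out.reaction("R").upper_bound == 0.0

    def test_idempotent_and_never_reverses_consistent_bounds(self, net):
        once = apply_actions(net, gibbs_restrict(net, [GibbsRecord("R", -10.0, 2.0)]))
        again = gibbs_restrict(once, [GibbsRecord("R", -10.0, 2.0)])
        assert again == []


class TestCuration:
    def test_removing_aggregate_reaction_closes_three_cycle(self, cycle_fixtures):
        net = cycle_fixtures["three_cycle"]
        fixed, report = curate_until_closed(
            net, [CurationAction("ACLM", "remove", "aggregate of RDMBO+DMBO")]
        )
        assert report.closed
        assert find_cycle_candidates(fixed) == set()

    def test_seven_cycle_fixed_by_removal_plus_restriction(self, cycle_fixtures):
        net = cycle_fixtures["seven_cycle"]
        actions = [
            CurationAction("MDH", "remove", "no flux in tracer data"),
            CurationAction("ASPA", "forward_only", "produces fumarate from aspartate"),
        ]
        fixed, report = curate_until_closed(net, actions)
        assert report.closed
        assert not fixed.has_reaction("MDH")
        assert fixed.reaction("ASPA").lower_bound == 0.0

    def test_acyclic_network_unchanged_with_empty_actions(self, chain_network):
        fixed, report = curate_until_closed(chain_network, [])
        assert report.closed
        assert len(report.passes) == 1 and report.passes[0].cycles == []
        assert fixed.reaction_ids == chain_network.reaction_ids

    def test_unresolved_cycles_are_reported_not_dropped(self, cycle_fixtures):
        net = cycle_fixtures["three_cycle"]
        _, report = curate_until_closed(net, [])
        assert not report.closed
        assert report.remaining_cycles

    def test_action_on_absent_reaction_errors(self, chain_network):
        with pytest.raises(KeyError):
            curate_until_closed(chain_network, [CurationAction("NOPE", "remove")])
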