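"""Structural invariants of network construction, moves and mutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnscape.network import (
    Mutation,
    NetworkParameterError,
    RegulatoryNetwork,
    apply_mutation,
    enumerate_all_networks,
    make_random_network,
    max_edges,
    propose_edge_move,
    structural_check,
)


def assert_structurally_sound(net, k):
    J = net.interactions
    assert np.all(np.diag(J) == 0)
    assert not np.any((J != 0) & (J.T != 0))
    assert np.count_nonzero(J) == k
    assert np.all(np.isin(J, (-1, 0, 1)))


class TestMakeRandomNetwork:
    @pytest.mark.parametrize("n, k", [(6, 15), (32, 80), (2, 1), (5, 10)])
    def test_invariants(self, n, k, rng):
        for _ in range(20):
            assert_structurally_sound(make_random_network(n, k, rng), k)

    def test_capacity_and_size_errors(self, rng):
        with pytest.raises(NetworkParameterError):
            make_random_network(3, 4, rng)  # capacity is 3
        with pytest.raises(NetworkParameterError):
            make_random_network(1, 0, rng)
        assert max_edges(3) == 3

    def test_invariants_many_draws(self, rng):
        """10^4 draws all satisfy the structural invariants; signs balance."""
        n, k = 8, 12
        pos = 0
        for _ in range(10_000):
            net = make_random_network(n, k, rng)
            J = net.interactions
            assert np.all(np.diag(J) == 0)
            assert not np.any((J != 0) & (J.T != 0))
            assert np.count_nonzero(J) == k
            pos += np.count_nonzero(J == 1)
        total = 10_000 * k
        # fraction of activations is 1/2 within 3 sigma binomial
        sigma = 0.5 / np.sqrt(total)
        assert abs(pos / total - 0.5) < 3 * sigma


class TestStructuralCheck:
    def test_two_gene_chain_passes(self, two_gene_chain):
        rep = structural_check(two_gene_chain, 1)
        assert rep.ok and rep.input_reaches_all and rep.nodes_reaching.all()

    def test_star_out_of_input_fails_reaching(self, rng):
        # edges only out of the input: g2 cannot reach g1
        J = np.zeros((3, 3), dtype=np.int8)
        J[1, 0] = 1
        J[2, 0] = 1
        rep = structural_check(RegulatoryNetwork(3, J), 1)
        assert rep.input_reaches_all
        assert not rep.nodes_reaching[2]
        assert rep.violation == "output_not_reached"

    def test_input_without_out_edges_fails(self):
        J = np.zeros((3, 3), dtype=np.int8)
        J[1, 2] = 1  # only 2 -> 1
        rep = structural_check(RegulatoryNetwork(3, J), 1)
        assert not rep.input_reaches_all
        assert rep.violation == "input_unreachable"

    def test_candidate_equal_input_rejected(self, two_gene_chain):
        with pytest.raises(NetworkParameterError):
            structural_check(two_gene_chain, 0)


class TestProposeEdgeMove:
    def test_preserves_edge_count_and_invariants(self, rng):
        net = make_random_network(10, 20, rng)
        for _ in range(10_000):
            prop = propose_edge_move(net, rng)
            assert_structurally_sound(prop, 20)
            net = prop

    def test_full_capacity_only_vacated_slot(self, rng):
        n = 4
        net = make_random_network(n, max_edges(n), rng)
        for _ in range(50):
            prop = propose_edge_move(net, rng)
            assert_structurally_sound(prop, max_edges(n))
            # at capacity the occupied pair set is unchanged
            occ = lambda J: {(min(i, j), max(i, j)) for i, j in np.argwhere(J != 0)}
            assert occ(prop.interactions) == occ(net.interactions)

    def test_seeded_reproducibility(self):
        net = make_random_network(6, 8, np.random.default_rng(7))
        a = propose_edge_move(net, np.random.default_rng(99))
        b = propose_edge_move(net, np.random.default_rng(99))
        assert np.array_equal(a.interactions, b.interactions)

    def test_keep_sign_option(self, rng):
        net = make_random_network(6, 8, rng)
        signs_before = set(net.interactions[net.interactions != 0].tolist())
        for _ in range(200):
            prop = propose_edge_move(net, rng, rerandomize_sign=False)
            # multiset of signs is preserved when the sign is carried over
            assert sorted(prop.interactions[prop.interactions != 0].tolist()) == sorted(
                net.interactions[net.interactions != 0].tolist()
            )
            net = prop
        assert signs_before  # sanity


class TestApplyMutation:
    def test_delete_then_add_restores(self, rng):
        net = make_random_network(7, 10, rng)
        i, j = map(int, net.edge_list()[3])
        sign = int(net.interactions[i, j])
        deleted = apply_mutation(net, Mutation("delete_edge", (i, j)))
        restored = apply_mutation(deleted, Mutation("add_edge", (i, j), sign))
        assert np.array_equal(restored.interactions, net.interactions)

    def test_delete_only_edge_keeps_mutant(self, two_gene_chain):
        mut = apply_mutation(two_gene_chain, Mutation("delete_edge", (1, 0)))
        assert mut.n_edges == 0
        assert mut.output_node == 1  # designations preserved

    def test_delete_absent_edge_errors(self, two_gene_chain):
        with pytest.raises(NetworkParameterError):
            apply_mutation(two_gene_chain, Mutation("delete_edge", (0, 1)))

    def test_add_onto_reverse_occupied_errors(self, two_gene_chain):
        with pytest.raises(NetworkParameterError):
            apply_mutation(two_gene_chain, Mutation("add_edge", (0, 1), 1))

    def test_knockout_middle_gene_zeroes_row_and_column(self, three_gene_chain):
        mut = apply_mutation(three_gene_chain, Mutation("knockout_node", (1,)))
        assert np.count_nonzero(mut.interactions) == 0

    def test_knockout_input_or_output_errors(self, three_gene_chain):
        for k in (0, 2):
            with pytest.raises(NetworkParameterError):
                apply_mutation(three_gene_chain, Mutation("knockout_node", (k,)))

    def test_scan_nondestructive(self, rng):
        net = make_random_network(6, 9, rng)
        before = net.interactions.copy()
        apply_mutation(net, Mutation("delete_edge", tuple(map(int, net.edge_list()[0]))))
        assert np.array_equal(net.interactions, before)


class TestEnumeration:
    @pytest.mark.parametrize("n, k, expected", [(2, 1, 4), (3, 3, 64), (3, 2, 48)])
    def test_counts_match_closed_form(self, n, k, expected):
        nets = list(enumerate_all_networks(n, k))
        assert len(nets) == expected
        # pairwise distinct
        seen = {net.interactions.tobytes() for net in nets}
        assert len(seen) == expected
        for net in nets:
            assert_structurally_sound(net, k)

    def test_cap_refused_with_estimate(self):
        with pytest.raises(NetworkParameterError, match="networks"):
            list(enumerate_all_networks(8, 14, cap=1000))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_random_networks_always_sound(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    k = int(rng.integers(1, max_edges(n) + 1))
    assert_structurally_sound(make_random_network(n, k, rng), k)
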