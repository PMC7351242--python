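"""Multicanonical sampler against exhaustive-enumeration oracles."""

import math

import numpy as np
import pytest

from grnscape.dynamics import DynamicsParams, evaluate_fitness
from grnscape.network import RegulatoryNetwork, enumerate_all_networks
from grnscape.sampler import (
    FitnessBins,
    MeasureConfig,
    WeightTable,
    WLConfig,
    entropic_run,
    estimate_density,
    exact_density_small,
    random_valid_network,
    wang_landau,
)


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


CHAIN_FITNESS = abs(sigmoid(sigmoid(1.0)) - sigmoid(sigmoid(0.0)))


class TestFitnessBins:
    def test_edges_cover_unit_interval(self):
        bins = FitnessBins(100)
        assert bins.edges[0] == 0.0 and bins.edges[-1] == 1.0
        assert len(bins.edges) == 101
        assert np.all(np.diff(bins.edges) > 0)

    def test_half_open_with_closed_last(self):
        bins = FitnessBins(100)
        assert bins.index(0.0) == 0
        assert bins.index(0.01) == 1  # [0.01, 0.02)
        assert bins.index(1.0) == 99  # closed last bin


class TestExactDensitySmall:
    def test_two_gene_hand_enumeration(self):
        """(2,1): of 4 networks only the two with an input->output edge are
        valid; both signs give |R(+-R(I))| differences of equal magnitude,
        so all mass sits in one bin at the chain fitness."""
        density = exact_density_small(2, 1)
        assert density.histogram.sum() == 2
        expected_bin = FitnessBins().index(CHAIN_FITNESS)
        assert density.histogram[expected_bin] == 2
        assert density.probability[expected_bin] == pytest.approx(1.0)

    def test_total_probability_one(self):
        density = exact_density_small(4, 4)
        assert density.probability[density.resolved].sum() == pytest.approx(1.0)

    def test_bin_refinement_preserves_coarse_mass(self):
        coarse = exact_density_small(4, 4, FitnessBins(10))
        fine = exact_density_small(4, 4, FitnessBins(100))
        folded = fine.histogram.reshape(10, 10).sum(axis=1)
        assert np.array_equal(folded, coarse.histogram)

    def test_validity_rule_matches_evaluate_fitness(self):
        n_valid = 0
        for net in enumerate_all_networks(3, 3):
            if evaluate_fitness(net).valid:
                n_valid += 1
        density = exact_density_small(3, 3)
        assert density.histogram.sum() == n_valid


@pytest.fixture(scope="module")
def toy_weights():
    rng = np.random.default_rng(777)
    return wang_landau(
        4,
        4,
        FitnessBins(),
        WLConfig(ln_f_final=1e-8, check_interval=2000, max_moves=5_000_000),
        rng,
    )


class TestWangLandau:
    def test_converges_on_toy(self, toy_weights):
        assert toy_weights.converged
        assert toy_weights.final_mod_factor < 1e-8

    def test_learned_weights_match_enumeration(self, toy_weights):
        """Learned ln-density per bin agrees with exact enumeration up to
        an additive constant on well-populated bins."""
        exact = exact_density_small(4, 4)
        sup = exact.histogram >= 10
        lng = -toy_weights.log_weight
        assert np.all(toy_weights.visited[sup])
        diff = lng[sup] - np.log(exact.histogram[sup])
        assert diff.max() - diff.min() < 0.6  # additive-constant agreement

    def test_entropic_flat_histogram_with_exact_weights(self, toy_weights):
        """With exact weights the recorded-bin frequencies are uniform over
        reachable bins (the stationary law is 1/Omega per network)."""
        exact = exact_density_small(4, 4)
        sup = exact.histogram > 0
        lw = np.zeros(100)
        lw[sup] = -np.log(exact.histogram[sup].astype(float))
        weights = WeightTable(
            bins=FitnessBins(),
            log_weight=lw,
            visit_histogram=np.zeros(100, dtype=np.int64),
            visited=sup.copy(),
            converged=True,
            final_mod_factor=0.0,
            moves_used=0,
            state=toy_weights.state,
            state_fitness=toy_weights.state_fitness,
        )
        res = entropic_run(
            weights,
            MeasureConfig(n_mcs=40_000, sample_interval=1),
            np.random.default_rng(5),
        )
        freqs = res.histogram[sup] / res.histogram.sum()
        n_sup = sup.sum()
        assert res.histogram[~sup].sum() == 0
        assert np.allclose(freqs, 1 / n_sup, atol=0.25 / n_sup)

    def test_estimated_density_matches_oracle(self, toy_weights):
        """KL(exact || estimated) is small at 10^5 recorded samples."""
        res = entropic_run(
            toy_weights,
            MeasureConfig(n_mcs=100_000, sample_interval=1),
            np.random.default_rng(6),
        )
        density = estimate_density(res.histogram, toy_weights)
        exact = exact_density_small(4, 4)
        sup = exact.probability > 0
        pe = exact.probability[sup]
        ps = density.probability[sup]
        assert np.all(ps > 0)
        kl = float(np.sum(pe * np.log(pe / ps)))
        assert kl < 0.05

    def test_reproducible_sample_stream(self, toy_weights):
        cfg = MeasureConfig(n_mcs=2_000, sample_interval=1)
        a = entropic_run(toy_weights, cfg, np.random.default_rng(11))
        b = entropic_run(toy_weights, cfg, np.random.default_rng(11))
        assert np.array_equal(a.fitness_values, b.fitness_values)
        assert np.array_equal(a.state.interactions, b.state.interactions)

    def test_sample_cadence(self, toy_weights):
        res = entropic_run(
            toy_weights,
            MeasureConfig(n_mcs=500, sample_interval=10),
            np.random.default_rng(3),
        )
        assert len(res.fitness_values) == 50

    def test_stored_networks_live_in_window(self, toy_weights):
        res = entropic_run(
            toy_weights,
            MeasureConfig(n_mcs=20_000, sample_interval=1, store_range=(0.05, 0.2)),
            np.random.default_rng(8),
        )
        assert res.stored_networks
        for net in res.stored_networks:
            f = evaluate_fitness(net).fitness
            assert 0.05 <= f < 0.2
            assert net.output_node == evaluate_fitness(net).output_node


class TestEstimateDensity:
    def test_algebraic_identity(self):
        """Exact weights + flat histogram recover the implied density."""
        bins = FitnessBins(10)
        lng = np.array([0.0, 2.0, 1.0, 0, 0, 0, 0, 0, 0, 0])
        hist = np.array([100, 100, 100, 0, 0, 0, 0, 0, 0, 0])
        dummy = RegulatoryNetwork(2, np.array([[0, 0], [1, 0]], dtype=np.int8))
        weights = WeightTable(bins, -lng, hist, hist > 0, True, 0.0, 0, dummy, 0.0)
        density = estimate_density(hist, weights)
        expected = np.exp(lng[:3]) / np.exp(lng[:3]).sum()
        assert density.probability[:3] == pytest.approx(expected)
        assert np.all(np.isneginf(density.log_rel_states[3:]))

    def test_empty_histogram_rejected(self):
        bins = FitnessBins(10)
        dummy = RegulatoryNetwork(2, np.array([[0, 0], [1, 0]], dtype=np.int8))
        weights = WeightTable(
            bins,
            np.zeros(10),
            np.zeros(10, dtype=np.int64),
            np.zeros(10, dtype=bool),
            True,
            0.0,
            0,
            dummy,
            0.0,
        )
        with pytest.raises(ValueError):
            estimate_density(np.zeros(10), weights)


def test_random_valid_network_satisfies_rule(rng):
    net, f = random_valid_network(8, 16, rng)
    res = evaluate_fitness(net)
    assert res.valid
    assert res.fitness == pytest.approx(f)
    assert net.output_node == res.output_node
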