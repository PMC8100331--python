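"""Unit and property tests for the five-step competitive update rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crba.core import (
    CRBAConfig,
    batch_em_update,
    firing_rates,
    init_weights,
    init_weights_spread,
    normalize_columns,
    predicted_spikes,
    select_winners,
    sequential_em_update,
    update_thresholds,
    update_winner_weights,
    winner_coefficients,
)


@pytest.fixture
def config():
    return CRBAConfig(m=3, n=1, seed=0)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"m": 0}, {"n": 0}, {"m": 2, "n": 3}, {"t": 0}, {"lam": -1},
        {"tau_theta": 0}, {"theta_0": 1e-4}, {"theta_floor": 0},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            CRBAConfig(**bad)

    def test_roundtrip_and_unknown_keys(self):
        cfg = CRBAConfig(m=7, seed=3)
        assert CRBAConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValueError, match="unknown config keys"):
            CRBAConfig.from_dict({"m": 7, "bogus": 1})


class TestNormalization:
    def test_column_sums_and_idempotence(self, rng):
        W = rng.uniform(0.1, 2.0, (5, 4))
        Wn = normalize_columns(W, 1.5)
        assert np.allclose(Wn.sum(axis=0), 1.5)
        assert np.allclose(normalize_columns(Wn, 1.5), Wn)

    def test_simple_column(self):
        assert np.allclose(normalize_columns(np.array([[2.0], [2.0]]), 1.0),
                           [[0.5], [0.5]])

    def test_commutes_with_positive_scaling(self, rng):
        W = rng.uniform(0.1, 1.0, (6, 3))
        scale = rng.uniform(0.5, 3.0, 3)
        assert np.allclose(normalize_columns(W * scale, 1.0),
                           normalize_columns(W, 1.0))

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            normalize_columns(np.zeros((3, 1)), 1.0)


class TestInitWeights:
    def test_single_sample_normalizes_to_equal_split(self):
        W = init_weights(np.array([[2.0, 2.0]]), m=1, lam=1.0, seed=0, jitter=0.0)
        assert np.allclose(W[:, 0], [0.5, 0.5])

    def test_deterministic_distinct_columns(self, rng):
        X = rng.uniform(0, 1, (10, 6))
        W1 = init_weights(X, m=3, lam=1.0, seed=5)
        W2 = init_weights(X, m=3, lam=1.0, seed=5)
        assert np.array_equal(W1, W2)
        assert np.allclose(W1.sum(axis=0), 1.0)
        # without replacement: three distinct source samples
        assert len({tuple(np.round(c, 6)) for c in W1.T}) == 3

    def test_more_neurons_than_samples_redraws(self, rng):
        X = rng.uniform(0.1, 1, (10, 8))
        W = init_weights(X, m=20, lam=2.0, seed=1)
        assert W.shape == (8, 20)
        assert np.allclose(W.sum(axis=0), 2.0)
        # every extra column is (a jittered copy of) one of the 10 samples
        Xn = X / X.sum(axis=1, keepdims=True)
        for j in range(10, 20):
            cos = (Xn @ W[:, j]) / (np.linalg.norm(Xn, axis=1) * np.linalg.norm(W[:, j]))
            assert cos.max() > 0.999

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no initialization samples"):
            init_weights(np.empty((0, 4)), m=2, lam=1.0)

    def test_spread_covers_clusters(self, two_cluster_data):
        W = init_weights_spread(two_cluster_data.X, m=2, lam=1.0, seed=0)
        protos = two_cluster_data.meta["prototypes"]
        Pn = protos / np.linalg.norm(protos, axis=1, keepdims=True)
        Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
        best = (Wn.T @ Pn.T).argmax(axis=1)
        assert set(best) == {0, 1}


class TestFiringRates:
    def test_zero_input_zero_rates(self):
        W = np.full((4, 3), 0.25)
        assert np.all(firing_rates(np.zeros(4), W, np.full(3, 20.0)) == 0)

    def test_hand_computed(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        rates = firing_rates(np.array([0.8, 0.2]), W, np.array([20.0, 20.0]))
        assert np.allclose(rates, [0.04, 0.01])

    def test_uniform_theta_preserves_dot_ranking(self, rng):
        x = rng.uniform(0, 1, 5)
        W = rng.uniform(0, 1, (5, 6))
        rates = firing_rates(x, W, np.full(6, 17.0))
        assert np.array_equal(np.argsort(rates), np.argsort(x @ W))

    def test_floor_guards_nonpositive_theta(self):
        W = np.array([[1.0], [0.0]])
        r = firing_rates(np.array([0.5, 0.5]), W, np.array([-4.0]), theta_floor=1e-3)
        assert np.isfinite(r[0]) and r[0] == 0.5 / 1e-3

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            firing_rates(np.ones(3), np.ones((4, 2)), np.full(2, 20.0))


class TestSelectWinners:
    def test_single_max(self):
        assert select_winners(np.array([0.1, 0.5, 0.2]), 1).tolist() == [1]

    def test_full_sort_is_descending_permutation(self, rng):
        rates = rng.uniform(0, 1, 7)
        order = select_winners(rates, 7)
        assert sorted(order.tolist()) == list(range(7))
        assert np.all(np.diff(rates[order]) <= 0)

    @pytest.mark.parametrize("rates,expected", [
        ([0.3, 0.3, 0.1], [0, 1]),
        ([0.3, 0.1, 0.3], [0, 2]),
        ([0.1, 0.3, 0.3], [1, 2]),
        ([0.3, 0.3, 0.3], [0, 1]),
    ])
    def test_tie_break_lowest_index(self, rates, expected):
        assert select_winners(np.array(rates), 2).tolist() == expected

    def test_n_exceeds_m(self):
        with pytest.raises(ValueError):
            select_winners(np.ones(3), 4)


class TestWinnerCoefficients:
    def test_single_winner_unit(self):
        assert np.allclose(winner_coefficients(1), [1.0])

    def test_three_winner_values(self):
        assert np.allclose(winner_coefficients(3),
                           [1.0, np.exp(-5 / 3), np.exp(-10 / 3)])

    @pytest.mark.parametrize("n", [1, 2, 5, 17])
    def test_leading_one_and_strictly_decreasing(self, n):
        c = winner_coefficients(n)
        assert c[0] == 1.0
        assert np.all(np.diff(c) < 0) or n == 1
        assert np.all(c > 0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            winner_coefficients(0)


class TestPredictedSpikes:
    def test_zero_rates(self, config):
        assert np.all(predicted_spikes(np.zeros(3), np.array([0]), config) == 0)

    def test_hand_computed(self):
        cfg = CRBAConfig(m=1, n=1, alpha_s=10.0, t=350.0)
        spikes = predicted_spikes(np.array([0.01]), np.array([0]), cfg)
        assert np.allclose(spikes, [35.0])

    def test_operating_point_bracket(self):
        # winner dot product tuned to the designed regime: the default
        # constants should put the winner near a few tens of spikes
        cfg = CRBAConfig()
        rate = 0.17 / cfg.theta_0
        spikes = predicted_spikes(np.array([rate]), np.array([0]), cfg)
        assert 10.0 <= spikes[0] <= 60.0


class TestWeightUpdate:
    def test_zero_learning_rate_is_identity(self, rng):
        cfg = CRBAConfig(m=2, n=1, alpha_w=0.0)
        W = normalize_columns(rng.uniform(0.1, 1, (4, 2)), cfg.lam)
        W2 = update_winner_weights(W.copy(), rng.uniform(0, 1, 4),
                                   np.array([1]), np.array([10.0]), cfg)
        assert np.allclose(W2, W)

    def test_hand_computed(self):
        cfg = CRBAConfig(m=1, n=1, alpha_w=1.0, lam=1.0)
        W = np.array([[0.5], [0.5]])
        W2 = update_winner_weights(W, np.array([1.0, 0.0]), np.array([0]),
                                   np.array([1.0]), cfg)
        assert np.allclose(W2[:, 0], [0.75, 0.25])

    def test_non_winner_columns_untouched(self, rng):
        cfg = CRBAConfig(m=4, n=1)
        W = normalize_columns(rng.uniform(0.1, 1, (5, 4)), cfg.lam)
        before = W.copy()
        update_winner_weights(W, rng.uniform(0, 1, 5), np.array([2]),
                              np.array([30.0]), cfg)
        others = [0, 1, 3]
        assert np.array_equal(W[:, others], before[:, others])

    def test_repeated_presentation_monotone_cosine(self, rng):
        # the winner column climbs toward the presented pattern
        cfg = CRBAConfig(m=1, n=1, alpha_w=5e-3)
        x = rng.uniform(0.1, 1, 8)
        W = normalize_columns(rng.uniform(0.1, 1, (8, 1)), cfg.lam)
        cosines = []
        for _ in range(200):
            update_winner_weights(W, x, np.array([0]), np.array([30.0]), cfg)
            cosines.append(float(x @ W[:, 0] / (np.linalg.norm(x) * np.linalg.norm(W[:, 0]))))
        assert np.all(np.diff(cosines) >= -1e-12)
        assert cosines[-1] > 0.999


class TestThresholdUpdate:
    def test_hand_computed_table_constants(self):
        cfg = CRBAConfig(m=1, n=1, alpha_theta=0.05, theta_r=-10.0, tau_theta=1e5)
        theta = update_thresholds(np.array([20.0]), np.array([0]),
                                  np.array([35.0]), cfg)
        assert np.allclose(theta, [21.75 + (-10.0 - 21.75) / 1e5])
        assert np.allclose(theta, [21.7496825])

    def test_infinite_tau_no_decay(self):
        cfg = CRBAConfig(m=2, n=1, tau_theta=np.inf)
        theta = update_thresholds(np.array([20.0, 20.0]), np.array([0]),
                                  np.array([0.0]), cfg)
        assert np.allclose(theta, [20.0, 20.0])

    def test_never_winning_neuron_relaxes_toward_rest(self):
        cfg = CRBAConfig(m=1, n=1, theta_r=-10.0, tau_theta=100.0)
        theta = np.array([20.0])
        prev = theta[0]
        for _ in range(50):
            update_thresholds(theta, np.array([], dtype=int), np.array([]), cfg)
            assert theta[0] < prev
            prev = theta[0]
        assert theta[0] > cfg.theta_r


class TestDiscreteEM:
    def test_single_sample_is_identity(self):
        assert np.allclose(batch_em_update(np.array([[0.2, 0.8]])), [0.2, 0.8])

    def test_mean_of_two(self):
        assert np.allclose(batch_em_update(np.array([[0.0, 1.0], [1.0, 0.0]])),
                           [0.5, 0.5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            batch_em_update(np.empty((0, 3)))

    def test_sequential_one_over_k_recovers_batch_mean(self, rng):
        # Robbins-Monro telescoping: with step 1/k the online rule equals
        # the running mean exactly, independent of the start value
        for _ in range(20):
            X = rng.uniform(0, 1, (rng.integers(1, 30), 5))
            mu = rng.uniform(0, 1, 5)  # arbitrary start, cancelled at k=1
            for k, x in enumerate(X, start=1):
                mu = sequential_em_update(mu, x, k)
            np.testing.assert_allclose(mu, batch_em_update(X), rtol=0, atol=1e-14)


class TestInvariantProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalization_conserved_and_single_winner_locality(self, seed):
        rng = np.random.default_rng(seed)
        m, p = 5, 6
        cfg = CRBAConfig(m=m, n=1, seed=0)
        W = normalize_columns(rng.uniform(0.05, 1, (p, m)), cfg.lam)
        theta = np.full(m, cfg.theta_0)
        for _ in range(5):
            x = rng.uniform(0, 1, p)
            rates = firing_rates(x, W, theta, cfg.theta_floor)
            winners = select_winners(rates, cfg.n)
            spikes = predicted_spikes(rates, winners, cfg)
            W_before, th_before = W.copy(), theta.copy()
            update_winner_weights(W, x, winners, spikes, cfg)
            update_thresholds(theta, winners, spikes, cfg)
            # column sums conserved to 1e-9 relative
            np.testing.assert_allclose(W.sum(axis=0), cfg.lam, rtol=1e-9)
            # exactly one column changed
            changed = [j for j in range(m) if not np.array_equal(W[:, j], W_before[:, j])]
            assert changed == [int(winners[0])] or changed == []
            # only the winner got a plasticity increment; everyone decayed
            decayed = th_before + (cfg.theta_r - th_before) / cfg.tau_theta
            non_winners = [j for j in range(m) if j != winners[0]]
            np.testing.assert_allclose(theta[non_winners], decayed[non_winners])
            assert theta[winners[0]] > decayed[winners[0]] or spikes[0] == 0
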