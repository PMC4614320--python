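"""Unit tests for the three-layer feed-forward lesion model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionlab import (
    ConfigurationError,
    EtaPolicy,
    ThreeLayerParams,
    UsageError,
    build_network,
    eta_of_H,
    hamming,
    hebbian_delta,
    middle_step,
    output_step,
    pre_lesion_train,
    train_step,
)
from lesionlab.threelayer import ring_mask


class TestBuildNetwork:
    def test_reference_fanout_is_inclusive_range(self):
        # the inclusive modular range j-n//2 .. j+n//2 holds n+1 nodes
        params = ThreeLayerParams()  # N=500, n=100
        state = build_network(params, seed=0)
        assert params.n_effective == 101
        np.testing.assert_array_equal(state.mask.sum(axis=0), 101)
        np.testing.assert_array_equal(state.mask.sum(axis=1), 101)

    def test_weights_masked_and_bounded(self):
        params = ThreeLayerParams(N=10, n=2)
        state = build_network(params, seed=3)
        for W in (state.W_im, state.W_mo):
            assert np.all(W[~state.mask] == 0.0)
            assert W.min() >= params.w_min and W.max() <= params.w_max

    def test_deterministic_given_seed(self, scaled_params):
        a = build_network(scaled_params, seed=42)
        b = build_network(scaled_params, seed=42)
        np.testing.assert_array_equal(a.W_im, b.W_im)
        np.testing.assert_array_equal(a.W_mo, b.W_mo)
        np.testing.assert_array_equal(a.input_pattern, b.input_pattern)
        np.testing.assert_array_equal(a.desired_output, b.desired_output)

    def test_pattern_active_fraction(self, scaled_params):
        state = build_network(scaled_params, seed=0)
        assert state.input_pattern.sum() == 50
        assert state.desired_output.sum() == 50

    @pytest.mark.parametrize(
        "bad",
        [
            dict(N=0),
            dict(n=0),
            dict(n=100, N=50),
            dict(w_min=5.0, w_max=1.0),
            dict(w_min=-1.0),
            dict(eta0=0.0),
            dict(active_fraction=1.5),
            dict(Hc=2.0),  # Hc <= H0
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            build_network(ThreeLayerParams(**bad), seed=0)


class TestDynamics:
    def test_middle_sigmoid_matches_hand_evaluation(self, scaled_params, rng):
        # drive a single middle node at a known X and measure its rate
        beta, theta = scaled_params.beta, scaled_params.theta_ml
        for X in [theta, theta - 4.0, theta + 4.0, 0.0, 20.0]:
            expected = 1.0 / (1.0 + np.exp(-beta * (X - theta)))
            state = build_network(scaled_params, seed=0)
            state.W_im[:, :] = 0.0
            state.input_pattern[:] = 0
            state.input_pattern[0] = 1
            state.W_im[:, 0] = np.where(state.mask[:, 0], X, 0.0)
            node = 0  # input 0 feeds middle 0
            draws = [middle_step(state, scaled_params, rng)[node] for _ in range(4000)]
            assert np.mean(draws) == pytest.approx(expected, abs=0.03)

    def test_dead_nodes_never_fire(self, scaled_params, rng):
        state = build_network(scaled_params, seed=0)
        state.kill(np.arange(0, 30))
        for _ in range(10):
            m = middle_step(state, scaled_params, rng)
            assert np.all(m[:30] == 0)

    def test_output_threshold_and_tie(self, scaled_params):
        state = build_network(scaled_params, seed=0)
        state.W_mo[:, :] = 0.0
        middle = np.zeros(state.N, dtype=np.int8)
        out = output_step(state, middle, scaled_params)
        assert np.all(out == 0)  # zero drive, positive threshold
        # one active middle node at w_max exceeds theta_output
        middle[0] = 1
        state.W_mo[0, 0] = scaled_params.w_max
        assert output_step(state, middle, scaled_params)[0] == 1
        # a tie at exactly theta counts as firing
        state.W_mo[0, 0] = scaled_params.theta_output
        assert output_step(state, middle, scaled_params)[0] == 1
        # deterministic on repeated calls
        np.testing.assert_array_equal(
            output_step(state, middle, scaled_params),
            output_step(state, middle, scaled_params),
        )

    def test_output_length_check(self, scaled_params):
        state = build_network(scaled_params, seed=0)
        with pytest.raises(UsageError):
            output_step(state, np.zeros(7, dtype=np.int8), scaled_params)


class TestHamming:
    def test_examples(self):
        assert hamming([1, 0, 1, 1, 0], [1, 1, 1, 0, 0]) == 2
        v = np.ones(500, dtype=np.int8)
        assert hamming(v, v) == 0
        assert hamming(v, 1 - v) == 500

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            hamming([1, 0], [1, 0, 1])

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_metric_properties(self, data):
        n = data.draw(st.integers(1, 40))
        bits = st.lists(st.integers(0, 1), min_size=n, max_size=n)
        a = np.array(data.draw(bits))
        b = np.array(data.draw(bits))
        c = np.array(data.draw(bits))
        assert hamming(a, a) == 0
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)
        # brute-force positionwise count
        assert hamming(a, b) == sum(int(x != y) for x, y in zip(a, b))


class TestEtaPolicy:
    def test_fixed_ignores_H(self):
        pol = EtaPolicy.fixed(0.01)
        assert eta_of_H(0, pol) == 0.01
        assert eta_of_H(1e6, pol) == 0.01

    def test_modified_piecewise_values(self):
        pol = EtaPolicy.modified(eta0=0.01, H0=5, Hc=25)
        assert eta_of_H(0, pol) == 0.01
        assert eta_of_H(5, pol) == 0.01  # continuous at the knee
        assert eta_of_H(25, pol) == 0.0
        assert eta_of_H(100, pol) == 0.0
        # interior point: eta0 * sqrt(1 - ((15-5)/(25-5))^2) = 0.01*sqrt(0.75)
        assert eta_of_H(15, pol) == pytest.approx(0.0086603, abs=1e-6)

    def test_continuous_and_nonincreasing(self):
        pol = EtaPolicy.modified(eta0=0.01, H0=5, Hc=25)
        H = np.linspace(0, 40, 4001)
        eta = eta_of_H(H, pol)
        assert np.all(np.diff(eta) <= 1e-12)
        assert np.max(np.abs(np.diff(eta))) < 1e-3  # no jumps on a dense grid

    def test_modified_requires_Hc(self):
        with pytest.raises(ConfigurationError, match="Hc"):
            EtaPolicy(mode="modified", Hc=None).validate()


class TestHebbianRule:
    def test_truth_table_with_reference_constants(self):
        params = ThreeLayerParams()
        eta = 0.01
        assert hebbian_delta(1, 1, eta, params) == pytest.approx(+0.005)
        assert hebbian_delta(1, 0, eta, params) == pytest.approx(-0.005)
        assert hebbian_delta(0, 1, eta, params) == pytest.approx(-0.005)
        assert hebbian_delta(0, 0, eta, params) == 0.0


class TestTrainStep:
    def test_no_update_when_output_correct(self, scaled_params, fixed_eta, rng):
        state = build_network(scaled_params, seed=0)
        # force a trivially correct configuration: desired all zero, zero W_mo
        state.W_mo[:, :] = 0.0
        state.desired_output[:] = 0
        W_im_before = state.W_im.copy()
        _, H = train_step(state, scaled_params, fixed_eta, rng)
        assert H == 0
        np.testing.assert_array_equal(state.W_im, W_im_before)

    def test_zero_eta_freezes_weights(self, scaled_params, rng):
        pol = EtaPolicy.modified(H0=1, Hc=2)
        state = build_network(scaled_params, seed=0)
        state.W_mo[:, :] = 0.0
        state.desired_output[:] = 1  # H = 100 >= Hc -> eta = 0
        W_before = state.W_mo.copy()
        _, H = train_step(state, scaled_params, pol, rng)
        assert H == state.N
        np.testing.assert_array_equal(state.W_mo, W_before)

    def test_weights_stay_bounded_along_trajectory(self, scaled_params, fixed_eta):
        gen = np.random.default_rng(7)
        state = build_network(scaled_params, gen)
        for _ in range(300):
            train_step(state, scaled_params, fixed_eta, gen)
            for W in (state.W_im, state.W_mo):
                assert W.min() >= scaled_params.w_min
                assert W.max() <= scaled_params.w_max
                assert np.all(W[~state.mask] == 0.0)

    def test_training_reduces_disability(self, scaled_params, fixed_eta):
        # learning must not be systematically worse than chance
        improved = 0
        for seed in range(20):
            gen = np.random.default_rng(seed)
            state = build_network(scaled_params, gen)
            _, H_first = train_step(state, scaled_params, fixed_eta, gen)
            H_last = H_first
            for _ in range(299):
                _, H_last = train_step(state, scaled_params, fixed_eta, gen)
            improved += H_last <= H_first
        assert improved >= 18  # >= 90% of 20 seeds

    def test_pre_lesion_train_composition(self, scaled_params, fixed_eta):
        gen = np.random.default_rng(5)
        s1 = build_network(scaled_params, gen)
        pre_lesion_train(s1, scaled_params, fixed_eta, 120, gen)

        gen = np.random.default_rng(5)
        s2 = build_network(scaled_params, gen)
        pre_lesion_train(s2, scaled_params, fixed_eta, 50, gen)
        pre_lesion_train(s2, scaled_params, fixed_eta, 70, gen)

        np.testing.assert_array_equal(s1.W_im, s2.W_im)
        np.testing.assert_array_equal(s1.W_mo, s2.W_mo)
        assert s1.t == s2.t == 120

    def test_zero_duration_is_identity(self, scaled_params, fixed_eta, rng):
        state = build_network(scaled_params, seed=0)
        W = state.W_im.copy()
        pre_lesion_train(state, scaled_params, fixed_eta, 0, rng)
        np.testing.assert_array_equal(state.W_im, W)
        assert state.t == 0
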