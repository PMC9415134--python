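"""Contribution degrees, thresholds, neuron split/merge, and the adaptation loop."""

import numpy as np
import pytest

from conftest import make_instance
from ospelm.adapt import (
    AdaptationConfig,
    adapt_step,
    compute_thresholds,
    contribution_degrees,
    merge_neurons,
    resize_F,
    split_neuron,
)
from ospelm.exceptions import ConfigurationError, DomainError
from ospelm.network import NetworkConfig, OSPELMState, design_matrix, init_batch, predict
from ospelm.online import os_update
from ospelm.preprocessing import FeatureGrouping


def _state(z1=3, z2=2, h="identity", g="identity", seed=0, b_zero=False):
    rng = np.random.default_rng(seed)
    st = OSPELMState(
        rho=rng.normal(size=(z1, 5)),
        phi=rng.normal(size=(z2, 5)),
        b1=np.zeros(z1) if b_zero else rng.normal(size=z1),
        b2=np.zeros(z2) if b_zero else rng.normal(size=z2),
        beta1=rng.normal(size=(z1, 1)),
        beta2=rng.normal(size=(z2, 1)),
        omega=rng.normal(size=(5, 1)),
        h_id=h,
        g_id=g,
        f_id="identity",
        F=None,
        grouping=FeatureGrouping(),
    )
    return st


class TestContributionDegrees:
    def test_single_neuron_full_attribution(self):
        st = _state(z1=1, z2=1)
        st.beta2[:] = 0.0
        st.omega[:] = 0.0
        X = np.random.default_rng(1).uniform(0.2, 1, (10, 5))
        rep = contribution_degrees(st, X)
        np.testing.assert_allclose(rep.layer1_signed.sum(), 1.0, rtol=1e-12)
        np.testing.assert_allclose(rep.layer1, [1.0], rtol=1e-12)

    def test_signed_degrees_sum_to_stream_share(self):
        st = _state(z1=4, z2=3, seed=3)
        X = np.random.default_rng(2).uniform(0, 1, (25, 5))
        rep = contribution_degrees(st, X)
        np.testing.assert_allclose(rep.layer1_signed.sum(), rep.stream_shares[0], rtol=1e-10)
        np.testing.assert_allclose(rep.layer2_signed.sum(), rep.stream_shares[1], rtol=1e-10)
        np.testing.assert_allclose(rep.stream_shares.sum(), 1.0, rtol=1e-10)

    def test_hand_arithmetic_two_neurons(self):
        st = _state(z1=2, z2=1, b_zero=True)
        st.rho[:] = 0.0
        st.rho[0, 0] = 1.0   # neuron 1 outputs x0
        st.rho[1, 2] = 1.0   # neuron 2 outputs x2
        st.phi[:] = 0.0      # layer 2 silent
        st.beta1[:, 0] = [2.0, -1.0]
        st.beta2[:] = 0.0
        st.omega[:] = 0.0
        st.omega[3, 0] = 1.0
        x = np.array([[0.5, 0.0, 0.2, 0.3, 0.0]])
        # streams: y' = 2*0.5 - 1*0.2 = 0.8 ; y''=0 ; y'''=0.3 ; s=1.1
        rep = contribution_degrees(st, x)
        np.testing.assert_allclose(rep.layer1, [1.0 / 1.1, 0.2 / 1.1], rtol=1e-12)
        np.testing.assert_allclose(rep.stream_shares, [0.8 / 1.1, 0.0, 0.3 / 1.1], rtol=1e-12)

    def test_zero_stream_sum_samples_excluded(self):
        st = _state(z1=1, z2=1)
        st.beta1[:] = 0.0
        st.beta2[:] = 0.0
        st.omega[:] = 0.0
        st.omega[0, 0] = 1.0
        X = np.vstack([np.zeros(5), np.ones(5)])  # first sample: s = 0
        rep = contribution_degrees(st, X)
        assert rep.n_excluded == 1
        assert rep.n_samples == 1


class TestThresholds:
    def test_constant_degrees_double_mean(self):
        st = _state(z1=1, z2=1)
        X = np.random.default_rng(0).uniform(0.1, 1, (8, 5))
        rep = contribution_degrees(st, X)
        c_hth, _ = compute_thresholds(rep, 10, 18, AdaptationConfig())
        mean = np.concatenate([rep.layer1, rep.layer2]).mean()
        assert c_hth == pytest.approx(2 * mean)

    def test_low_threshold_reference_sizes(self):
        st = _state()
        rep = contribution_degrees(st, np.random.default_rng(1).uniform(0.1, 1, (5, 5)))
        # 1/(10+18) < 0.05 -> reciprocal branch, independently 1/28 = 0.03571...
        _, c_lth = compute_thresholds(rep, 10, 18, AdaptationConfig())
        assert c_lth == pytest.approx(1.0 / 28.0)
        _, c_lth_small = compute_thresholds(rep, 5, 5, AdaptationConfig())
        assert c_lth_small == pytest.approx(0.05)


class TestSplit:
    def test_zero_bias_identity_preserves_output_exactly(self):
        st = _state(b_zero=True)
        X = np.random.default_rng(5).uniform(0, 1, (20, 5))
        before = predict(st, X)
        st2 = split_neuron(st, 1, 0, AdaptationConfig())
        after = predict(st2, X)
        np.testing.assert_allclose(after, before, rtol=1e-12)
        assert st2.z1 == st.z1 + 1

    def test_children_inherit_input_weights(self):
        st = _state()
        st2 = split_neuron(st, 2, 1, AdaptationConfig())
        np.testing.assert_array_equal(st2.phi[1], st.phi[1])
        np.testing.assert_array_equal(st2.phi[2], st.phi[1])

    def test_children_betas_and_biases_sum_to_parent(self):
        st = _state()
        om = 0.3
        st2 = split_neuron(st, 1, 0, AdaptationConfig(omega_factor=om))
        assert st2.beta1[0, 0] + st2.beta1[1, 0] == pytest.approx(st.beta1[0, 0], rel=1e-12)
        assert st2.b1[0] + st2.b1[1] == pytest.approx(st.b1[0], rel=1e-12)
        assert st2.beta1[0, 0] == pytest.approx(om * st.beta1[0, 0], rel=1e-12)

    def test_skipped_at_max_size(self):
        st = _state(z1=3)
        cfg = AdaptationConfig(max_neurons_per_layer=3)
        st2 = split_neuron(st, 1, 0, cfg)
        assert st2.z1 == 3

    def test_missing_neuron_rejected(self):
        with pytest.raises(DomainError):
            split_neuron(_state(), 1, 99, AdaptationConfig())


class TestMerge:
    def _report(self, st, seed=0):
        return contribution_degrees(st, np.random.default_rng(seed).uniform(0.1, 1, (15, 5)))

    def test_cardinality_decreases_by_one(self):
        st = _state(z1=4, z2=3)
        st2 = merge_neurons(st, 1, 0, 2, self._report(st))
        assert st2.z1 == 3
        assert st2.z2 == st.z2

    def test_contribution_conserved_at_operating_point(self):
        st = _state(z1=4, z2=3)
        rep = self._report(st)
        st2 = merge_neurons(st, 1, 0, 2, rep)
        lhs = st2.beta1[0, 0] * rep.lambda1[0]
        rhs = st.beta1[0, 0] * rep.lambda1[0] + st.beta1[2, 0] * rep.lambda1[2]
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_lambda_delete_leaves_survivor(self):
        st = _state(z1=3, z2=2, h="relu")
        st.rho[2] = -1.0  # dead ReLU on positive inputs
        st.b1[2] = -5.0
        rep = self._report(st)
        assert rep.lambda1[2] == 0.0
        st2 = merge_neurons(st, 1, 0, 2, rep)
        assert st2.beta1[0, 0] == st.beta1[0, 0]

    def test_identical_indices_rejected(self):
        st = _state()
        with pytest.raises(DomainError):
            merge_neurons(st, 1, 1, 1, self._report(st))


class TestResizeF:
    def test_matches_plain_window_computation(self):
        st = _state(seed=2)
        X = np.random.default_rng(3).uniform(0, 1, (30, 5))
        st2 = resize_F(st, X, epsilon=1e-6)
        A = design_matrix(st, X)
        M = A.T @ A
        eps_eff = 1e-6 * np.trace(M) / M.shape[0]
        expected = np.linalg.inv(M + eps_eff * np.eye(M.shape[0]))
        expected = 0.5 * (expected + expected.T)  # stored F is symmetrized
        np.testing.assert_allclose(st2.F, expected, rtol=1e-8)

    def test_spd_and_shape(self):
        st = _state(z1=6, z2=4)
        st2 = resize_F(st, np.random.default_rng(4).uniform(0, 1, (12, 5)))
        assert st2.F.shape == (st2.n_params, st2.n_params)
        assert np.linalg.eigvalsh(st2.F).min() > 0

    def test_empty_window_rejected(self):
        with pytest.raises(DomainError):
            resize_F(_state(), np.empty((0, 5)))


class TestAdaptStep:
    def _initialized(self, seed=0):
        X, Y = make_instance(seed, n=300)
        st = init_batch(X[:200], Y[:200], NetworkConfig(z1=6, z2=6), rng_seed=seed, eps=1e-8)
        return st, X, Y

    def test_caps_zero_reduces_to_plain_update_bitwise(self):
        st, X, Y = self._initialized(1)
        cfg = AdaptationConfig(max_splits_per_step=0, max_merges_per_step=0)
        a, log = adapt_step(st, X[200:240], Y[200:240], cfg)
        b = os_update(st, X[200:240], Y[200:240])
        np.testing.assert_array_equal(a.stacked_beta, b.stacked_beta)
        np.testing.assert_array_equal(a.F, b.F)
        assert log["actions"] == []

    def test_planted_dominant_neuron_splits_once(self):
        st, X, Y = self._initialized(2)
        # one always-active neuron carries essentially the whole output
        st.h_id = "leaky_relu"
        st.beta1[:, 0] = 0.01
        st.beta1[0, 0] = 100.0
        st.beta2[:] = 0.0
        st.omega[:] = 0.0
        # zero-innovation chunk so the RLS update preserves the planted weights
        Xk = X[200:240]
        Yk = design_matrix(st, Xk) @ st.stacked_beta
        cfg = AdaptationConfig(max_merges_per_step=0)
        st2, log = adapt_step(st, Xk, Yk, cfg)
        splits = [a for a in log["actions"] if a["action"] == "split"]
        assert len(splits) == 1
        assert st2.z1 == st.z1 + 1

    def test_no_trigger_leaves_structure(self):
        st, X, Y = self._initialized(3)
        # impossible thresholds: enormous split bar, tiny merge bar
        cfg = AdaptationConfig(c_hth_multiplier=1e9, c_lth_floor=1e-12)
        st2, log = adapt_step(st, X[200:240], Y[200:240], cfg)
        assert (st2.z1, st2.z2) == (st.z1, st.z2)
        assert log["actions"] == []

    def test_layer_sizes_respect_bounds_over_many_steps(self):
        st, X, Y = self._initialized(4)
        cfg = AdaptationConfig(max_neurons_per_layer=8, min_neurons_per_layer=3)
        rng = np.random.default_rng(0)
        for _ in range(12):
            Xk = rng.uniform(-2, 2, (30, 5))
            Yk = rng.normal(size=(30, 1))
            z_before = (st.z1, st.z2)
            st, _ = adapt_step(st, Xk, Yk, cfg)
            assert 3 <= st.z1 <= 8 and 3 <= st.z2 <= 8
            assert abs(st.z1 - z_before[0]) + abs(st.z2 - z_before[1]) <= 2

    def test_deterministic(self):
        st, X, Y = self._initialized(5)
        cfg = AdaptationConfig()
        a, _ = adapt_step(st, X[200:260], Y[200:260], cfg)
        b, _ = adapt_step(st, X[200:260], Y[200:260], cfg)
        np.testing.assert_array_equal(a.stacked_beta, b.stacked_beta)
        assert (a.z1, a.z2) == (b.z1, b.z2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            AdaptationConfig(omega_factor=0.0)
        with pytest.raises(ConfigurationError):
            AdaptationConfig(max_neurons_per_layer=1, min_neurons_per_layer=2)
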