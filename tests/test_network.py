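"""Network data model: invariants, manipulations, coding conversion, star embedding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emonet as em
from emonet.network import NetworkValidationError, InvalidParameterError


def _random_net(seed, n=5):
    return em.random_network(n, seed=seed)


class TestValidation:
    def test_asymmetric_weights_rejected(self):
        w = np.array([[0.0, 0.3], [0.301, 0.0]])
        with pytest.raises(NetworkValidationError, match="symmetric"):
            em.ComponentNetwork(("a", "b"), w, np.zeros(2))

    def test_nonzero_diagonal_rejected(self):
        w = np.array([[0.1, 0.0], [0.0, 0.0]])
        with pytest.raises(NetworkValidationError, match="diagonal"):
            em.ComponentNetwork(("a", "b"), w, np.zeros(2))

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_entries_rejected(self, bad):
        w = np.array([[0.0, bad], [bad, 0.0]])
        with pytest.raises(NetworkValidationError, match="finite"):
            em.ComponentNetwork(("a", "b"), w, np.zeros(2))
        with pytest.raises(NetworkValidationError, match="finite"):
            em.ComponentNetwork(("a", "b"), np.zeros((2, 2)), np.array([bad, 0.0]))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NetworkValidationError, match="unique"):
            em.ComponentNetwork(("a", "a"), np.zeros((2, 2)), np.zeros(2))

    def test_unknown_coding_rejected(self):
        with pytest.raises(NetworkValidationError, match="coding"):
            em.ComponentNetwork(("a",), np.zeros((1, 1)), np.zeros(1), coding="ordinal")

    def test_weights_are_immutable(self, three_node_net):
        with pytest.raises(ValueError):
            three_node_net.weights[0, 1] = 9.0


class TestManipulations:
    def test_scale_identity_and_annihilation(self, three_node_net):
        same = em.scale_connectivity(three_node_net, 1.0)
        np.testing.assert_array_equal(same.weights, three_node_net.weights)
        zero = em.scale_connectivity(three_node_net, 0.0)
        assert np.all(zero.weights == 0.0)
        np.testing.assert_array_equal(zero.thresholds, three_node_net.thresholds)

    def test_scale_elementwise(self, three_node_net):
        doubled = em.scale_connectivity(three_node_net, 2.0)
        assert doubled.weights[0, 1] == pytest.approx(0.8)
        assert doubled.weights[0, 2] == pytest.approx(0.4)
        assert doubled.weights[1, 2] == 0.0
        # input unmodified
        assert three_node_net.weights[0, 1] == pytest.approx(0.4)

    @pytest.mark.parametrize("factor", [-0.5, np.nan, np.inf])
    def test_scale_invalid_factor(self, three_node_net, factor):
        with pytest.raises(InvalidParameterError):
            em.scale_connectivity(three_node_net, factor)

    def test_shift_examples(self):
        net = em.ComponentNetwork(("a", "b"), np.zeros((2, 2)), np.array([-1.0, -0.5]))
        shifted = em.shift_thresholds(net, 0.5)
        np.testing.assert_allclose(shifted.thresholds, [-0.5, 0.0])
        np.testing.assert_array_equal(
            em.shift_thresholds(net, 0.0).thresholds, net.thresholds
        )
        sym = em.shift_thresholds(
            em.ComponentNetwork(("a", "b"), np.zeros((2, 2)), np.array([-0.7, -0.7])),
            0.7,
        )
        np.testing.assert_allclose(sym.thresholds, 0.0)

    def test_shift_invalid_constant(self, three_node_net):
        with pytest.raises(InvalidParameterError):
            em.shift_thresholds(three_node_net, np.inf)

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(0.0, 4.0), b=st.floats(0.0, 4.0), seed=st.integers(0, 50))
    def test_scaling_composes_multiplicatively(self, a, b, seed):
        net = _random_net(seed)
        once = em.scale_connectivity(net, a * b)
        twice = em.scale_connectivity(em.scale_connectivity(net, a), b)
        np.testing.assert_allclose(once.weights, twice.weights, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(-2.0, 2.0), b=st.floats(-2.0, 2.0), seed=st.integers(0, 50))
    def test_shifts_compose_additively(self, a, b, seed):
        net = _random_net(seed)
        once = em.shift_thresholds(net, a + b)
        twice = em.shift_thresholds(em.shift_thresholds(net, a), b)
        np.testing.assert_allclose(once.thresholds, twice.thresholds, atol=1e-12)


class TestCodingConversion:
    def test_zero_network_maps_to_zero(self):
        net = em.ComponentNetwork(("a", "b"), np.zeros((2, 2)), np.zeros(2), coding="binary")
        spin = em.convert_coding(net, "spin")
        assert np.all(spin.weights == 0) and np.all(spin.thresholds == 0)

    def test_two_node_formula(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = em.ComponentNetwork(("a", "b"), w, np.zeros(2), coding="binary")
        spin = em.convert_coding(net, "spin")
        assert spin.weights[0, 1] == pytest.approx(0.25)
        np.testing.assert_allclose(spin.thresholds, [0.25, 0.25])

    def test_same_coding_is_identity(self, three_node_net):
        assert em.convert_coding(three_node_net, "spin") is three_node_net

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 100))
    def test_involution_recovers_exactly(self, seed):
        net = _random_net(seed, n=6)
        back = em.convert_coding(em.convert_coding(net, "binary"), "spin")
        np.testing.assert_allclose(back.weights, net.weights, atol=1e-12)
        np.testing.assert_allclose(back.thresholds, net.thresholds, atol=1e-12)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_state_distribution_invariant_under_conversion(self, seed):
        net = em.random_network(6, seed=seed)
        before = em.exact_distribution(net)
        after = em.exact_distribution(em.convert_coding(net, "binary"))
        assert np.abs(before.probs - after.probs).max() < 1e-10


class TestCommonCause:
    def test_star_topology(self):
        model = em.build_common_cause(
            ["x", "y", "z"], [0.5, 0.5, 0.5], [-1.0, -1.0, -1.0], -1.0
        )
        star = em.star_network(model)
        assert star.n == 4
        iu = np.triu_indices(4, k=1)
        nonzero = np.count_nonzero(star.weights[iu])
        assert nonzero == 3  # exactly one edge per component, to the cause
        # zero coupling for every pair of components
        assert np.all(star.weights[:3, :3] == 0.0)
        np.testing.assert_allclose(star.thresholds, [-1, -1, -1, -1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            em.build_common_cause(["x", "y"], [0.5], [-1.0, -1.0], -1.0)

    def test_zero_loadings_decouple_components(self):
        """With all loadings 0 the components are independent biased spins."""
        model = em.build_common_cause(["x", "y", "z"], [0.0] * 3, [0.4] * 3, -1.0)
        star = em.star_network(model)
        dist = em.exact_distribution(star, beta=1.0)
        # marginal activation of each component: p = sigmoid(2*0.4)
        p = 1.0 / (1.0 + np.exp(-2 * 0.4))
        # project the 4-node distribution onto the 3 components by summing
        # over the cause node: component count is Binomial(3, p)
        from scipy.stats import binom

        from emonet.states import enumerate_spin_states, exact_state_distribution

        probs = exact_state_distribution(star)
        states = enumerate_spin_states(4)
        k = (states[:, :3] > 0).sum(axis=1)
        comp_dist = np.bincount(k, weights=probs, minlength=4)
        np.testing.assert_allclose(comp_dist, binom.pmf(np.arange(4), 3, p), atol=1e-10)
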