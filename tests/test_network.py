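"""Rate network: weight counting, forward pass, Jacobians, dropout."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import biohybrid as bh
from biohybrid.errors import ContractError


def layout(n_in, hidden, n_out, activation="tanh"):
    return bh.NetworkLayout(n_in, tuple(hidden), n_out, activation)


class TestCountWeights:
    @pytest.mark.parametrize(
        "n_in,hidden,n_out,expected",
        [
            (30, (17,), 30, 1067),
            (26, (12,), 25, 649),
            (1, (), 1, 2),
            (30, (20, 20, 20), 30, 2090),
            (26, (7, 7, 7), 25, 501),
            (26, (7,), 25, 389),
        ],
    )
    def test_published_architectures(self, n_in, hidden, n_out, expected):
        assert bh.count_weights(layout(n_in, hidden, n_out)) == expected

    @given(
        n_in=st.integers(1, 8),
        hidden=st.lists(st.integers(1, 6), max_size=3),
        n_out=st.integers(1, 8),
    )
    def test_matches_enumeration_of_parameters(self, n_in, hidden, n_out):
        lay = layout(n_in, hidden, n_out)
        w = bh.init_weights(lay, 0)
        assert bh.count_weights(lay) == sum(m.size for m in w.w) + sum(
            b.size for b in w.b
        )
        assert w.flatten().size == bh.count_weights(lay)


class TestNormalizeInputs:
    @pytest.fixture
    def species(self):
        return bh.SpeciesSet(("Xv", "A"), np.array([4.0, 2.0]))

    def test_cmax_maps_to_one_and_zero_to_zero(self, species):
        lay = layout(2, (3,), 2)
        assert bh.normalize_inputs(species.cmax, species, lay) == pytest.approx([1.0, 1.0])
        assert bh.normalize_inputs(np.zeros(2), species, lay) == pytest.approx([0.0, 0.0])

    def test_extras_appended_with_own_maximum(self, species):
        lay = bh.NetworkLayout(3, (3,), 2, "tanh", (bh.ExtraInput("volume", 2.0),))
        h0 = bh.normalize_inputs(species.cmax / 2, species, lay, {"volume": 1.6})
        assert h0 == pytest.approx([0.5, 0.5, 0.8])

    def test_missing_extra_is_contract_error(self, species):
        lay = bh.NetworkLayout(3, (3,), 2, "tanh", (bh.ExtraInput("volume", 2.0),))
        with pytest.raises(ContractError):
            bh.normalize_inputs(species.cmax, species, lay, {})

    def test_negative_concentrations_clamped(self, species):
        lay = layout(2, (3,), 2)
        h0 = bh.normalize_inputs(np.array([-1.0, 1.0]), species, lay)
        assert h0 == pytest.approx([0.0, 0.5])


class TestForward:
    def test_zero_weights_give_zero_output(self):
        lay = layout(3, (4,), 2)
        w = bh.NetworkWeights(
            [np.zeros((4, 3)), np.zeros((2, 4))], [np.zeros(4), np.zeros(2)]
        )
        assert bh.forward(lay, w, np.array([0.3, 0.5, 0.9])) == pytest.approx([0.0, 0.0])

    def test_single_hidden_node_hand_computed(self):
        """One tanh node: v = 2 * tanh(0.5)."""
        lay = layout(2, (1,), 1)
        w = bh.NetworkWeights(
            [np.array([[1.0, 0.0]]), np.array([[2.0]])],
            [np.zeros(1), np.zeros(1)],
        )
        v = bh.forward(lay, w, np.array([0.5, 0.0]))
        assert v[0] == pytest.approx(2 * np.tanh(0.5), abs=1e-12)

    def test_relu_all_negative_preactivations_yield_output_bias(self):
        lay = layout(2, (3,), 2, "relu")
        w = bh.NetworkWeights(
            [-np.ones((3, 2)), np.ones((2, 3))],
            [-np.ones(3), np.array([0.7, -0.2])],
        )
        v = bh.forward(lay, w, np.array([0.5, 0.5]))
        assert v == pytest.approx([0.7, -0.2])


class TestJacobians:
    @pytest.mark.parametrize("activation", ["tanh", "relu"])
    @pytest.mark.parametrize("seed", range(5))
    def test_input_jacobian_matches_central_differences(self, activation, seed):
        rng = np.random.default_rng(seed)
        lay = layout(4, (5, 3), 2, activation)
        w = bh.init_weights(lay, seed)
        w = bh.NetworkWeights([wi * 80 for wi in w.w], [bi * 80 for bi in w.b])
        h0 = rng.uniform(0.05, 1.0, 4)
        jac = bh.jacobian_wrt_inputs(lay, w, h0)
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            fd = (bh.forward(lay, w, h0 + e) - bh.forward(lay, w, h0 - e)) / (2 * h)
            assert np.allclose(jac[:, j], fd, rtol=1e-5, atol=1e-9)

    @pytest.mark.parametrize("activation", ["tanh", "relu"])
    @pytest.mark.parametrize("seed", range(5))
    def test_weight_jacobian_matches_central_differences(self, activation, seed):
        rng = np.random.default_rng(100 + seed)
        lay = layout(3, (4,), 2, activation)
        w = bh.init_weights(lay, seed)
        theta = w.flatten() * 60
        w = bh.NetworkWeights.unflatten(lay, theta)
        h0 = rng.uniform(0.05, 1.0, 3)
        jac = bh.jacobian_wrt_weights(lay, w, h0)
        h = 1e-6
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (
                bh.forward(lay, bh.NetworkWeights.unflatten(lay, tp), h0)
                - bh.forward(lay, bh.NetworkWeights.unflatten(lay, tm), h0)
            ) / (2 * h)
            assert np.allclose(jac[:, j], fd, rtol=1e-5, atol=1e-8)

    def test_affine_net_input_jacobian_is_weight_matrix(self):
        lay = layout(3, (), 2)
        w = bh.init_weights(lay, 1)
        jac = bh.jacobian_wrt_inputs(lay, w, np.array([0.1, 0.2, 0.3]))
        assert np.array_equal(jac, w.w[0])

    def test_output_bias_block_is_identity(self):
        lay = layout(3, (4,), 2)
        w = bh.init_weights(lay, 2)
        jac = bh.jacobian_wrt_weights(lay, w, np.array([0.1, 0.2, 0.3]))
        assert np.allclose(jac[:, -2:], np.eye(2))

    def test_zero_input_zero_bias_tanh_hidden_connection_columns_zero(self):
        lay = layout(2, (3,), 2)
        w = bh.init_weights(lay, 3)
        w.b[0][:] = 0.0
        jac = bh.jacobian_wrt_weights(lay, w, np.zeros(2))
        # first-layer connection block: tanh(0)=0 propagates a zero activation
        assert np.allclose(jac[:, : 3 * 2], 0.0)


class TestInitWeights:
    def test_deterministic_for_fixed_seed(self):
        lay = layout(5, (4,), 3)
        a, b = bh.init_weights(lay, 42), bh.init_weights(lay, 42)
        assert np.array_equal(a.flatten(), b.flatten())

    def test_support_and_moments(self):
        lay = layout(100, (100, 100, 100), 100)  # ~40k draws
        th = bh.init_weights(lay, 7).flatten()
        assert th.min() >= -0.01 and th.max() <= 0.01
        se = 0.01 / np.sqrt(3 * th.size)  # SE of the mean of U(-0.01, 0.01)
        assert abs(th.mean()) < 3 * se


class TestDropout:
    def test_pdrop_zero_keeps_everything(self):
        lay = layout(3, (4, 4), 2)
        mask = bh.sample_dropout_mask(lay, 0.0, np.random.default_rng(0))
        w = bh.init_weights(lay, 0)
        h0 = np.array([0.2, 0.4, 0.6])
        assert np.allclose(bh.forward(lay, w, h0, mask), bh.forward(lay, w, h0))

    def test_pdrop_one_rejected(self):
        lay = layout(3, (4,), 2)
        with pytest.raises(ContractError):
            bh.sample_dropout_mask(lay, 1.0, np.random.default_rng(0))

    def test_empirical_drop_fraction(self):
        lay = layout(3, (100,), 2)
        rng = np.random.default_rng(5)
        drops = [
            1.0 - bh.sample_dropout_mask(lay, 0.2, rng).keep[0].mean()
            for _ in range(100)
        ]  # 10^4 Bernoulli draws total
        se = np.sqrt(0.2 * 0.8 / 1e4)
        assert abs(np.mean(drops) - 0.2) < 3 * se

    def test_reproducible_for_fixed_rng(self):
        lay = layout(3, (6, 6), 2)
        m1 = bh.sample_dropout_mask(lay, 0.3, np.random.default_rng(9))
        m2 = bh.sample_dropout_mask(lay, 0.3, np.random.default_rng(9))
        for a, b in zip(m1.keep, m2.keep):
            assert np.array_equal(a, b)

    def test_inverted_dropout_unbiased_on_linear_path(self):
        """For a linear (identity-activation-free) path the mask expectation
        reproduces the maskless forward; empirically on a ReLU net with
        all-positive preactivations (exactly linear regime)."""
        lay = layout(2, (50,), 1, "relu")
        rng = np.random.default_rng(11)
        w = bh.NetworkWeights(
            [rng.uniform(0.1, 0.5, (50, 2)), rng.uniform(-0.3, 0.3, (1, 50))],
            [rng.uniform(0.1, 0.2, 50), np.zeros(1)],
        )
        h0 = np.array([0.8, 0.6])
        ref = bh.forward(lay, w, h0)[0]
        draws = np.array([
            bh.forward(lay, w, h0, bh.sample_dropout_mask(lay, 0.2, rng))[0]
            for _ in range(10_000)
        ])
        assert abs(draws.mean() - ref) < 3 * draws.std(ddof=1) / np.sqrt(draws.size)
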