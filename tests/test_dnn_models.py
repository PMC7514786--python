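import numpy as np
import pytest

from pulsegate.dnn_models import (
    ConfigurationError,
    S1Config,
    S2Config,
    _block_lengths,
    bgru_forward,
    build_s1,
    build_s2,
    conv_layer_forward,
    count_parameters,
    dense_sigmoid,
    global_max_pool,
    gru_forward,
    max_pool,
    min_input_length,
    predict,
    s1_param_count,
    s2_param_count,
)

from _oracles import (
    bgru_oracle_concat,
    conv_oracle,
    dense_sigmoid_oracle,
    global_max_pool_oracle,
    gru_oracle,
    max_pool_oracle,
    random_gru_params,
)


class TestConvLayer:
    def test_zero_input_zero_bias_gives_zero(self, rng):
        W = rng.standard_normal((2, 1, 3))
        out = conv_layer_forward(np.zeros((1, 12)), W, np.zeros(2))
        np.testing.assert_array_equal(out, 0.0)

    def test_valid_convolution_discards_first_lags(self, rng):
        out = conv_layer_forward(rng.standard_normal((1, 500)),
                                 rng.standard_normal((4, 1, 7)), np.zeros(4))
        assert out.shape == (4, 494)

    def test_matches_loop_oracle(self, rng):
        for _ in range(25):
            C, L = int(rng.integers(1, 4)), int(rng.integers(1, 5))
            M, N = int(rng.integers(1, 4)), int(rng.integers(5, 15))
            x = rng.standard_normal((C, N))
            W = rng.standard_normal((M, C, L))
            b = rng.standard_normal(M)
            np.testing.assert_allclose(conv_layer_forward(x, W, b),
                                       conv_oracle(x, W, b), rtol=1e-6)

    def test_input_shorter_than_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            conv_layer_forward(np.zeros((1, 2)), rng.standard_normal((1, 1, 3)),
                               np.zeros(1))


class TestPooling:
    def test_pairwise_max(self):
        np.testing.assert_array_equal(max_pool(np.array([[1., 3., 2., 0.]])),
                                      [[3., 2.]])

    def test_odd_length_remainder_dropped(self):
        np.testing.assert_array_equal(max_pool(np.full((1, 5), 5.0)),
                                      [[5., 5.]])

    def test_matches_window_oracle(self, rng):
        x = rng.standard_normal((3, 20))
        np.testing.assert_allclose(max_pool(x), max_pool_oracle(x), rtol=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((1, 1)))

    def test_global_max_constant_channels(self):
        x = np.tile(np.array([[1.5], [-2.0], [0.25]]), (1, 9))
        np.testing.assert_array_equal(global_max_pool(x), [1.5, -2.0, 0.25])

    def test_global_max_single_channel(self):
        np.testing.assert_array_equal(global_max_pool(np.array([[1., 5., 3.]])),
                                      [5.0])

    def test_global_max_matches_oracle_and_permutation_invariant(self, rng):
        x = rng.standard_normal((8, 25))
        v = global_max_pool(x)
        np.testing.assert_allclose(v, global_max_pool_oracle(x), rtol=1e-6)
        perm = rng.permutation(25)
        np.testing.assert_array_equal(global_max_pool(x[:, perm]), v)


class TestGru:
    def test_saturated_update_gate_freezes_zero_state(self, rng):
        p = random_gru_params(rng, units=3, channels=2)
        p.bz[:] = 50.0  # z -> 1 copies the (zero) initial state forever
        h = gru_forward(rng.standard_normal((2, 6)), p)
        np.testing.assert_allclose(h, 0.0, atol=1e-12)

    def test_all_zero_parameters_give_zero_state(self, rng):
        p = random_gru_params(rng, units=3, channels=2)
        for a in (p.Wz, p.Wr, p.W, p.Uz, p.Ur, p.U, p.bz, p.br, p.b):
            a[:] = 0.0
        h = gru_forward(rng.standard_normal((2, 6)), p)
        np.testing.assert_array_equal(h, 0.0)

    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_matches_scalar_oracle(self, rng, direction):
        for _ in range(10):
            p = random_gru_params(rng, units=3, channels=4)
            x = rng.standard_normal((4, 6))
            np.testing.assert_allclose(
                gru_forward(x, p, direction),
                gru_oracle(x, p, backward=(direction == "backward")),
                rtol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        p = random_gru_params(rng, units=3, channels=4)
        with pytest.raises(ValueError):
            gru_forward(rng.standard_normal((2, 6)), p)


class TestBgru:
    def test_output_is_two_theta(self, rng):
        p = random_gru_params(rng, units=6, channels=3)
        q = random_gru_params(rng, units=6, channels=3)
        assert bgru_forward(rng.standard_normal((3, 9)), p, q).size == 12

    def test_time_symmetric_input_shared_params(self, rng):
        p = random_gru_params(rng, units=4, channels=2)
        half = rng.standard_normal((2, 5))
        x = np.concatenate([half, half[:, ::-1]], axis=1)  # palindrome
        out = bgru_forward(x, p, p)
        np.testing.assert_allclose(out[:4], out[4:], rtol=1e-10)

    def test_matches_concatenated_oracles(self, rng):
        p = random_gru_params(rng, units=3, channels=4)
        q = random_gru_params(rng, units=3, channels=4)
        x = rng.standard_normal((4, 7))
        np.testing.assert_allclose(bgru_forward(x, p, q),
                                   bgru_oracle_concat(x, p, q), rtol=1e-6)


class TestDenseSigmoid:
    def test_zero_score_is_half(self):
        assert dense_sigmoid(np.zeros(3), np.ones(3), 0.0) == 0.5

    def test_saturation_clamped_inside_unit_interval(self):
        hi = dense_sigmoid(np.array([1.0]), np.array([1e4]), 0.0)
        lo = dense_sigmoid(np.array([1.0]), np.array([-1e4]), 0.0)
        assert 0.0 < lo < hi < 1.0

    def test_direct_value(self):
        # w.v + b = 0.5 - 0.5 + 0.1 = 0.1
        p = dense_sigmoid(np.array([1.0, 2.0]), np.array([0.5, -0.25]), 0.1)
        assert abs(p - 0.52498) < 1e-5

    def test_matches_oracle(self, rng):
        for _ in range(20):
            v, w = rng.standard_normal(5), rng.standard_normal(5)
            b = float(rng.standard_normal())
            np.testing.assert_allclose(dense_sigmoid(v, w, b),
                                       dense_sigmoid_oracle(v, w, b),
                                       rtol=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dense_sigmoid(np.zeros(3), np.zeros(4), 0.0)


class TestBuilders:
    def test_s1_reference_block_lengths(self):
        lengths = _block_lengths(500, n_blocks=4, kernel_len=7)
        assert lengths == [(494, 247), (241, 120), (114, 57), (51, 25)]

    def test_s2_reference_block_lengths(self):
        assert _block_lengths(500, 2, 6) == [(495, 247), (242, 121)]

    def test_degenerate_single_tap_kernel(self):
        model = build_s1(S1Config(1, 1, 1, 0.05), input_len=10)
        assert model.predict_proba(np.zeros((1, 10))).shape == (1,)

    def test_underflow_raises_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_s1(S1Config(5, 8, 8, 0.1), input_len=12)

    def test_s2_dense_input_dimension(self):
        model = build_s2(S2Config(1, 8, 5, 0.1, gru_units=4), input_len=500)
        assert model.layers[-1].w.size == 8  # 2 * theta

    def test_min_input_length_boundary(self):
        cfg = S1Config(3, 8, 6, 0.1)
        n_min = min_input_length(cfg)
        model = build_s1(cfg, input_len=n_min)
        assert model.predict_proba(np.zeros((1, n_min))).shape == (1,)
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((1, n_min - 1)))


class TestParameterCounts:
    def test_reference_architectures(self):
        assert s1_param_count(S1Config(4, 8, 7, 0.2)) == 1441
        assert s2_param_count(S2Config(2, 24, 6, 0.4, gru_units=6)) == 4777

    def test_minimal_s1(self):
        assert s1_param_count(S1Config(1, 1, 1, 0.05)) == 4

    @pytest.mark.parametrize("m", [8, 16, 24])
    @pytest.mark.parametrize("length", [5, 6, 7, 8])
    @pytest.mark.parametrize("lam", [1, 2, 3, 4, 5])
    def test_s1_closed_form_matches_enumeration(self, lam, m, length):
        cfg = S1Config(lam, m, length, 0.1)
        assert count_parameters(build_s1(cfg, 500)) == s1_param_count(cfg)

    @pytest.mark.parametrize("theta", [4, 5, 6, 7, 8])
    @pytest.mark.parametrize("lam,m,length", [(1, 8, 5), (2, 24, 6),
                                              (5, 16, 8), (3, 8, 7)])
    def test_s2_closed_form_matches_enumeration(self, lam, m, length, theta):
        cfg = S2Config(lam, m, length, 0.1, gru_units=theta)
        assert count_parameters(build_s2(cfg, 500)) == s2_param_count(cfg)


class TestPredict:
    def test_deterministic_with_dropout_off(self, rng):
        model = build_s1(S1Config(2, 8, 5, 0.3), 500, seed=4)
        x = rng.standard_normal(500)
        p1 = predict(model, x).p_pr
        p2 = predict(model, x).p_pr
        assert p1 == p2
        assert 0.0 < p1 < 1.0

    def test_label_threshold(self, rng):
        model = build_s1(S1Config(1, 4, 5, 0.1), 500, seed=0)
        pred = predict(model, rng.standard_normal(500))
        assert pred.label == ("PR" if pred.p_pr >= 0.5 else "PEA")

    def test_positive_homogeneity_with_zero_biases(self, rng):
        # ReLU conv stacks and max pools are positively homogeneous when all
        # biases are zero, so the pre-sigmoid score scales with the input.
        model = build_s1(S1Config(2, 4, 5, 0.0), 500, seed=1)
        x = rng.standard_normal((1, 500))
        s1 = model.forward_score(x)[0]
        s2 = model.forward_score(1.02 * x)[0]
        np.testing.assert_allclose(s2, 1.02 * s1, rtol=1e-9)

    def test_variable_input_length(self, rng):
        model = build_s2(S2Config(2, 8, 5, 0.1, gru_units=4), 500, seed=0)
        for n in (200, 350, 500):
            assert 0.0 < model.predict_proba(rng.standard_normal((1, n)))[0] < 1.0
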