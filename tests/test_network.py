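"""Perceptron: bias-energy law, forward/cost closed forms, gradient signs."""

import math

import numpy as np
import pytest

from anvn import network as nn
from anvn.data import make_synthetic, one_hot


def logistic_ref(z, slope=1.0):
    return 1.0 / (1.0 + math.exp(-slope * z))


class TestBiasEnergyLaw:
    @pytest.mark.parametrize("e, b", [(0.0, 1.0), (1.0, 0.0), (2.0, -1.0), (3.0, -1.0)])
    def test_values(self, e, b):
        assert nn.bias_from_energy(e) == pytest.approx(b)

    def test_continuous_at_saturation(self):
        eps = 1e-9
        assert nn.bias_from_energy(2.0 - eps) == pytest.approx(nn.bias_from_energy(2.0 + eps), abs=1e-8)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            nn.bias_from_energy(-0.1)

    def test_monotone_nonincreasing(self):
        e = np.linspace(0, 4, 200)
        b = nn.bias_from_energy(e)
        assert np.all(np.diff(b) <= 0)


class TestNormalization:
    @pytest.mark.parametrize(
        "row, expected",
        [([1.0, -1.0], [0.5, -0.5]), ([3.0, 1.0], [0.75, 0.25])],
    )
    def test_examples(self, row, expected):
        w = np.array([row])
        nn.normalize_input_weights(w)
        np.testing.assert_allclose(w[0], expected)

    def test_idempotent(self):
        w = np.array([[0.6, -0.4]])
        nn.normalize_input_weights(w)
        np.testing.assert_allclose(w[0], [0.6, -0.4])

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            nn.normalize_input_weights(np.array([[0.0, 0.0]]))


def _toy_111(w=1.0, slope_hidden=4.0):
    return nn.MLPParams(
        w_in=np.array([[w]]), w_out=np.array([[1.0]]), b_out=np.zeros(1),
        slope_hidden=slope_hidden,
    )


class TestForward:
    def test_toy_chain_of_logistics(self):
        # 1-1-1 net, W=1, b_s=0, E=1 (so hidden bias 0), x=0.4
        params = _toy_111()
        cache = nn.forward(np.array([0.4]), params, energies=np.array([1.0]))
        v = logistic_ref(0.4, slope=params.slope_hidden)
        assert cache.v[0, 0] == pytest.approx(v)
        assert cache.y[0, 0] == pytest.approx(logistic_ref(v, slope=params.slope_out))

    def test_zero_input_half_activation(self):
        rng = np.random.default_rng(0)
        params = nn.init_mlp(5, 4, 3, rng)
        cache = nn.forward(np.zeros(5), params, energies=np.ones(4))
        # E=1 -> bias 0 -> hidden net input 0 -> activation exactly 1/2
        np.testing.assert_allclose(cache.v, 0.5)
        expected = 1.0 / (1.0 + np.exp(-(params.w_out.sum(axis=1) * 0.5)))
        np.testing.assert_allclose(cache.y[0], expected)

    def test_energy_shifts_net_input_linearly(self):
        params = _toy_111()
        h_e1 = nn.forward(np.array([0.2]), params, np.array([1.0])).h_hidden[0, 0]
        h_e0 = nn.forward(np.array([0.2]), params, np.array([0.0])).h_hidden[0, 0]
        assert h_e0 == pytest.approx(h_e1 - 1.0)

    def test_activation_nondecreasing_in_energy(self):
        params = _toy_111()
        v = [nn.forward(np.array([0.3]), params, np.array([e])).v[0, 0]
             for e in np.linspace(0, 3, 40)]
        assert np.all(np.diff(v) >= 0)

    def test_dimension_mismatch_rejected(self):
        params = _toy_111()
        with pytest.raises(ValueError):
            nn.forward(np.zeros(2), params, np.array([1.0]))
        with pytest.raises(ValueError):
            nn.forward(np.zeros(1), params, np.array([1.0, 1.0]))


class TestCost:
    def test_zero_iff_exact(self):
        assert nn.cost(np.array([0.2, 0.8]), np.array([0.2, 0.8])) == 0.0
        assert nn.cost(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]])) == pytest.approx(0.5)

    def test_weight_penalty(self):
        params = nn.MLPParams(
            w_in=np.array([[0.0]]), w_out=np.array([[2.0]]), b_out=np.zeros(1),
            lam_w=0.1,
        )
        y = d = np.array([[0.3]])
        assert nn.cost(y, d, params) == pytest.approx(0.2)

    def test_energy_penalty(self):
        params = _toy_111()
        params.lam_e = 0.5
        y = d = np.array([[0.3]])
        assert nn.cost(y, d, params, energies=np.array([1.5])) == pytest.approx(0.75)


class TestBackward:
    def test_exact_fit_gives_zero_updates(self):
        params = _toy_111()
        x = np.array([0.4])
        cache = nn.forward(x, params, np.array([1.0]))
        upd = nn.backward(cache, x, cache.y, params, np.array([1.0]))
        assert np.all(upd.dw_out == 0) and np.all(upd.dw_in == 0)
        assert np.all(upd.db_out == 0) and np.all(upd.d_energy == 0)

    def test_saturated_neuron_demands_nothing(self):
        params = _toy_111()
        x, d = np.array([0.4]), np.array([[1.0]])
        cache = nn.forward(x, params, np.array([2.5]))
        upd = nn.backward(cache, x, d, params, np.array([2.5]))
        assert upd.d_energy[0] == 0.0

    def test_reservoir_return_gradient_above_saturation(self):
        grad = nn.energy_gradient(np.array([0.4, 0.4]), np.array([1.0, 2.4]),
                                  eta=0.1, reservoir=True, gamma=0.005)
        assert grad[0] == pytest.approx(0.04)
        assert grad[1] == pytest.approx(-0.005)

    @pytest.mark.parametrize("lam_w, lam_e", [(0.0, 0.0), (0.05, 0.0), (0.0, 0.02), (0.03, 0.01)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradients_match_finite_differences(self, fd_oracle, lam_w, lam_e, seed):
        rng = np.random.default_rng(seed)
        params = nn.init_mlp(3, 3, 2, rng, lam_w=lam_w, lam_e=lam_e)
        x = rng.uniform(0, 1, 3)
        d = rng.uniform(0, 1, 2)
        energies = rng.uniform(0.1, 1.9, 3)   # linear branch of the bias law
        cache = nn.forward(x, params, energies)
        upd = nn.backward(cache, x, np.atleast_2d(d), params, energies)
        ref = fd_oracle(params, x, np.atleast_2d(d), energies)
        np.testing.assert_allclose(upd.dw_out, ref["dw_out"], rtol=1e-4, atol=1e-10)
        np.testing.assert_allclose(upd.db_out, ref["db_out"], rtol=1e-4, atol=1e-10)
        np.testing.assert_allclose(upd.dw_in, ref["dw_in"], rtol=1e-4, atol=1e-10)
        np.testing.assert_allclose(upd.d_energy, ref["d_energy"], rtol=1e-4, atol=1e-10)

    def test_free_bias_gradient_matches_energy_route(self):
        # standalone bias update -eta*delta equals the energy demand eta*delta
        # flipped in sign: the bias law has slope -1 on its linear branch
        rng = np.random.default_rng(3)
        params = nn.init_mlp(4, 3, 2, rng, standalone=True)
        params.b_hidden = np.array([0.3, -0.2, 0.6])
        x = rng.uniform(0, 1, 4)
        d = np.atleast_2d(rng.uniform(0, 1, 2))
        energies = 1.0 - params.b_hidden      # same biases via the energy law
        cache_free = nn.forward(x, params)
        upd_free = nn.backward(cache_free, x, d, params)
        cache_e = nn.forward(x, params, energies)
        upd_e = nn.backward(cache_e, x, d, params, energies)
        np.testing.assert_allclose(upd_free.db_hidden, -upd_e.d_energy, rtol=1e-12)


class TestPredict:
    def test_one_hot_position(self):
        y = np.zeros(10)
        y[3] = 1.0
        assert nn.predict_class(y)[0] == 3

    def test_ties_break_low(self):
        assert nn.predict_class(np.array([0.5, 0.5, 0.1]))[0] == 0
        assert nn.predict_class(np.full(10, 0.1))[0] == 0


def test_one_full_batch_update_does_not_increase_cost():
    """A small step along the analytic gradient lowers the quadratic cost
    on a fixed toy problem, across seeds."""
    improved = 0
    for seed in range(6):
        ds = make_synthetic(n_train=40, n_test=10, n_features=16, seed=seed)
        rng = np.random.default_rng(seed)
        params = nn.init_mlp(16, 6, 10, rng, standalone=True, eta=0.05)
        d = one_hot(ds.y_train, 10)
        before = nn.cost(nn.forward(ds.x_train, params).y, d)
        upd = nn.backward(nn.forward(ds.x_train, params), ds.x_train, d, params)
        nn.apply_update(params, upd, renormalize=False)
        after = nn.cost(nn.forward(ds.x_train, params).y, d)
        improved += after <= before + 1e-12
    assert improved >= 5


def test_params_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    params = nn.init_mlp(6, 4, 3, rng, standalone=True, lam_w=0.01)
    path = tmp_path / "mlp.json"
    nn.save_params(path, params)
    loaded = nn.load_params(path)
    np.testing.assert_array_equal(loaded.w_in, params.w_in)
    np.testing.assert_array_equal(loaded.w_out, params.w_out)
    np.testing.assert_array_equal(loaded.b_hidden, params.b_hidden)
    assert loaded.lam_w == params.lam_w
    assert loaded.slope_hidden == params.slope_hidden
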