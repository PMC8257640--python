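"""Shared fixtures.

Heavy simulation products (regime comparison, attractor sweep, EECC and
transfer tables) are session-scoped so that each is computed once and
shared by every test that inspects it.  Scales follow the package's
scaled-down study conditions: 784-feature synthetic data, 500/200
splits, networks of 16-128 hidden neurons.
"""

from __future__ import annotations

import numpy as np
import pytest

from anvn import experiments, network as nn
from anvn.data import make_synthetic


# ---------------------------------------------------------------------------
# datasets

@pytest.fixture(scope="session")
def dataset():
    """The study-condition synthetic dataset (784 features, 500/200)."""
    return make_synthetic(seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature dataset for fast unit tests of the training plumbing."""
    return make_synthetic(n_train=80, n_test=40, n_features=64, seed=3)


# ---------------------------------------------------------------------------
# finite-difference gradient oracle

def finite_difference_updates(params: nn.MLPParams, x, d, energies, step=1e-6):
    """Independent central-difference gradients of the cost.

    Returns the update increments (-eta * dC/dtheta) that the analytic
    backward pass should produce, obtained purely by perturbing the cost.
    """
    def eval_cost():
        cache = nn.forward(x, params, energies)
        return nn.cost(cache.y, d, params, energies)

    def fd_array(arr):
        out = np.empty_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + step
            c_plus = eval_cost()
            arr[idx] = orig - step
            c_minus = eval_cost()
            arr[idx] = orig
            out[idx] = (c_plus - c_minus) / (2 * step)
        return out

    grads = {
        "dw_out": -params.eta * fd_array(params.w_out),
        "db_out": -params.eta * fd_array(params.b_out),
        "dw_in": -params.eta * fd_array(params.w_in),
    }
    if energies is not None:
        grads["d_energy"] = -params.eta * fd_array(energies)
    return grads


@pytest.fixture(scope="session")
def fd_oracle():
    return finite_difference_updates


# ---------------------------------------------------------------------------
# heavy simulation products (session-scoped, computed once)

@pytest.fixture(scope="session")
def regime_df(dataset):
    """Three-regime efficiency sweep: 5 seeds, N=32, k=4, 2000 epochs."""
    return experiments.regime_compare(dataset, seeds=(0, 1, 2, 3, 4))


@pytest.fixture(scope="session")
def deficit_result(dataset):
    return experiments.deficit_sweep(dataset)


@pytest.fixture(scope="session")
def reservoir_grid(dataset):
    """Reservoir runs over sizes {16, 24, 128} x initial per-capita
    {0.2, 0.6, 1.0} x 3 seeds, with ablation scoring; shared by the
    attractor and energy-error correlation analyses."""
    return experiments.reservoir_grid_study(
        dataset, n_values=(16, 24, 128), per_capita_grid=(0.2, 0.6, 1.0),
        seeds=(0, 1, 2), score_ablation=True,
    )


@pytest.fixture(scope="session")
def attractor_df(reservoir_grid):
    return reservoir_grid[reservoir_grid.n_hidden.isin([24, 128])].copy()


@pytest.fixture(scope="session")
def eecc_df(reservoir_grid):
    sub = reservoir_grid[reservoir_grid.n_hidden.isin([16, 128])]
    return (
        sub.groupby(["n_hidden", "seed"]).agg(eecc=("eecc", "mean")).reset_index()
    )


@pytest.fixture(scope="session")
def transfer_df():
    return experiments.transfer_experiment(seeds=(0, 1, 2))
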