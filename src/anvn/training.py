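"""Training regimes coupling the perceptron to the vascular tree.

Four procedures are provided:

* ``train_standalone`` — plain perceptron training with free hidden
  biases; the result serves as the pre-trained net for the untrained and
  sequential vascular regimes.
* ``run_untrained`` — the tree is fixed to split the root energy equally
  among the leaves; only the resulting biases change with root energy.
* ``run_sequential`` — the perceptron is frozen; the tree learns to
  deliver energies whose derived biases approach the trained biases.
* ``run_simultaneous`` — perceptron and tree learn together each epoch:
  forward pass with energy-derived biases, backpropagation, neural
  updates, then the batch-averaged energy-demand gradient drives one
  vascular update.
* ``run_reservoir`` — the simultaneous scheme with a constant 5000-unit
  source split between the tree root (weight U_0) and a reservoir; leaves
  holding more than 2 units push back a small constant gradient -gamma so
  excess energy returns to the reservoir.

Neural and vascular updates use gradients averaged over a mini-batch
(default 25 samples, i.e. twenty interleaved neural + vascular updates
per epoch over the 500 training points); ``batch_size=None`` selects a single
full-batch update per epoch.  Mini-batching is what makes the scaled-down
epoch budgets converge: the original formulation relies on a very large
number of updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as nn
from . import tree as vt
from .data import Dataset, one_hot

__all__ = [
    "RegimeConfig",
    "TrainingTrace",
    "train_standalone",
    "evaluate_accuracy",
    "run_untrained",
    "run_sequential",
    "run_simultaneous",
    "run_reservoir",
]

RESERVOIR_SOURCE_ENERGY = 5000.0


@dataclass
class RegimeConfig:
    """Everything that determines one training run."""

    regime: str = "simultaneous"            # untrained | sequential | simultaneous | reservoir
    n_hidden: int = 32
    k: int = 4
    e_source: float | None = None           # root energy (non-reservoir regimes)
    per_capita0: float | None = None        # initial per-neuron energy (reservoir)
    epochs: int = 2000
    eta: float = 0.05
    eta_v: float = 0.01
    gamma: float = 0.005
    lam_w: float = 0.0
    lam_e: float = 0.0
    seed: int = 0
    eval_every: int = 50
    batch_size: int | None = 25

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrainingTrace:
    """Per-epoch log; test accuracy is evaluated every ``eval_every``
    epochs (and at the last epoch), NaN elsewhere."""

    xi: np.ndarray                 # total leaf energy per epoch
    per_capita: np.ndarray         # xi / n_hidden
    train_acc: np.ndarray          # percent
    test_acc: np.ndarray           # percent, sparse
    reservoir: np.ndarray | None = None   # reservoir energy (reservoir regime)

    def steady_state_per_capita(self, frac: float = 0.05) -> float:
        """Mean per-capita consumption over the final ``frac`` of epochs."""
        tail = max(1, int(round(frac * self.per_capita.size)))
        return float(self.per_capita[-tail:].mean())

    def final_test_acc(self) -> float:
        vals = self.test_acc[~np.isnan(self.test_acc)]
        return float(vals[-1])

    def to_frame(self) -> pd.DataFrame:
        d = {
            "epoch": np.arange(self.xi.size),
            "xi": self.xi,
            "per_capita": self.per_capita,
            "train_acc": self.train_acc,
            "test_acc": self.test_acc,
        }
        d["reservoir"] = self.reservoir if self.reservoir is not None else np.nan
        return pd.DataFrame(d)


def _accuracy_pct(y: np.ndarray, labels: np.ndarray) -> float:
    return 100.0 * float(np.mean(nn.predict_class(y) == labels))


def evaluate_accuracy(
    params: nn.MLPParams,
    x: np.ndarray,
    labels: np.ndarray,
    energies: np.ndarray | None = None,
) -> float:
    """Test accuracy (percent) of a net, with biases derived from
    ``energies`` when given."""
    cache = nn.forward(x, params, energies)
    return _accuracy_pct(cache.y, labels)


def _batches(n: int, batch_size: int | None, rng) -> list:
    if batch_size is None or batch_size >= n:
        return [slice(None)]
    perm = rng.permutation(n)
    return [perm[i : i + batch_size] for i in range(0, n, batch_size)]


def train_standalone(
    data: Dataset,
    n_hidden: int,
    epochs: int = 2000,
    eta: float = 0.05,
    seed: int = 0,
    lam_w: float = 0.0,
    renormalize: bool = True,
    batch_size: int | None = 25,
) -> nn.MLPParams:
    """Train a free-bias perceptron by mini-batch gradient descent."""
    rng = np.random.default_rng(seed)
    params = nn.init_mlp(
        data.n_features, n_hidden, data.n_classes, rng,
        standalone=True, eta=eta, lam_w=lam_w,
    )
    d = one_hot(data.y_train, data.n_classes)
    for _ in range(epochs):
        for idx in _batches(data.x_train.shape[0], batch_size, rng):
            xb, db = data.x_train[idx], d[idx]
            cache = nn.forward(xb, params)
            upd = nn.backward(cache, xb, db, params)
            nn.apply_update(params, upd, renormalize=renormalize)
    return params


def run_untrained(
    params: nn.MLPParams,
    topology: vt.TreeTopology,
    e_source_values,
    data: Dataset,
) -> pd.DataFrame:
    """Evaluate a pre-trained net through a fixed equal-split tree.

    Every leaf receives E_s / N; the trained biases are overridden by the
    bias-energy law.  Returns one row per root energy with the consumed
    energy and test accuracy.
    """
    state = vt.equal_split_weights(topology)
    rows = []
    for e_s in e_source_values:
        vt.propagate_energy(state, topology, e_s)
        energies = vt.leaf_energies(state, topology)
        acc = evaluate_accuracy(params, data.x_test, data.y_test, energies)
        rows.append({"e_source": e_s, "xi": float(energies.sum()), "test_acc": acc})
    return pd.DataFrame(rows)


def run_sequential(
    params: nn.MLPParams,
    topology: vt.TreeTopology,
    e_source: float,
    epochs: int = 2000,
    eta_v: float = 0.01,
    seed: int = 0,
    data: Dataset | None = None,
    eval_every: int = 200,
) -> tuple[vt.VascularState, TrainingTrace]:
    """Train only the tree against a frozen, pre-trained perceptron.

    The leaf energy-demand gradient is the (sign-flipped) gap between the
    trained bias and the energy-derived bias, dE_j = -(b_T - b_E), zeroed
    above the saturation branch where the bias no longer responds to
    energy; the bias-energy law has slope -1 on its linear branch, so this
    drives the delivered bias toward the trained one.
    """
    if params.b_hidden is None:
        raise ValueError("sequential training needs a pre-trained standalone net")
    b_trained = params.b_hidden
    state = vt.init_weights(topology, seed)
    n = topology.n_leaves
    xi = np.empty(epochs)
    train_acc = np.full(epochs, np.nan)
    test_acc = np.full(epochs, np.nan)
    for epoch in range(epochs):
        vt.propagate_energy(state, topology, e_source)
        energies = vt.leaf_energies(state, topology)
        b_energy = nn.bias_from_energy(energies)
        d_energy = np.where(energies <= 2.0, -(b_trained - b_energy), 0.0)
        vt.backpropagate_energy(state, topology, d_energy, eta_v)
        xi[epoch] = energies.sum()
        if data is not None and (epoch % eval_every == 0 or epoch == epochs - 1):
            test_acc[epoch] = evaluate_accuracy(params, data.x_test, data.y_test, energies)
    vt.propagate_energy(state, topology, e_source)
    return state, TrainingTrace(xi, xi / n, train_acc, test_acc)


def _simultaneous_loop(
    topology: vt.TreeTopology,
    state: vt.VascularState,
    data: Dataset,
    cfg: RegimeConfig,
    rng_seed,
    e_source: float | None,
    reservoir: bool,
    params: nn.MLPParams | None = None,
) -> tuple[nn.MLPParams, vt.VascularState, TrainingTrace]:
    if params is None:
        params = nn.init_mlp(
            data.n_features, topology.n_leaves, data.n_classes, rng_seed,
            eta=cfg.eta, lam_w=cfg.lam_w, lam_e=cfg.lam_e,
        )
    d = one_hot(data.y_train, data.n_classes)
    n = topology.n_leaves
    n_train = data.x_train.shape[0]
    rng = np.random.default_rng(rng_seed)
    epochs = cfg.epochs
    xi = np.empty(epochs)
    train_acc = np.empty(epochs)
    test_acc = np.full(epochs, np.nan)
    res = np.empty(epochs) if reservoir else None
    for epoch in range(epochs):
        correct = 0
        for idx in _batches(n_train, cfg.batch_size, rng):
            xb, db = data.x_train[idx], d[idx]
            vt.propagate_energy(state, topology, e_source)
            energies = vt.leaf_energies(state, topology)
            cache = nn.forward(xb, params, energies)
            correct += int(np.sum(nn.predict_class(cache.y) == data.y_train[idx]))
            upd = nn.backward(
                cache, xb, db, params, energies,
                reservoir=reservoir, gamma=cfg.gamma,
            )
            nn.apply_update(params, upd)
            vt.backpropagate_energy(state, topology, upd.d_energy, cfg.eta_v)
        vt.propagate_energy(state, topology, e_source)
        energies = vt.leaf_energies(state, topology)
        xi[epoch] = energies.sum()
        train_acc[epoch] = 100.0 * correct / n_train
        if res is not None:
            res[epoch] = state.reservoir_energy
        if epoch % cfg.eval_every == 0 or epoch == epochs - 1:
            test_acc[epoch] = evaluate_accuracy(params, data.x_test, data.y_test, energies)
    return params, state, TrainingTrace(xi, xi / n, train_acc, test_acc, res)


def run_simultaneous(
    topology: vt.TreeTopology,
    e_source: float,
    epochs: int,
    data: Dataset,
    *,
    eta: float = 0.05,
    eta_v: float = 0.01,
    lam_w: float = 0.0,
    lam_e: float = 0.0,
    seed: int = 0,
    eval_every: int = 50,
    batch_size: int | None = 25,
) -> tuple[nn.MLPParams, vt.VascularState, TrainingTrace]:
    """Train perceptron and tree together from scratch at fixed root
    energy.  The consumed energy equals the root energy at every epoch."""
    cfg = RegimeConfig(
        regime="simultaneous", n_hidden=topology.n_leaves, k=topology.k,
        e_source=e_source, epochs=epochs, eta=eta, eta_v=eta_v,
        lam_w=lam_w, lam_e=lam_e, seed=seed, eval_every=eval_every,
        batch_size=batch_size,
    )
    rng = np.random.default_rng(seed)
    state = vt.init_weights(topology, rng)
    return _simultaneous_loop(topology, state, data, cfg, rng, e_source, reservoir=False)


def run_reservoir(
    topology: vt.TreeTopology,
    per_capita0: float,
    epochs: int,
    data: Dataset,
    *,
    eta: float = 0.05,
    eta_v: float = 0.01,
    gamma: float = 0.005,
    lam_w: float = 0.0,
    lam_e: float = 0.0,
    seed: int = 0,
    eval_every: int = 50,
    batch_size: int | None = 25,
    source_energy: float = RESERVOIR_SOURCE_ENERGY,
    init_params: nn.MLPParams | None = None,
    init_state: vt.VascularState | None = None,
) -> tuple[nn.MLPParams, vt.VascularState, TrainingTrace]:
    """Simultaneous training against a constant source with a reservoir.

    The source (5000 units) splits between the tree root, weight
    U_0 = N * per_capita0 / source_energy initially, and the reservoir,
    weight 1 - U_0.  Leaves above 2 units of energy feed back the constant
    gradient -gamma, returning excess energy to the reservoir; the root
    gradient also moves U_0 itself.
    """
    u0 = topology.n_leaves * per_capita0 / source_energy
    if u0 > 1.0:
        raise ValueError(
            f"initial per-capita {per_capita0} implies source weight {u0:.3f} > 1"
        )
    cfg = RegimeConfig(
        regime="reservoir", n_hidden=topology.n_leaves, k=topology.k,
        per_capita0=per_capita0, epochs=epochs, eta=eta, eta_v=eta_v,
        gamma=gamma, lam_w=lam_w, lam_e=lam_e, seed=seed, eval_every=eval_every,
        batch_size=batch_size,
    )
    rng = np.random.default_rng(seed)
    if init_state is not None:
        state = init_state.copy()
    else:
        state = vt.init_weights(topology, rng)
        state.source_weight = float(u0)
    state.source_energy = float(source_energy)
    params = None if init_params is None else init_params.copy()
    return _simultaneous_loop(
        topology, state, data, cfg, rng, None, reservoir=True, params=params
    )
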