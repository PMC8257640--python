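"""Single-hidden-layer perceptron with energy-coupled hidden biases.

The hidden bias of neuron j is not a free parameter when the net is
coupled to a vascular tree: it is derived from the energy E_j delivered
to that neuron, b_j = 1 - E_j for 0 <= E_j <= 2 and b_j = -1 above 2
(more energy lowers the firing threshold, saturating once the neuron is
fully fuelled).  Biases enter the net input with a minus sign,
h = sum(W x) - b, and both layers use logistic activations g(z) = 1/(1 + exp(-slope z)).
The hidden slope defaults to 4 so that biases spanning [-1, 1] — the
range reachable through the bias-energy law against unit-normalized
input rows — genuinely gate a neuron on or off; the output slope stays 1.

Gradient quantities returned by :func:`backward` are *update increments*:
they already carry the learning rate and the descent sign, so a step is
``param += increment``.  The hidden-bias gradient is converted into an
energy-demand gradient dE_j = eta * delta_j on the linear branch of the
bias-energy law (zero above saturation), which the vascular tree consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MLPParams",
    "ForwardCache",
    "Updates",
    "logistic",
    "bias_from_energy",
    "normalize_input_weights",
    "init_mlp",
    "forward",
    "cost",
    "backward",
    "energy_gradient",
    "apply_update",
    "predict_class",
    "save_params",
    "load_params",
]


def logistic(z: np.ndarray) -> np.ndarray:
    # exp overflow for very negative z is benign: 1/(1+inf) == 0 exactly
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MLPParams:
    """Weights and hyper-parameters of the perceptron.

    ``b_hidden`` is only populated for a standalone (uncoupled) net; a
    coupled net derives hidden biases from leaf energies every pass.
    """

    w_in: np.ndarray          # (n_hidden, n_in), rows absolute-normalized
    w_out: np.ndarray         # (n_out, n_hidden)
    b_out: np.ndarray         # (n_out,)
    b_hidden: np.ndarray | None = None
    eta: float = 0.05
    lam_w: float = 0.0
    lam_e: float = 0.0
    slope_hidden: float = 4.0
    slope_out: float = 1.0

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[0]

    def copy(self) -> "MLPParams":
        return replace(
            self,
            w_in=self.w_in.copy(),
            w_out=self.w_out.copy(),
            b_out=self.b_out.copy(),
            b_hidden=None if self.b_hidden is None else self.b_hidden.copy(),
        )


@dataclass
class ForwardCache:
    h_hidden: np.ndarray   # net input to hidden layer, (m, n_hidden)
    v: np.ndarray          # hidden activations g1(h_hidden)
    h_out: np.ndarray      # net input to output layer, (m, n_out)
    y: np.ndarray          # outputs g2(h_out)


@dataclass
class Updates:
    dw_out: np.ndarray
    db_out: np.ndarray
    dw_in: np.ndarray
    d_energy: np.ndarray
    db_hidden: np.ndarray | None = None


def bias_from_energy(energy) -> np.ndarray:
    """Bias-energy law: b = 1 - E on [0, 2], saturating at -1 above 2."""
    e = np.asarray(energy, dtype=float)
    if np.any(e < 0):
        raise ValueError("leaf energies must be nonnegative")
    return np.where(e <= 2.0, 1.0 - e, -1.0)


def normalize_input_weights(w_in: np.ndarray) -> np.ndarray:
    """Scale each hidden row to unit absolute sum (in place)."""
    sums = np.abs(w_in).sum(axis=1)
    if np.any(sums == 0.0):
        raise ValueError("all-zero input-weight row cannot be normalized")
    w_in /= sums[:, None]
    return w_in


def init_mlp(
    n_in: int,
    n_hidden: int,
    n_out: int,
    rng,
    *,
    standalone: bool = False,
    eta: float = 0.05,
    lam_w: float = 0.0,
    lam_e: float = 0.0,
    slope_hidden: float = 4.0,
    slope_out: float = 1.0,
) -> MLPParams:
    """Random initialization: input rows uniform then normalized; output
    weights ~ N(0, 1); output biases zero.  A standalone net also draws
    free hidden biases uniform in [-1, 1] (the range reachable through
    the bias-energy law).

    The unit-scale output weights matter: the normalized input rows keep
    hidden net inputs within about [-1, 1], so smaller output weights
    leave the backpropagated hidden error too weak to escape the initial
    plateau within a realistic epoch budget."""
    rng = np.random.default_rng(rng)
    w_in = normalize_input_weights(rng.uniform(-1.0, 1.0, size=(n_hidden, n_in)))
    w_out = rng.normal(0.0, 1.0, size=(n_out, n_hidden))
    b_out = np.zeros(n_out)
    b_hidden = rng.uniform(-1.0, 1.0, size=n_hidden) if standalone else None
    return MLPParams(
        w_in=w_in, w_out=w_out, b_out=b_out, b_hidden=b_hidden,
        eta=eta, lam_w=lam_w, lam_e=lam_e,
        slope_hidden=slope_hidden, slope_out=slope_out,
    )


def _hidden_biases(params: MLPParams, energies: np.ndarray | None) -> np.ndarray:
    if energies is not None:
        return bias_from_energy(energies)
    if params.b_hidden is None:
        raise ValueError("either leaf energies or free hidden biases required")
    return params.b_hidden


def forward(x: np.ndarray, params: MLPParams, energies: np.ndarray | None = None) -> ForwardCache:
    """Forward pass for one sample (1-D x) or a batch (rows of x).

    Hidden biases come from ``energies`` through the bias-energy law, or
    from ``params.b_hidden`` for a standalone net; biases are subtracted
    from the weighted input sums.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.w_in.shape[1]:
        raise ValueError(f"input width {x.shape[1]} != {params.w_in.shape[1]}")
    b_hidden = _hidden_biases(params, energies)
    if b_hidden.shape[0] != params.n_hidden:
        raise ValueError("one energy/bias per hidden neuron required")
    h_hidden = x @ params.w_in.T - b_hidden
    v = logistic(params.slope_hidden * h_hidden)
    h_out = v @ params.w_out.T - params.b_out
    return ForwardCache(h_hidden=h_hidden, v=v, h_out=h_out,
                        y=logistic(params.slope_out * h_out))


def cost(
    y: np.ndarray,
    d: np.ndarray,
    params: MLPParams | None = None,
    energies: np.ndarray | None = None,
) -> float:
    """Quadratic cost C = 1/2 ||d - y||^2 (mean over batch rows), plus the
    optional L2 weight penalty lam_w/2 * sum(W^2) over both weight tables
    and the L1 energy penalty lam_e * sum|E|."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if y.shape != d.shape:
        raise ValueError("prediction/target shape mismatch")
    c = 0.5 * np.sum((d - y) ** 2) / y.shape[0]
    if params is not None and params.lam_w:
        c += 0.5 * params.lam_w * (np.sum(params.w_out**2) + np.sum(params.w_in**2))
    if params is not None and params.lam_e and energies is not None:
        c += params.lam_e * np.sum(np.abs(energies))
    return float(c)


def energy_gradient(
    delta_hidden_mean: np.ndarray,
    energies: np.ndarray,
    eta: float,
    *,
    lam_e: float = 0.0,
    reservoir: bool = False,
    gamma: float = 0.005,
) -> np.ndarray:
    """Convert the hidden error term into an energy-demand gradient.

    On the linear branch of the bias-energy law (0 <= E <= 2) the demand
    is dE = eta * delta (minus eta*lam_e under L1 energy regularization).
    Above saturation the demand is 0, or a constant -gamma when the
    network can return excess energy to a reservoir.
    """
    linear = energies <= 2.0
    above = eta * (delta_hidden_mean - lam_e) if lam_e else eta * delta_hidden_mean
    below = -gamma if reservoir else 0.0
    return np.where(linear, above, below)


def backward(
    cache: ForwardCache,
    x: np.ndarray,
    d: np.ndarray,
    params: MLPParams,
    energies: np.ndarray | None = None,
    *,
    reservoir: bool = False,
    gamma: float = 0.005,
) -> Updates:
    """Backpropagation; returns update increments averaged over the batch.

    Sign conventions follow h = sum(Wx) - b: with e = d - y,
    delta_out = e g2'(h_out), delta_hidden = (delta_out W_out) g1'(h_hidden),
    and the increments are dW_out = eta delta_out v, db_out = -eta delta_out,
    dW_in = eta delta_hidden x, dE = eta delta_hidden on the linear branch.
    With lam_w > 0 both weight increments gain -eta lam_w W.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = np.atleast_2d(np.asarray(d, dtype=float))
    m = x.shape[0]
    e = d - cache.y
    delta_out = e * params.slope_out * cache.y * (1.0 - cache.y)
    delta_hidden = (
        (delta_out @ params.w_out) * params.slope_hidden * cache.v * (1.0 - cache.v)
    )

    eta = params.eta
    dw_out = eta * (delta_out.T @ cache.v) / m
    dw_in = eta * (delta_hidden.T @ x) / m
    if params.lam_w:
        dw_out -= eta * params.lam_w * params.w_out
        dw_in -= eta * params.lam_w * params.w_in
    db_out = -eta * delta_out.mean(axis=0)
    delta_hidden_mean = delta_hidden.mean(axis=0)

    if energies is not None:
        d_energy = energy_gradient(
            delta_hidden_mean, np.asarray(energies, dtype=float), eta,
            lam_e=params.lam_e, reservoir=reservoir, gamma=gamma,
        )
    else:
        d_energy = eta * delta_hidden_mean
    db_hidden = -eta * delta_hidden_mean if params.b_hidden is not None else None
    return Updates(dw_out=dw_out, db_out=db_out, dw_in=dw_in,
                   d_energy=d_energy, db_hidden=db_hidden)


def apply_update(params: MLPParams, upd: Updates, *, renormalize: bool = True) -> MLPParams:
    """Take one gradient step in place; by default the input rows are
    re-normalized after every step, mirroring the vascular normalization."""
    params.w_out += upd.dw_out
    params.b_out += upd.db_out
    params.w_in += upd.dw_in
    if params.b_hidden is not None and upd.db_hidden is not None:
        params.b_hidden += upd.db_hidden
    if renormalize:
        normalize_input_weights(params.w_in)
    return params


def predict_class(y: np.ndarray) -> np.ndarray:
    """Class label = index of the maximal output (output i codes label i;
    one-hot targets put the 1 at the label's index).  Ties resolve to the
    lowest index."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    return np.argmax(y, axis=1)


def save_params(path, params: MLPParams) -> None:
    payload = {
        "w_in": params.w_in.tolist(),
        "w_out": params.w_out.tolist(),
        "b_out": params.b_out.tolist(),
        "b_hidden": None if params.b_hidden is None else params.b_hidden.tolist(),
        "eta": params.eta,
        "lam_w": params.lam_w,
        "lam_e": params.lam_e,
        "slope_hidden": params.slope_hidden,
        "slope_out": params.slope_out,
    }
    Path(path).write_text(json.dumps(payload))


def load_params(path) -> MLPParams:
    d = json.loads(Path(path).read_text())
    return MLPParams(
        w_in=np.asarray(d["w_in"], dtype=float),
        w_out=np.asarray(d["w_out"], dtype=float),
        b_out=np.asarray(d["b_out"], dtype=float),
        b_hidden=None if d["b_hidden"] is None else np.asarray(d["b_hidden"], dtype=float),
        eta=d["eta"], lam_w=d["lam_w"], lam_e=d["lam_e"],
        slope_hidden=d.get("slope_hidden", 4.0), slope_out=d.get("slope_out", 1.0),
    )
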