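"""Derived statistics: accuracy, energy efficiency, energy deficit,
transfer-learning weight drift, neuron-ablation error contribution, and
the energy-error correlation coefficient (EECC).

Conventions.  Accuracy is carried in percent inside the efficiency
ratios: this is the convention under which a network at ~80% accuracy and
100 units of consumed energy has an efficiency near 0.62.  The ablation
"RMSE" statistics are, as printed in the defining formulas, mean squared
errors without a root, and the per-level transfer drift is a plain sum of
squared weight differences; optionally-rooted variants are exposed under
explicit names.  All functions here are pure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import network as nn
from . import tree as vt
from .data import one_hot

__all__ = [
    "ZeroVarianceError",
    "EfficiencyRecord",
    "DeficitRecord",
    "AblationResult",
    "accuracy",
    "efficiency",
    "energy_deficit",
    "ablate_and_score",
    "transfer_drift",
    "transfer_drift_rooted",
    "attractor_spread",
]


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant input."""


@dataclass(frozen=True)
class EfficiencyRecord:
    alpha: float        # accuracy, percent
    alpha_baseline: float
    xi: float           # consumed energy
    psi: float          # efficiency


@dataclass(frozen=True)
class DeficitRecord:
    desired: float      # E_D = sum_j (1 - b_j), from trained biases only
    available: float    # E_A = sum of leaf energies
    deficit: float      # E_D - E_A (sign-indefinite)


@dataclass(frozen=True)
class AblationResult:
    mse_control: float
    mse_ablated: np.ndarray      # per switched-off neuron
    delta_mse: np.ndarray        # mse_ablated - mse_control
    energies: np.ndarray         # per-neuron consumed energy
    eecc: float                  # Pearson(delta_mse, energies)


def accuracy(predictions: np.ndarray, labels: np.ndarray, n_classes: int = 10) -> float:
    """Percent of correct class predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    for arr in (predictions, labels):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"label outside 0..{n_classes - 1}")
    return 100.0 * float(np.mean(predictions == labels))


def efficiency(alpha: float, alpha_baseline: float, xi: float) -> EfficiencyRecord:
    """psi = (alpha - alpha_baseline) / xi, accuracy in percent.

    The baseline is the accuracy at unit root energy for energy sweeps, or
    at the minimum network size for size sweeps.
    """
    if xi <= 0:
        raise ValueError(f"consumed energy must be positive, got {xi}")
    return EfficiencyRecord(alpha, alpha_baseline, xi, (alpha - alpha_baseline) / xi)


def energy_deficit(trained_biases: np.ndarray, leaf_energies: np.ndarray) -> DeficitRecord:
    """Desired energy sum_j (1 - b_j) from the trained biases, minus the
    energy actually available at the leaves."""
    trained_biases = np.asarray(trained_biases, dtype=float)
    leaf_energies = np.asarray(leaf_energies, dtype=float)
    if trained_biases.shape != leaf_energies.shape:
        raise ValueError("bias/energy length mismatch")
    desired = float(np.sum(1.0 - trained_biases))
    available = float(np.sum(leaf_energies))
    return DeficitRecord(desired, available, desired - available)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ZeroVarianceError("constant input: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def ablate_and_score(
    params: nn.MLPParams,
    leaf_energies: np.ndarray,
    x: np.ndarray,
    labels: np.ndarray,
    n_classes: int = 10,
) -> AblationResult:
    """Switch off each hidden neuron in turn and score the damage.

    The control error is the per-class mean squared prediction error
    against one-hot targets on the fixed test set; ablating neuron k
    forces its activation to zero before the output layer.  The EECC is
    the Pearson correlation between the per-neuron error increase and the
    per-neuron consumed energy; constant inputs raise
    :class:`ZeroVarianceError` rather than silently returning 0.
    """
    n_hidden = params.n_hidden
    if n_hidden < 3:
        raise ValueError("correlation undefined for fewer than 3 hidden neurons")
    d = one_hot(np.asarray(labels), n_classes)
    m, n_out = d.shape
    cache = nn.forward(x, params, leaf_energies)
    mse_control = float(np.sum((d - cache.y) ** 2) / (m * n_out))

    mse = np.empty(n_hidden)
    for k_off in range(n_hidden):
        # removing neuron k only subtracts its column from the output net input
        h_out = cache.h_out - np.outer(cache.v[:, k_off], params.w_out[:, k_off])
        y = nn.logistic(h_out)
        mse[k_off] = np.sum((d - y) ** 2) / (m * n_out)

    delta = mse - mse_control
    energies = np.asarray(leaf_energies, dtype=float)
    return AblationResult(mse_control, mse, delta, energies, _pearson(delta, energies))


def _per_level_sq(diff: np.ndarray, topology: vt.TreeTopology) -> pd.Series:
    # edge i (feeding node i) emerges from the node at level[parent[i]]
    parent_level = topology.level[topology.parent[1:]]
    sq = diff[1:] ** 2
    out = {}
    for lvl in range(1, topology.n_levels):
        out[lvl] = float(sq[parent_level == lvl].sum())
    return pd.Series(out, name="drift")


def transfer_drift(
    weights_a: np.ndarray | vt.VascularState,
    weights_b: np.ndarray | vt.VascularState,
    topology: vt.TreeTopology,
) -> pd.Series:
    """Per-level sum of squared weight differences between two trainings.

    Level l (root = 1) aggregates the branches emerging from its nodes;
    the leaf level has no outgoing branches, so levels run 1..L-1, with
    L-1 the leaf-adjacent (microvascular) level.
    """
    wa = weights_a.weights if isinstance(weights_a, vt.VascularState) else np.asarray(weights_a)
    wb = weights_b.weights if isinstance(weights_b, vt.VascularState) else np.asarray(weights_b)
    if wa.shape != (topology.n_nodes,) or wb.shape != (topology.n_nodes,):
        raise ValueError("weight vectors do not match the topology")
    return _per_level_sq(wa - wb, topology)


def transfer_drift_rooted(weights_a, weights_b, topology) -> pd.Series:
    """Root-mean-square variant of :func:`transfer_drift` (mean over the
    level's branches, then square root)."""
    drift = transfer_drift(weights_a, weights_b, topology)
    counts = pd.Series(
        {lvl: int((topology.level[topology.parent[1:]] == lvl).sum())
         for lvl in drift.index}
    )
    return np.sqrt(drift / counts)


def attractor_spread(per_capita_traces, steady_frac: float = 0.05) -> dict:
    """Summary of steady-state per-capita energy across initial conditions.

    Each trace is a per-epoch per-capita consumption series; its steady
    state is the mean over the final ``steady_frac`` of epochs.  Returns
    min, max, median, and spread (max - min) across traces.
    """
    finals = []
    for trace in per_capita_traces:
        arr = np.asarray(trace, dtype=float)
        tail = max(1, int(round(steady_frac * arr.size)))
        finals.append(arr[-tail:].mean())
    if len(finals) < 3:
        raise ValueError("need at least three traces to summarize a spread")
    finals = np.asarray(finals)
    return {
        "min": float(finals.min()),
        "max": float(finals.max()),
        "median": float(np.median(finals)),
        "spread": float(finals.max() - finals.min()),
    }
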