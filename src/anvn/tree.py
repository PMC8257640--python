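"""k-ary vascular tree: topology, branch weights, and energy transport.

The vascular network is a rooted tree with at most ``k`` branches per
junction and exactly one terminal (leaf) node per hidden neuron of the
coupled perceptron.  Each branch carries a weight giving the fraction of
the parent node's energy routed down that branch; sibling weights are
absolute-normalized so that energy is conserved at every junction.  Energy
flows root -> leaves; during learning an energy-demand gradient produced
at the leaves flows leaves -> root (each parent receiving the mean of its
children's gradients) and nudges the branch weights.

Nodes are numbered in breadth-first order with the root first, so the
nodes of each level — and the children of each parent — occupy contiguous
index ranges.  All array fields below use that numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DegenerateWeightsError",
    "TreeTopology",
    "VascularState",
    "plan_tree",
    "node_count_closed_form",
    "level_count_closed_form",
    "init_weights",
    "equal_split_weights",
    "normalize_weights",
    "propagate_energy",
    "leaf_energies",
    "backpropagate_energy",
    "topology_to_dict",
    "topology_from_dict",
    "state_to_dict",
    "state_from_dict",
    "save_checkpoint",
    "load_checkpoint",
]


class DegenerateWeightsError(ValueError):
    """A sibling group whose weights sum to zero cannot be normalized."""


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


@dataclass(frozen=True)
class TreeTopology:
    """Static structure of the vascular tree.

    Attributes
    ----------
    n_leaves : int
        Number of terminal nodes; equals the hidden-layer width N.
    k : int
        Branching factor (every junction has at most ``k`` children).
    n_levels : int
        Number of levels L; the root is level 1, leaves level L.
    n_nodes : int
        Total node count T_n.
    parent : ndarray of int, shape (n_nodes,)
        ``parent[i]`` is the breadth-first index of node i's parent;
        ``parent[0] == -1`` (root).
    level : ndarray of int, shape (n_nodes,)
        1-based level of each node.
    child_start, child_count : ndarray of int, shape (n_nodes,)
        Children of node x are ``child_start[x] : child_start[x] + child_count[x]``.
    level_slices : tuple of (int, int)
        Half-open node-index range of each level, root level first.
    """

    n_leaves: int
    k: int
    n_levels: int
    n_nodes: int
    parent: np.ndarray
    level: np.ndarray
    child_start: np.ndarray
    child_count: np.ndarray
    level_slices: tuple

    @property
    def leaf_ids(self) -> np.ndarray:
        start, stop = self.level_slices[-1]
        return np.arange(start, stop)

    def children_of(self, x: int) -> np.ndarray:
        return np.arange(self.child_start[x], self.child_start[x] + self.child_count[x])

    def adjacency(self) -> np.ndarray:
        """Dense adjacency matrix A with A[y, x] = 1 for an edge x -> y."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        a[np.arange(1, self.n_nodes), self.parent[1:]] = 1
        return a


def level_count_closed_form(n_leaves: int, k: int) -> int:
    """L = 1 + ceil(log N / log k), evaluated in exact integer arithmetic."""
    if n_leaves == 1:
        return 1
    m, p = 0, 1
    while p < n_leaves:
        p *= k
        m += 1
    return 1 + m


def node_count_closed_form(n_leaves: int, k: int) -> int:
    """T_n = sum_{l=0}^{L-1} ceil(N / k^l)."""
    L = level_count_closed_form(n_leaves, k)
    return sum(_ceil_div(n_leaves, k**l) for l in range(L))


def plan_tree(n_leaves: int, k: int) -> TreeTopology:
    """Construct the k-ary vascular tree with ``n_leaves`` terminal nodes.

    Level l (1-based, root = 1) holds ceil(N / k^(L-l)) nodes.  When N is
    not a power of k the children of a level are allotted so that the
    first floor(c/k) parents receive k branches each and the remaining
    children attach to the next parent in breadth-first order.

    Deterministic; raises ``ValueError`` for N < 1, k < 2, or k > N
    (N > 1) since over-branching has no defined allocation.
    """
    if n_leaves < 1:
        raise ValueError(f"need at least one leaf, got {n_leaves}")
    if k < 2:
        raise ValueError(f"branching factor must be >= 2, got {k}")
    if n_leaves > 1 and k > n_leaves:
        raise ValueError(f"branching factor {k} exceeds leaf count {n_leaves}")

    L = level_count_closed_form(n_leaves, k)
    counts = [_ceil_div(n_leaves, k ** (L - l)) for l in range(1, L + 1)]
    n_nodes = sum(counts)

    parent = np.full(n_nodes, -1, dtype=np.int64)
    level = np.empty(n_nodes, dtype=np.int64)
    child_start = np.zeros(n_nodes, dtype=np.int64)
    child_count = np.zeros(n_nodes, dtype=np.int64)

    offsets = np.concatenate([[0], np.cumsum(counts)])
    level_slices = tuple((int(offsets[i]), int(offsets[i + 1])) for i in range(L))
    for li, (start, stop) in enumerate(level_slices):
        level[start:stop] = li + 1

    for li in range(L - 1):
        p0, p1 = level_slices[li]
        c0, c1 = level_slices[li + 1]
        n_parents, c = p1 - p0, c1 - c0
        full, rem = divmod(c, k)
        assert full + (1 if rem else 0) == n_parents
        pos = c0
        for j in range(n_parents):
            take = k if j < full else rem
            child_start[p0 + j] = pos
            child_count[p0 + j] = take
            parent[pos : pos + take] = p0 + j
            pos += take

    return TreeTopology(
        n_leaves=n_leaves,
        k=k,
        n_levels=L,
        n_nodes=n_nodes,
        parent=parent,
        level=level,
        child_start=child_start,
        child_count=child_count,
        level_slices=level_slices,
    )


@dataclass
class VascularState:
    """Branch weights and node energies of a vascular tree.

    ``weights[i]`` is the fraction of node ``parent[i]``'s energy routed to
    node ``i``; ``weights[0]`` is unused (the root has no incoming branch).
    ``source_weight`` (U_0) is set only for the reservoir variant, where a
    constant ``source_energy`` splits between the tree root (weight U_0)
    and a reservoir (weight 1 - U_0).
    """

    weights: np.ndarray
    energies: np.ndarray | None = None
    source_weight: float | None = None
    source_energy: float = 5000.0

    @property
    def reservoir_weight(self) -> float:
        if self.source_weight is None:
            raise ValueError("not a reservoir-coupled state")
        return 1.0 - self.source_weight

    @property
    def reservoir_energy(self) -> float:
        return self.source_energy * self.reservoir_weight

    def copy(self) -> "VascularState":
        return replace(
            self,
            weights=self.weights.copy(),
            energies=None if self.energies is None else self.energies.copy(),
        )


def init_weights(topology: TreeTopology, rng) -> VascularState:
    """Random positive branch weights, normalized per sibling group.

    ``rng`` is a seed or a ``numpy.random.Generator``; identical seeds give
    identical weights.
    """
    rng = np.random.default_rng(rng)
    w = rng.uniform(0.05, 1.0, size=topology.n_nodes)
    w[0] = 1.0
    state = VascularState(weights=w)
    return normalize_weights(state, topology)


def equal_split_weights(topology: TreeTopology) -> VascularState:
    """Fixed weights that deliver exactly E_s / N to every leaf.

    Each branch weight is the fraction of leaves in its subtree, so the
    root energy is equally distributed among the leaf nodes even when the
    tree is unbalanced.  Used by the untrained regime.
    """
    leaves_below = np.zeros(topology.n_nodes, dtype=np.int64)
    leaves_below[topology.leaf_ids] = 1
    for start, stop in reversed(topology.level_slices[:-1]):
        for x in range(start, stop):
            ch = topology.children_of(x)
            leaves_below[x] = leaves_below[ch].sum()
    w = np.ones(topology.n_nodes, dtype=float)
    w[1:] = leaves_below[1:] / leaves_below[topology.parent[1:]]
    return VascularState(weights=w)


def normalize_weights(state: VascularState, topology: TreeTopology) -> VascularState:
    """Divide each sibling group by its absolute sum (in place).

    Raises ``DegenerateWeightsError`` if any sibling group sums to zero in
    absolute value: such a junction can no longer apportion energy.
    """
    w = state.weights
    sums = np.bincount(topology.parent[1:], weights=np.abs(w[1:]), minlength=topology.n_nodes)
    has_children = topology.child_count > 0
    if np.any(sums[has_children] == 0.0):
        bad = int(np.nonzero(has_children & (sums == 0.0))[0][0])
        raise DegenerateWeightsError(f"all-zero sibling weights under node {bad}")
    w[1:] = w[1:] / sums[topology.parent[1:]]
    return state


def propagate_energy(
    state: VascularState, topology: TreeTopology, e_source: float | None = None
) -> VascularState:
    """Fill node energies root -> leaves: E(child) = U(child) * E(parent).

    For a plain tree the root receives ``e_source`` (must be >= 0).  For a
    reservoir-coupled state the root receives
    ``source_weight * source_energy`` and ``e_source`` must be omitted.
    """
    if state.source_weight is not None:
        if e_source is not None:
            raise ValueError("reservoir state derives its root energy from U_0")
        e_root = state.source_weight * state.source_energy
    else:
        if e_source is None:
            raise ValueError("root energy required for a non-reservoir tree")
        if e_source < 0:
            raise ValueError(f"root energy must be nonnegative, got {e_source}")
        e_root = float(e_source)

    e = np.empty(topology.n_nodes, dtype=float)
    e[0] = e_root
    for start, stop in topology.level_slices[1:]:
        idx = np.arange(start, stop)
        e[idx] = state.weights[idx] * e[topology.parent[idx]]
    state.energies = e
    return state


def leaf_energies(state: VascularState, topology: TreeTopology) -> np.ndarray:
    """Energies at the terminal nodes, ordered by hidden-neuron index."""
    if state.energies is None:
        raise ValueError("energies not propagated yet")
    return state.energies[topology.leaf_ids]


def backpropagate_energy(
    state: VascularState,
    topology: TreeTopology,
    leaf_gradients: np.ndarray,
    eta_v: float = 0.01,
    clamp_nonnegative: bool = True,
) -> np.ndarray:
    """Propagate leaf energy-demand gradients to the root and update weights.

    Each internal node's gradient is the mean of its children's gradients;
    every branch weight is incremented by ``eta_v`` times the gradient of
    the node it feeds, then (optionally clamped to >= 0 and) renormalized
    per sibling group.  For a reservoir-coupled state the source weight U_0
    moves with the root-node gradient and the reservoir weight stays
    1 - U_0.

    Returns the full per-node gradient vector (useful for inspection).
    """
    leaf_gradients = np.asarray(leaf_gradients, dtype=float)
    if leaf_gradients.shape != (topology.n_leaves,):
        raise ValueError(
            f"expected {topology.n_leaves} leaf gradients, got shape {leaf_gradients.shape}"
        )

    grads = np.zeros(topology.n_nodes, dtype=float)
    grads[topology.leaf_ids] = leaf_gradients
    for start, stop in reversed(topology.level_slices[:-1]):
        idx = np.arange(start, stop)
        child_lo, child_hi = topology.level_slices[topology.level[start]]
        child_idx = np.arange(child_lo, child_hi)
        sums = np.bincount(
            topology.parent[child_idx] - start, weights=grads[child_idx], minlength=stop - start
        )
        grads[idx] = sums / topology.child_count[idx]

    state.weights[1:] += eta_v * grads[1:]
    if clamp_nonnegative:
        np.clip(state.weights[1:], 0.0, None, out=state.weights[1:])
    normalize_weights(state, topology)

    if state.source_weight is not None:
        u0 = state.source_weight + eta_v * grads[0]
        state.source_weight = float(np.clip(u0, 0.0, 1.0))
    return grads


# ---------------------------------------------------------------------------
# Checkpointing

def topology_to_dict(topology: TreeTopology) -> dict:
    return {"n_leaves": topology.n_leaves, "k": topology.k}


def topology_from_dict(d: dict) -> TreeTopology:
    return plan_tree(d["n_leaves"], d["k"])


def state_to_dict(state: VascularState) -> dict:
    d = {"weights": state.weights.tolist()}
    if state.energies is not None:
        d["energies"] = state.energies.tolist()
    if state.source_weight is not None:
        d["source_weight"] = state.source_weight
        d["source_energy"] = state.source_energy
    return d


def state_from_dict(d: dict) -> VascularState:
    return VascularState(
        weights=np.asarray(d["weights"], dtype=float),
        energies=None if "energies" not in d else np.asarray(d["energies"], dtype=float),
        source_weight=d.get("source_weight"),
        source_energy=d.get("source_energy", 5000.0),
    )


def save_checkpoint(path, topology: TreeTopology, state: VascularState) -> None:
    """Exact JSON round-trip of topology plus weights/energies."""
    payload = {"topology": topology_to_dict(topology), "state": state_to_dict(state)}
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> tuple[TreeTopology, VascularState]:
    payload = json.loads(Path(path).read_text())
    return topology_from_dict(payload["topology"]), state_from_dict(payload["state"])
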