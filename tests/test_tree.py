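"""Vascular tree: topology closed forms, normalization, energy transport."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anvn import tree as vt


def brute_force_node_count(n_leaves: int, k: int) -> int:
    """Independent enumeration: walk upward from the leaf level, each
    level holding ceil(previous / k) parents, until a single root."""
    total, c = n_leaves, n_leaves
    while c > 1:
        c = -(-c // k)
        total += c
    return total


class TestPlanTree:
    @pytest.mark.parametrize(
        "n, k, levels",
        [(512, 8, 4), (512, 512, 2), (512, 2, 10), (1, 2, 1)],
    )
    def test_level_counts(self, n, k, levels):
        assert vt.plan_tree(n, k).n_levels == levels

    def test_single_node_tree(self):
        topo = vt.plan_tree(1, 2)
        assert topo.n_nodes == 1
        assert list(topo.leaf_ids) == [0]

    def test_node_count_for_reference_tree(self):
        assert vt.plan_tree(512, 8).n_nodes == 585

    def test_node_count_matches_closed_form_and_enumeration(self):
        for n in range(1, 101):
            for k in range(2, min(n, 10) + 1):
                topo = vt.plan_tree(n, k)
                assert topo.n_nodes == vt.node_count_closed_form(n, k)
                assert topo.n_nodes == brute_force_node_count(n, k)

    @pytest.mark.parametrize("n, k", [(0, 2), (5, 1), (3, 7)])
    def test_invalid_arguments(self, n, k):
        with pytest.raises(ValueError):
            vt.plan_tree(n, k)

    @pytest.mark.parametrize("n, k", [(5, 3), (37, 4), (100, 7), (64, 2)])
    def test_structural_invariants(self, n, k):
        topo = vt.plan_tree(n, k)
        assert topo.leaf_ids.size == n
        assert np.all(topo.level[topo.leaf_ids] == topo.n_levels)
        # every non-root node has exactly one parent at the previous level
        assert topo.parent[0] == -1
        assert np.all(topo.parent[1:] >= 0)
        assert np.all(topo.level[topo.parent[1:]] == topo.level[1:] - 1)
        # at most k children; the floor/ceil allocation fills early parents
        assert topo.child_count.max() <= k
        for lo, hi in topo.level_slices[:-1]:
            counts = topo.child_count[lo:hi]
            full = int(np.sum(counts == k))
            assert np.all(counts[:full] == k)
            assert np.all(counts[full:] < k)

    def test_adjacency_matrix(self):
        topo = vt.plan_tree(6, 2)
        a = topo.adjacency()
        assert a.sum() == topo.n_nodes - 1
        assert np.all(a[np.arange(1, topo.n_nodes), topo.parent[1:]] == 1)


class TestWeights:
    def test_init_normalized_and_reproducible(self):
        topo = vt.plan_tree(13, 3)
        s1 = vt.init_weights(topo, 42)
        s2 = vt.init_weights(topo, 42)
        s3 = vt.init_weights(topo, 43)
        for x in range(topo.n_nodes):
            ch = topo.children_of(x)
            if ch.size:
                assert np.abs(s1.weights[ch]).sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(s1.weights, s2.weights)
        assert np.any(s1.weights != s3.weights)

    @pytest.mark.parametrize(
        "raw, expected",
        [((2.0, 2.0), (0.5, 0.5)), ((1.0, 3.0), (0.25, 0.75)),
         ((-1.0, 3.0), (-0.25, 0.75))],
    )
    def test_normalization_examples(self, raw, expected):
        topo = vt.plan_tree(2, 2)
        state = vt.VascularState(weights=np.array([1.0, *raw]))
        vt.normalize_weights(state, topo)
        np.testing.assert_allclose(state.weights[1:], expected)

    def test_degenerate_group_raises(self):
        topo = vt.plan_tree(2, 2)
        state = vt.VascularState(weights=np.array([1.0, 0.0, 0.0]))
        with pytest.raises(vt.DegenerateWeightsError):
            vt.normalize_weights(state, topo)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.floats(0.1, 50.0))
    def test_normalization_idempotent_and_scale_invariant(self, seed, scale):
        topo = vt.plan_tree(9, 3)
        state = vt.init_weights(topo, seed)
        once = state.weights.copy()
        vt.normalize_weights(state, topo)
        np.testing.assert_allclose(state.weights, once, rtol=1e-14)
        scaled = vt.VascularState(weights=once * scale)
        scaled.weights[0] = 1.0
        vt.normalize_weights(scaled, topo)
        np.testing.assert_allclose(scaled.weights[1:], once[1:], rtol=1e-12)


class TestEnergyTransport:
    def test_equal_split_two_leaves(self):
        topo = vt.plan_tree(2, 2)
        state = vt.VascularState(weights=np.array([1.0, 0.5, 0.5]))
        vt.propagate_energy(state, topo, 10.0)
        np.testing.assert_allclose(vt.leaf_energies(state, topo), [5.0, 5.0])

    def test_hand_computed_unbalanced_split(self):
        # N=4, k=2: level-2 weights (0.3, 0.7); level-3 (0.5, 0.5), (0.2, 0.8)
        topo = vt.plan_tree(4, 2)
        state = vt.VascularState(weights=np.array([1.0, 0.3, 0.7, 0.5, 0.5, 0.2, 0.8]))
        vt.propagate_energy(state, topo, 10.0)
        leaves = vt.leaf_energies(state, topo)
        np.testing.assert_allclose(leaves, [1.5, 1.5, 1.4, 5.6])
        assert leaves.sum() == pytest.approx(10.0)

    def test_negative_root_energy_rejected(self):
        topo = vt.plan_tree(2, 2)
        state = vt.init_weights(topo, 0)
        with pytest.raises(ValueError):
            vt.propagate_energy(state, topo, -1.0)

    @pytest.mark.parametrize("k", [2, 3, 4, 8])
    def test_conservation_over_random_trees_and_updates(self, k):
        rng = np.random.default_rng(k)
        for _ in range(10):
            n = int(rng.integers(max(2, k), 65))
            topo = vt.plan_tree(n, k)
            state = vt.init_weights(topo, rng)
            e_s = float(rng.uniform(0.5, 200.0))
            vt.propagate_energy(state, topo, e_s)
            assert vt.leaf_energies(state, topo).sum() == pytest.approx(e_s, rel=1e-9)
            vt.backpropagate_energy(state, topo, rng.normal(0, 1, n), eta_v=0.05)
            vt.propagate_energy(state, topo, e_s)
            assert vt.leaf_energies(state, topo).sum() == pytest.approx(e_s, rel=1e-9)

    def test_equal_split_weights_unbalanced_tree(self):
        topo = vt.plan_tree(3, 2)
        state = vt.equal_split_weights(topo)
        vt.propagate_energy(state, topo, 9.0)
        np.testing.assert_allclose(vt.leaf_energies(state, topo), [3.0, 3.0, 3.0])


class TestBackpropagation:
    def test_zero_gradients_leave_weights_unchanged(self):
        topo = vt.plan_tree(8, 2)
        state = vt.init_weights(topo, 5)
        before = state.weights.copy()
        vt.backpropagate_energy(state, topo, np.zeros(8))
        np.testing.assert_allclose(state.weights, before, rtol=1e-14)

    def test_uniform_gradient_propagates_to_every_internal_node(self):
        topo = vt.plan_tree(16, 4)
        state = vt.init_weights(topo, 0)
        grads = vt.backpropagate_energy(state, topo, np.full(16, 0.7))
        np.testing.assert_allclose(grads, 0.7)

    def test_two_leaf_antisymmetric_update(self):
        g, eta_v = 0.3, 0.01
        topo = vt.plan_tree(2, 2)
        state = vt.VascularState(weights=np.array([1.0, 0.5, 0.5]))
        grads = vt.backpropagate_energy(state, topo, np.array([g, -g]), eta_v=eta_v)
        assert grads[0] == pytest.approx(0.0)   # root receives the mean
        np.testing.assert_allclose(state.weights[1:], [0.5 + eta_v * g, 0.5 - eta_v * g])
        assert state.weights[1:].sum() == pytest.approx(1.0)

    def test_clamp_keeps_weights_nonnegative(self):
        topo = vt.plan_tree(2, 2)
        state = vt.VascularState(weights=np.array([1.0, 0.01, 0.99]))
        vt.backpropagate_energy(state, topo, np.array([-5.0, 5.0]), eta_v=0.1)
        assert np.all(state.weights[1:] >= 0)
        assert state.weights[1:].sum() == pytest.approx(1.0)

    def test_wrong_gradient_length_rejected(self):
        topo = vt.plan_tree(4, 2)
        state = vt.init_weights(topo, 0)
        with pytest.raises(ValueError):
            vt.backpropagate_energy(state, topo, np.zeros(3))


def test_checkpoint_roundtrip(tmp_path):
    topo = vt.plan_tree(11, 3)
    state = vt.init_weights(topo, 9)
    vt.propagate_energy(state, topo, 7.5)
    path = tmp_path / "tree.json"
    vt.save_checkpoint(path, topo, state)
    topo2, state2 = vt.load_checkpoint(path)
    assert topo2.n_leaves == topo.n_leaves and topo2.k == topo.k
    np.testing.assert_array_equal(state2.weights, state.weights)
    np.testing.assert_array_equal(state2.energies, state.energies)
    # reservoir fields survive too
    state.source_weight = 0.25
    vt.save_checkpoint(path, topo, state)
    _, state3 = vt.load_checkpoint(path)
    assert state3.source_weight == 0.25
    assert state3.reservoir_weight == 0.75
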