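"""ST-GCN layers, forward pass, gradients and persistence."""

import numpy as np
import pytest

import fallgcn as fg
from fallgcn.model import AdamOptimizer, STGCN, tree_iter

import oracles


def tiny_model(tiny_graph, dropout=0.0, dtype=np.float32, seed=1, num_classes=2):
    cfg = fg.ModelConfig(
        num_classes=num_classes,
        in_channels=3,
        block_channels=(4, 4),
        temporal_kernel=3,
        dropout=dropout,
        partition=fg.PartitionConfig("spatial-configuration", 1),
    )
    return STGCN.from_graph(cfg, tiny_graph, seed=seed, dtype=dtype)


class TestSpatialGraphConv:
    def test_identity_adjacency_identity_weights(self, rng):
        stack = fg.AdjacencyStack(np.eye(4)[None])
        x = rng.normal(size=(3, 7, 4))
        out = fg.spatial_graph_conv(x, stack, np.eye(3)[None])
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_matches_double_loop_oracle(self, default_graph, rng):
        stack = fg.build_adjacency_stack(
            default_graph, fg.PartitionConfig("spatial-configuration", 1)
        )
        for _ in range(20):
            x = rng.normal(size=(3, 4, 5))
            w = rng.normal(size=(stack.K, 3, 6))
            got = fg.spatial_graph_conv(x, stack, w)
            expected = oracles.brute_force_spatial_conv(x, stack.subsets, w)
            np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_node_permutation_equivariance(self, default_graph, rng):
        cfg = fg.PartitionConfig("distance", 1)
        stack = fg.build_adjacency_stack(default_graph, cfg)
        perm = rng.permutation(5)
        stack_p = fg.build_adjacency_stack(default_graph.relabel(perm), cfg)
        x = rng.normal(size=(3, 4, 5))
        w = rng.normal(size=(stack.K, 3, 3))
        out = fg.spatial_graph_conv(x, stack, w)
        out_p = fg.spatial_graph_conv(x[:, :, np.argsort(perm)], stack_p, w)
        np.testing.assert_allclose(out_p[:, :, perm[np.arange(5)]], out[:, :, np.arange(5)], atol=1e-9)

    def test_subset_count_mismatch_rejected(self, default_graph, rng):
        stack = fg.build_adjacency_stack(
            default_graph, fg.PartitionConfig("spatial-configuration", 1)
        )
        with pytest.raises(ValueError, match="subsets"):
            fg.spatial_graph_conv(rng.normal(size=(3, 4, 5)), stack, np.zeros((2, 3, 3)))


class TestTemporalConv:
    def test_unit_impulse_is_identity(self, rng):
        x = rng.normal(size=(2, 9, 3))
        kern = np.zeros((2, 2, 3))
        kern[:, :, 1] = np.eye(2)  # centre tap, identity channel map
        np.testing.assert_allclose(fg.temporal_conv(x, kern), x, atol=1e-12)

    def test_averaging_kernel_preserves_constant_interior(self):
        x = np.full((1, 10, 2), 4.0)
        kern = np.full((1, 1, 3), 1.0 / 3.0)
        out = fg.temporal_conv(x, kern)
        np.testing.assert_allclose(out[:, 1:-1, :], 4.0, atol=1e-12)
        # boundary frames see zero padding
        np.testing.assert_allclose(out[:, 0, :], 8.0 / 3.0, atol=1e-12)

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=(3, 12, 4))
        kern = rng.normal(size=(5, 3, 9))
        np.testing.assert_allclose(
            fg.temporal_conv(x, kern),
            oracles.brute_force_temporal_conv(x, kern),
            rtol=1e-6,
            atol=1e-9,
        )


class TestBlocksAndForward:
    def test_probabilities_sum_to_one(self, default_graph, rng):
        cfg = fg.ModelConfig(partition=fg.PartitionConfig("uni-labeling", 1))
        model = STGCN.from_graph(cfg, default_graph, seed=0)
        probs = model.forward(rng.normal(size=(4, 6, 36, 5)))
        assert probs.shape == (4, 11)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, default_graph, rng):
        cfg = fg.ModelConfig(dropout=0.5)
        model = STGCN.from_graph(cfg, default_graph, seed=0)
        x = rng.normal(size=(2, 6, 36, 5))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_duplicated_sample_identical_rows(self, default_graph, rng):
        model = STGCN.from_graph(fg.ModelConfig(), default_graph, seed=0)
        x = rng.normal(size=(1, 6, 36, 5)).astype(np.float32)
        batch = np.concatenate([x, x, x])
        probs = model.forward(batch)
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-6)
        np.testing.assert_allclose(probs[0], probs[2], atol=1e-6)

    def test_first_block_expands_channels(self, default_graph, rng):
        model = STGCN.from_graph(fg.ModelConfig(), default_graph, seed=0)
        x = rng.normal(size=(2, 36, 5, 6)).astype(np.float32)  # channels-last
        out, _ = model._block_forward(
            x, model.params["blocks"][0], model.state["blocks"][0], False, False
        )
        assert out.shape == (2, 36, 5, 32)

    def test_zero_weights_pass_residual_through(self, tiny_graph, rng):
        model = tiny_model(tiny_graph)
        bp = model.params["blocks"][1]  # same channel count -> identity residual
        bp["W"][:] = 0
        bp["tk"][:] = 0
        bp["bn2_beta"][:] = 0
        x = np.abs(rng.normal(size=(2, 4, 2, 4))).astype(np.float32)
        out, _ = model._block_forward(x, bp, model.state["blocks"][1], False, False)
        np.testing.assert_allclose(out, np.maximum(x, 0), atol=1e-6)

    def test_parameter_count_uni_labeling_independent_of_md(self, default_graph):
        counts = []
        for md in (1, 2):
            cfg = fg.ModelConfig(partition=fg.PartitionConfig("uni-labeling", md))
            counts.append(STGCN.from_graph(cfg, default_graph, seed=0).n_parameters)
        assert counts[0] == counts[1]

    def test_end_to_end_node_permutation_invariance(self, default_graph, rng):
        """Global pooling erases node order: permuting graph + input together
        leaves class probabilities unchanged."""
        cfg = fg.ModelConfig(partition=fg.PartitionConfig("spatial-configuration", 1))
        model = STGCN.from_graph(cfg, default_graph, seed=3)
        perm = rng.permutation(5)
        graph_p = default_graph.relabel(perm)
        model_p = STGCN.from_graph(cfg, graph_p, seed=3)
        model_p.params = model.params  # same weights, different node order
        x = rng.normal(size=(2, 6, 36, 5)).astype(np.float32)
        x_p = x[:, :, :, np.argsort(perm)]
        np.testing.assert_allclose(
            model_p.forward(x_p), model.forward(x), rtol=1e-4, atol=1e-6
        )

    def test_node_count_mismatch_rejected(self, default_graph, rng):
        model = STGCN.from_graph(fg.ModelConfig(), default_graph, seed=0)
        with pytest.raises(ValueError, match="node count"):
            model.forward(rng.normal(size=(1, 6, 36, 4)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, tiny_graph, rng):
        """Backprop through SGC, BN (training mode), ReLU, T-Conv, residual
        and softmax head agrees with central finite differences."""
        model = tiny_model(tiny_graph, dtype=np.float64)
        x = rng.normal(size=(3, 3, 4, 2))
        y = np.array([0, 1, 1])
        _, grads = model.loss_and_gradients(x, y)
        flat_grads = dict(tree_iter(grads))
        eps = 1e-6
        worst = 0.0
        for path, arr in tree_iter(model.params):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(min(arr.size, 6)):
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                lp, _ = model.loss_and_gradients(x, y)
                arr[idx] = old - eps
                lm, _ = model.loss_and_gradients(x, y)
                arr[idx] = old
                numeric = (lp - lm) / (2 * eps)
                denom = max(abs(numeric), abs(flat_grads[path][idx]), 1e-8)
                worst = max(worst, abs(numeric - flat_grads[path][idx]) / denom)
                it.iternext()
        assert worst < 1e-4

    def test_adam_reduces_loss_on_fixed_batch(self, tiny_graph, rng):
        model = tiny_model(tiny_graph)
        x = rng.normal(size=(8, 3, 6, 2)).astype(np.float32)
        y = rng.integers(0, 2, 8)
        opt = AdamOptimizer(model.params, lr=1e-2)
        first, _ = model.loss_and_gradients(x, y)
        for _ in range(30):
            loss, grads = model.loss_and_gradients(x, y)
            opt.step(model.params, grads)
        assert loss < first


class TestPersistence:
    def test_checkpoint_roundtrip(self, tiny_graph, tmp_path, rng):
        model = tiny_model(tiny_graph, dropout=0.3)
        x = rng.normal(size=(4, 3, 6, 2)).astype(np.float32)
        path = tmp_path / "model.npz"
        model.save(path, extra={"classes": [1, 2]})
        loaded, extra = STGCN.load(path)
        assert extra == {"classes": [1, 2]}
        np.testing.assert_allclose(loaded.forward(x), model.forward(x), atol=1e-7)
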