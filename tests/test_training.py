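"""Splits, the training loop, repeated CV and the hyperparameter grid."""

import numpy as np
import pytest

import fallgcn as fg
from fallgcn.model import STGCN, tree_iter


def tiny_two_class_data(rng, n_per_class=30, frames=12, nodes=2):
    """Well-separated two-class windows: constant +1 vs -1 signal plus noise."""
    x0 = rng.normal(1.0, 0.1, size=(n_per_class, 3, frames, nodes))
    x1 = rng.normal(-1.0, 0.1, size=(n_per_class, 3, frames, nodes))
    x = np.concatenate([x0, x1]).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y


def tiny_model(seed=0, dropout=0.0):
    graph = fg.SkeletonGraph(("a", "b"), frozenset({(0, 1)}), 0)
    cfg = fg.ModelConfig(
        num_classes=2,
        in_channels=3,
        block_channels=(4, 4),
        temporal_kernel=3,
        dropout=dropout,
        partition=fg.PartitionConfig("spatial-configuration", 1),
    )
    return STGCN.from_graph(cfg, graph, seed=seed)


class TestSplitDataset:
    def test_hundred_samples_split_80_10_10(self, rng):
        labels = rng.integers(0, 5, 100)
        tr, va, te = fg.split_dataset(labels, fg.SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_disjoint_exhaustive_cover(self, rng):
        labels = rng.integers(0, 4, 173)
        tr, va, te = fg.split_dataset(labels, fg.SplitSpec(seed=3))
        allidx = np.concatenate([tr, va, te])
        assert len(np.unique(allidx)) == len(allidx) == 173
        assert abs(len(te) - round(0.1 * 173)) <= 1
        assert abs(len(va) - round(0.1 * 173)) <= 1

    def test_every_class_in_every_split(self, rng):
        labels = np.repeat(np.arange(11), [50, 40, 30, 30, 30, 200, 150, 90, 20, 10, 60])
        tr, va, te = fg.split_dataset(labels, fg.SplitSpec(seed=1))
        for idx in (tr, va, te):
            assert set(labels[idx]) == set(range(11))

    def test_seed_determinism_and_variation(self, rng):
        labels = rng.integers(0, 3, 90)
        a = fg.split_dataset(labels, fg.SplitSpec(seed=5))
        b = fg.split_dataset(labels, fg.SplitSpec(seed=5))
        c = fg.split_dataset(labels, fg.SplitSpec(seed=6))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))
        assert tuple(len(s) for s in a) == tuple(len(s) for s in c)

    def test_small_class_error_names_offender(self):
        labels = np.array([0] * 50 + [1] * 2)
        with pytest.raises(ValueError, match="1"):
            fg.split_dataset(labels, fg.SplitSpec(seed=0))

    def test_unstratified_allows_small_classes(self):
        labels = np.array([0] * 50 + [1] * 2)
        tr, va, te = fg.split_dataset(labels, fg.SplitSpec(stratified=False, seed=0))
        assert len(tr) + len(va) + len(te) == 52


class TestTrainLoop:
    def test_loss_descends_on_separable_classes(self, rng):
        x, y = tiny_two_class_data(rng)
        model = tiny_model(seed=0)
        cfg = fg.TrainConfig(
            minibatch_size=16, learning_rate=1e-2, max_epochs=5, patience=5, seed=0
        )
        res = fg.train(model, x, y, x[:10], y[:10], cfg)
        history = res.history
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_early_stopping_when_validation_cannot_improve(self, rng):
        """With validation predictions pinned constant, epoch 1 sets the best
        and patience=1 stops the loop right after the second evaluation.

        (Plain lr=0 does not freeze the validation loss: batch-norm running
        statistics still drift toward the batch statistics, which is why the
        probe pins the predictions instead.)"""
        x, y = tiny_two_class_data(rng, n_per_class=8)
        model = tiny_model(seed=0)
        frozen = np.full((6, 2), 0.5)
        model.predict_proba = lambda xv, batch_size=512: frozen
        cfg = fg.TrainConfig(
            minibatch_size=8, learning_rate=0.0, max_epochs=100, patience=1, seed=0
        )
        res = fg.train(model, x, y, x[:6], y[:6], cfg)
        assert res.stopped_epoch == 2
        assert res.best_epoch == 1

    def test_identical_seeds_identical_parameters(self, rng):
        x, y = tiny_two_class_data(rng, n_per_class=12)
        results = []
        for _ in range(2):
            model = tiny_model(seed=4, dropout=0.5)
            cfg = fg.TrainConfig(
                minibatch_size=8, learning_rate=1e-3, max_epochs=3, patience=3, seed=4
            )
            results.append(fg.train(model, x, y, x[:6], y[:6], cfg))
        for (pa, a), (pb, b) in zip(
            tree_iter(results[0].model.params), tree_iter(results[1].model.params)
        ):
            assert pa == pb
            np.testing.assert_array_equal(a, b)

    def test_best_validation_loss_never_worse_than_history(self, rng):
        x, y = tiny_two_class_data(rng)
        model = tiny_model(seed=2, dropout=0.5)
        cfg = fg.TrainConfig(
            minibatch_size=16, learning_rate=5e-3, max_epochs=8, patience=8, seed=2
        )
        res = fg.train(model, x, y, x[:10], y[:10], cfg)
        assert res.best_val_loss <= res.history["val_loss"].min() + 1e-12

    def test_non_finite_loss_aborts(self, rng):
        x, y = tiny_two_class_data(rng, n_per_class=8)
        model = tiny_model(seed=0)
        model.params["head_b"][:] = np.inf
        cfg = fg.TrainConfig(minibatch_size=8, max_epochs=1, patience=1, seed=0)
        with pytest.raises(FloatingPointError):
            fg.train(model, x, y, x[:4], y[:4], cfg)


def small_experiment_configs(max_epochs=2):
    mc = fg.ModelConfig(
        block_channels=(8, 8),
        temporal_kernel=5,
        dropout=0.1,
        partition=fg.PartitionConfig("spatial-configuration", 1),
    )
    tc = fg.TrainConfig(
        minibatch_size=64, learning_rate=1e-3, max_epochs=max_epochs, patience=max_epochs, seed=0
    )
    return mc, tc, fg.SplitSpec(seed=0)


class TestPipelines:
    def test_cross_validate_bookkeeping(self, small_windows):
        mc, tc, sp = small_experiment_configs()
        cv = fg.cross_validate(small_windows, mc, tc, sp, rounds=2)
        assert len(cv.reports) == 2
        accs = [r.accuracy for r in cv.reports]
        assert min(accs) <= cv.summary.loc["mean", "accuracy"] <= max(accs)

    def test_cross_validate_deterministic(self, small_windows):
        mc, tc, sp = small_experiment_configs(max_epochs=1)
        a = fg.cross_validate(small_windows, mc, tc, sp, rounds=2)
        b = fg.cross_validate(small_windows, mc, tc, sp, rounds=2)
        assert a.summary.equals(b.summary)

    def test_grid_uni_labeling_equal_on_complete_graph(self):
        """On a diameter-1 graph the MD=1 and MD=2 neighbourhoods coincide,
        so uni-labeling adjacency stacks (and models) are identical."""
        g = fg.SkeletonGraph(
            ("a", "b", "c"), frozenset({(0, 1), (1, 2), (0, 2)}), 0
        )
        s1 = fg.build_adjacency_stack(g, fg.PartitionConfig("uni-labeling", 1))
        s2 = fg.build_adjacency_stack(g, fg.PartitionConfig("uni-labeling", 2))
        np.testing.assert_array_equal(s1.subsets, s2.subsets)

    def test_experiment_normalization_uses_train_indices_only(self, small_windows):
        mc, tc, sp = small_experiment_configs(max_epochs=1)
        res = fg.run_experiment(small_windows, mc, tc, sp)
        tr = res.splits[0]
        stats = fg.channel_stats(small_windows, tr)
        np.testing.assert_array_equal(res.stats_mean, stats.mean)
        np.testing.assert_array_equal(res.stats_sd, stats.sd)
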