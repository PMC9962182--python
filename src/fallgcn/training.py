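"""Training protocol: splits, Adam with early stopping, repeated CV, grids.

The protocol mirrors common practice for windowed activity recognition:
windows are split 80/10/10 into train/validation/test (stratified by label),
the network minimizes cross-entropy with Adam at a fixed learning rate,
validation loss is checked once per epoch and training stops after
``patience`` checks without improvement, returning the parameters with the
best validation loss. Repeated cross-validation re-runs the whole protocol
on independent random partitions; the hyperparameter grid crosses the three
partition strategies with the neighbourhood radius MD in {1, 2} under
identical splits. Channel z-scoring statistics always come from the
training indices alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import (
    STRATEGIES,
    PartitionConfig,
    SkeletonGraph,
    build_adjacency_stack,
    build_default_graph,
)
from .metrics import MetricsReport, confusion_matrix, metrics_report
from .model import AdamOptimizer, ModelConfig, STGCN, cross_entropy
from .windowing import (
    WindowedDataset,
    channel_stats,
    normalize_channels,
    segment_many,
)

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "TrainResult",
    "ExperimentResult",
    "CVResult",
    "GridSearchResult",
    "split_dataset",
    "train",
    "run_experiment",
    "cross_validate",
    "grid_search",
    "window_sweep",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization parameters (defaults follow the reference evaluation protocol)."""

    minibatch_size: int = 128
    learning_rate: float = 1e-4
    max_epochs: int = 1000
    patience: int = 50  # validation evaluations without improvement
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if min(self.minibatch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("minibatch_size, max_epochs, patience must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (0.8/0.1/0.1 by default)."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("all split fractions must be positive")


def _bounded_allocate(counts, target, mins, caps):
    """Largest-remainder proportional allocation with per-class bounds."""
    counts = np.asarray(counts, dtype=float)
    quota = counts * target / counts.sum()
    alloc = np.clip(np.floor(quota).astype(int), mins, caps)
    frac = quota - np.floor(quota)
    while alloc.sum() < target:
        cand = np.where(alloc < caps)[0]
        if len(cand) == 0:
            break
        best = cand[np.argmax(frac[cand] - (alloc[cand] - np.floor(quota[cand])))]
        alloc[best] += 1
    while alloc.sum() > target:
        cand = np.where(alloc > mins)[0]
        best = cand[np.argmin(frac[cand] - (alloc[cand] - np.floor(quota[cand])))]
        alloc[best] -= 1
    return alloc


def split_dataset(labels, spec: SplitSpec):
    """Disjoint, exhaustive train/val/test index arrays.

    Global split sizes land within one sample of the requested fractions;
    under stratification every class appears in every split (requires at
    least 3 samples per class) and per-class proportions are matched by
    largest-remainder allocation. Deterministic given ``spec.seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    n_test = round(spec.test * n)
    n_val = round(spec.val * n)
    if not spec.stratified:
        perm = rng.permutation(n)
        return perm[n_test + n_val :], perm[n_test : n_test + n_val], perm[:n_test]
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < 3]
    if len(too_small):
        raise ValueError(
            f"stratified split needs >= 3 samples per class; offending class(es): "
            f"{too_small.tolist()}"
        )
    ones = np.ones(len(classes), dtype=int)
    a_test = _bounded_allocate(counts, n_test, ones, counts - 2)
    a_val = _bounded_allocate(counts - a_test, n_val, ones, counts - a_test - 1)
    tr, va, te = [], [], []
    for c, cls in enumerate(classes):
        idx = rng.permutation(np.where(labels == cls)[0])
        te.append(idx[: a_test[c]])
        va.append(idx[a_test[c] : a_test[c] + a_val[c]])
        tr.append(idx[a_test[c] + a_val[c] :])
    return (
        np.sort(np.concatenate(tr)),
        np.sort(np.concatenate(va)),
        np.sort(np.concatenate(te)),
    )


@dataclass
class TrainResult:
    """Best parameters plus the per-epoch loss trace."""

    model: STGCN
    history: pd.DataFrame  # epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float
    stopped_epoch: int


def train(
    model: STGCN,
    x_train,
    y_train,
    x_val,
    y_val,
    cfg: TrainConfig,
) -> TrainResult:
    """Minimize cross-entropy with Adam; early-stop on validation loss.

    Validation loss is evaluated once per epoch; after ``patience``
    evaluations without a new best the loop stops and the best snapshot is
    restored into the model. Identical seeds and data give identical final
    parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(model.params, lr=cfg.learning_rate)
    n = len(y_train)
    best_snap = model.snapshot()
    best_val = np.inf
    best_epoch = 0
    since_best = 0
    rows = []
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.minibatch_size):
            sel = order[start : start + cfg.minibatch_size]
            loss, grads = model.loss_and_gradients(x_train[sel], y_train[sel])
            opt.step(model.params, grads)
            batch_losses.append(loss)
        val_probs = model.predict_proba(x_val)
        val_loss = cross_entropy(val_probs, y_val)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
            }
        )
        if cfg.verbose:
            print(
                f"epoch {epoch:4d}  train {rows[-1]['train_loss']:.4f}  "
                f"val {val_loss:.4f}"
            )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_snap = model.snapshot()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.restore(best_snap)
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        stopped_epoch=epoch,
    )


@dataclass
class ExperimentResult:
    """One full split -> normalize -> train -> test evaluation."""

    report: MetricsReport
    train_result: TrainResult
    classes: np.ndarray
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    stats_mean: np.ndarray
    stats_sd: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray


def run_experiment(
    windows: WindowedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_spec: SplitSpec,
    graph: SkeletonGraph | None = None,
    model_seed: int | None = None,
) -> ExperimentResult:
    """The standard pipeline on an already-windowed dataset.

    Splits the windows, z-scores channels with training-split statistics,
    builds the classifier for the configured partition, trains with early
    stopping and reports test-split metrics (labels are the original
    activity ids).
    """
    graph = graph or build_default_graph()
    classes = np.unique(windows.labels)
    if len(classes) != model_config.num_classes:
        model_config = replace(model_config, num_classes=len(classes))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in windows.labels])
    tr, va, te = split_dataset(windows.labels, split_spec)
    stats = channel_stats(windows, tr)
    normed = normalize_channels(windows, stats)
    x = normed.tensor
    stack = build_adjacency_stack(graph, model_config.partition)
    model = STGCN(
        model_config,
        stack,
        seed=train_config.seed if model_seed is None else model_seed,
    )
    result = train(model, x[tr], y[tr], x[va], y[va], train_config)
    pred_idx = model.predict(x[te])
    y_true = classes[y[te]]
    y_pred = classes[pred_idx]
    cm = confusion_matrix(y_true, y_pred, class_ids=classes.tolist())
    report = metrics_report(cm)
    return ExperimentResult(
        report=report,
        train_result=result,
        classes=classes,
        splits=(tr, va, te),
        stats_mean=stats.mean,
        stats_sd=stats.sd,
        y_true=y_true,
        y_pred=y_pred,
    )


@dataclass
class CVResult:
    """Per-round reports and their mean/sd summary."""

    reports: list[MetricsReport]
    summary: pd.DataFrame  # rows mean/sd, columns accuracy..f1


def cross_validate(
    windows: WindowedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_spec: SplitSpec,
    rounds: int = 10,
    graph: SkeletonGraph | None = None,
) -> CVResult:
    """Monte-Carlo cross-validation: independent random partitions per round.

    Each round re-splits with a seed derived from the base seed, retrains and
    evaluates on its own test split; the summary is the unweighted mean and
    standard deviation over rounds.
    """
    seeds = np.random.SeedSequence(split_spec.seed).generate_state(rounds) % (2**31)
    reports = []
    for r in range(rounds):
        spec_r = replace(split_spec, seed=int(seeds[r]))
        cfg_r = replace(train_config, seed=int(seeds[r]))
        reports.append(
            run_experiment(windows, model_config, cfg_r, spec_r, graph).report
        )
    frame = pd.DataFrame([rep.summary() for rep in reports])
    summary = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)}).T
    return CVResult(reports=reports, summary=summary)


@dataclass
class GridSearchResult:
    """Accuracy per (MD, strategy) cell plus the winning combination."""

    table: pd.DataFrame  # rows MD, columns strategies, accuracy in percent
    best: tuple[str, int]
    reports: dict[tuple[str, int], MetricsReport]


def grid_search(
    windows: WindowedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_spec: SplitSpec,
    strategies=STRATEGIES,
    max_distances=(1, 2),
    graph: SkeletonGraph | None = None,
) -> GridSearchResult:
    """Cross partition strategy with MD under identical splits and seeds."""
    reports = {}
    table = pd.DataFrame(
        index=pd.Index(list(max_distances), name="MD"),
        columns=pd.Index(list(strategies), name="strategy"),
        dtype=float,
    )
    for md in max_distances:
        for strat in strategies:
            cfg = replace(
                model_config,
                partition=PartitionConfig(strategy=strat, max_distance=md),
            )
            res = run_experiment(windows, cfg, train_config, split_spec, graph)
            reports[(strat, md)] = res.report
            table.loc[md, strat] = res.report.accuracy
    best_pos = np.unravel_index(np.nanargmax(table.values), table.shape)
    best = (table.columns[best_pos[1]], int(table.index[best_pos[0]]))
    return GridSearchResult(table=table, best=best, reports=reports)


def window_sweep(
    sequences,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_spec: SplitSpec,
    window_secs=(1.0, 2.0, 3.0),
    overlap_frac: float = 0.5,
    graph: SkeletonGraph | None = None,
) -> pd.DataFrame:
    """Accuracy/precision/recall/F1 for each window size at 50% overlap."""
    rows = []
    for wsec in window_secs:
        windows = segment_many(
            sequences, wsec, overlap_frac=overlap_frac, drop_background=True
        )
        res = run_experiment(windows, model_config, train_config, split_spec, graph)
        rows.append({"window_sec": wsec, **res.report.summary()})
    return pd.DataFrame(rows).set_index("window_sec")
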