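"""Spatial-temporal graph convolutional classifier for windowed IMU tensors.

The network consumes batches shaped (samples, channels, frames, nodes). Each
of its residual blocks applies, in order: a spatial graph convolution over
the partitioned skeleton adjacency (one weight map per partition subset),
batch normalization, ReLU, a 1-D temporal convolution along frames, a second
batch normalization and dropout; the block input is added back (through a
1x1 channel projection when the channel counts differ) before a final ReLU.
Global average pooling over frames and nodes feeds a linear softmax head.

Everything is implemented directly on NumPy arrays, with hand-derived
analytic gradients for every layer (validated against finite differences in
the test suite) so training runs on a plain CPU stack. The spatial
convolution computes, per frame,

    out = sum_k (X A_k) W_k

where ``A_k`` are the normalized subset adjacency matrices and ``W_k`` the
per-subset channel maps. Internally features are held frames/nodes-first
(batch, frames, nodes, channels) so that both convolutions collapse into
single GEMM calls: the spatial convolution contracts against the fused
kernel M[(m,c),(n,o)] = sum_k A_k[m,n] W_k[c,o], and the temporal
convolution runs on an im2col layout with symmetric zero padding.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numba import njit

from .graph import AdjacencyStack, PartitionConfig, build_adjacency_stack

__all__ = [
    "ModelConfig",
    "STGCN",
    "AdamOptimizer",
    "cross_entropy",
    "tree_iter",
    "spatial_graph_conv",
    "temporal_conv",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference fall-detection configuration: 11 activity
    classes, 6 input channels (tri-axial accelerometer + gyroscope), five
    blocks of 32 output channels each. The temporal kernel length and dropout
    rate are open choices exposed here; the default 5-frame kernel covers
    about 0.3 s at 18 Hz, matching the temporal receptive field (in seconds)
    of the reference skeleton architecture at video frame rates, and the
    five-block stack widens coverage to over a second.
    """

    num_classes: int = 11
    in_channels: int = 6
    block_channels: tuple[int, ...] = (32, 32, 32, 32, 32)
    temporal_kernel: int = 5
    dropout: float = 0.5
    partition: PartitionConfig = field(default_factory=PartitionConfig)

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.block_channels) < 1:
            raise ValueError("need at least one block")
        if self.temporal_kernel % 2 != 1:
            raise ValueError("temporal kernel must be odd for symmetric padding")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


# ---------------------------------------------------------------------------
# layer primitives (forward + analytic backward); features are (B, T, N, C)
# ---------------------------------------------------------------------------

def _fuse_sgc_kernel(A, W):
    # A (K,M,N), W (K,C,O) -> M[(m,c),(n,o)]
    K, M, N = A.shape
    _, C, O = W.shape
    fused = np.einsum("kmn,kco->mcno", A, W, optimize=True)
    return fused.reshape(M * C, N * O)


def _sgc_forward(x, A, W):
    B, T, M, C = x.shape
    N = A.shape[2]
    O = W.shape[2]
    fused = _fuse_sgc_kernel(A, W)
    y = (x.reshape(B * T, M * C) @ fused).reshape(B, T, N, O)
    return y, fused


def _sgc_backward(dy, A, W, fused, x):
    B, T, M, C = x.shape
    N, O = dy.shape[2], dy.shape[3]
    dy2 = dy.reshape(B * T, N * O)
    x2 = x.reshape(B * T, M * C)
    dfused = (x2.T @ dy2).reshape(M, C, N, O)
    dW = np.einsum("kmn,mcno->kco", A, dfused, optimize=True)
    dx = (dy2 @ fused.T).reshape(B, T, M, C)
    return dx, dW


# Fused elementwise kernels: once the GEMMs run at BLAS speed, batch norm
# and the dropout/residual/ReLU tail dominate wall time, so each chain is a
# single memory pass instead of a stack of NumPy temporaries.

@njit(cache=True)
def _nb_colstats(x2):
    m, c = x2.shape
    s = np.zeros(c, np.float64)
    ss = np.zeros(c, np.float64)
    for i in range(m):
        for j in range(c):
            v = np.float64(x2[i, j])
            s[j] += v
            ss[j] += v * v
    mean = s / m
    return mean, ss / m - mean * mean


@njit(cache=True)
def _nb_bn_apply(x2, mu, inv, gamma, beta, xhat2, y2):
    m, c = x2.shape
    for i in range(m):
        for j in range(c):
            xh = (x2[i, j] - mu[j]) * inv[j]
            xhat2[i, j] = xh
            y2[i, j] = gamma[j] * xh + beta[j]


@njit(cache=True)
def _nb_bn_reduce(dy2, xhat2):
    m, c = dy2.shape
    dgamma = np.zeros(c, np.float64)
    dbeta = np.zeros(c, np.float64)
    for i in range(m):
        for j in range(c):
            dgamma[j] += np.float64(dy2[i, j]) * np.float64(xhat2[i, j])
            dbeta[j] += np.float64(dy2[i, j])
    return dgamma, dbeta


@njit(cache=True)
def _nb_bn_dx(dy2, xhat2, scale, dbeta_m, dgamma_m, dx2):
    m, c = dy2.shape
    for i in range(m):
        for j in range(c):
            dx2[i, j] = scale[j] * (
                dy2[i, j] - dbeta_m[j] - xhat2[i, j] * dgamma_m[j]
            )


def _bn_forward(x, gamma, beta, rmean, rvar, training):
    c = x.shape[-1]
    x2 = x.reshape(-1, c)
    if training:
        mu, var = _nb_colstats(x2)
        rmean *= 1.0 - _BN_MOMENTUM
        rmean += _BN_MOMENTUM * mu
        rvar *= 1.0 - _BN_MOMENTUM
        rvar += _BN_MOMENTUM * var
    else:
        mu, var = rmean, rvar
    inv = (1.0 / np.sqrt(var + _BN_EPS)).astype(x.dtype)
    xhat = np.empty_like(x)
    y = np.empty_like(x)
    _nb_bn_apply(
        x2, mu.astype(x.dtype), inv, gamma, beta,
        xhat.reshape(-1, c), y.reshape(-1, c),
    )
    return y, (xhat, inv, gamma, training)


def _bn_backward(dy, cache):
    xhat, inv, gamma, training = cache
    c = dy.shape[-1]
    dy2 = np.ascontiguousarray(dy).reshape(-1, c)
    dgamma64, dbeta64 = _nb_bn_reduce(dy2, xhat.reshape(-1, c))
    dgamma = dgamma64.astype(dy.dtype)
    dbeta = dbeta64.astype(dy.dtype)
    scale = gamma * inv
    dx = np.empty_like(dy)
    if training:
        m = dy2.shape[0]
        _nb_bn_dx(
            dy2, xhat.reshape(-1, c), scale,
            dbeta / m, dgamma / m, dx.reshape(-1, c),
        )
    else:
        np.multiply(dy, scale, out=dx)
    return dx, dgamma, dbeta


@njit(cache=True)
def _nb_drop_res_relu(hf, uf, keep, rf, of):
    # flat views: out = relu(dropout(h) + residual)
    for i in range(hf.size):
        v = hf[i] / keep if uf[i] < keep else 0.0
        p = v + rf[i]
        of[i] = p if p > 0 else 0.0


@njit(cache=True)
def _nb_drop_res_relu_bwd(df, of, uf, keep, dpf, dhf):
    for i in range(df.size):
        g = df[i] if of[i] > 0 else 0.0
        dpf[i] = g
        dhf[i] = g / keep if uf[i] < keep else 0.0


@njit(cache=True)
def _nb_im2col(xp, col, T, kt):
    # col[b,t,n, tau*C + c] = xp[b, t+tau, n, c]
    B, Tp, N, C = xp.shape
    for b in range(B):
        for t in range(T):
            for n in range(N):
                for tau in range(kt):
                    off = tau * C
                    for c in range(C):
                        col[b, t, n, off + c] = xp[b, t + tau, n, c]


@njit(cache=True)
def _nb_col2im(dcol, dxp, T, kt):
    B, Tp, N, C = dxp.shape
    for b in range(B):
        for t in range(T):
            for n in range(N):
                for tau in range(kt):
                    off = tau * C
                    for c in range(C):
                        dxp[b, t + tau, n, c] += dcol[b, t, n, off + c]


def _tconv_forward(x, kern):
    # x (B,T,N,C), kern (O,C,kt) -> (B,T,N,O); zero padding keeps T
    B, T, N, C = x.shape
    O, _, kt = kern.shape
    pad = kt // 2
    xp = np.zeros((B, T + 2 * pad, N, C), dtype=x.dtype)
    xp[:, pad : pad + T] = x
    col = np.empty((B, T, N, kt * C), dtype=x.dtype)
    _nb_im2col(xp, col, T, kt)
    col2 = col.reshape(B * T * N, kt * C)
    wm = kern.transpose(2, 1, 0).reshape(kt * C, O)
    y = (col2 @ wm).reshape(B, T, N, O)
    return y, col2


def _tconv_backward(dy, kern, col2, x_shape):
    B, T, N, C = x_shape
    O, _, kt = kern.shape
    pad = kt // 2
    g2 = dy.reshape(B * T * N, O)
    dW = (col2.T @ g2).reshape(kt, C, O).transpose(2, 1, 0)
    wm = kern.transpose(2, 1, 0).reshape(kt * C, O)
    dcol = (g2 @ wm.T).reshape(B, T, N, kt * C)
    dxp = np.zeros((B, T + 2 * pad, N, C), dtype=dy.dtype)
    _nb_col2im(dcol, dxp, T, kt)
    return dxp[:, pad : pad + T], np.ascontiguousarray(dW)


def _apply_channels_first(x, fn):
    """Run a channels-last layer on (C,T,N) or (B,C,T,N) input."""
    x = np.asarray(x, dtype=np.float64)
    batched = x.ndim == 4
    if not batched:
        x = x[None]
    y = fn(np.ascontiguousarray(x.transpose(0, 2, 3, 1)))
    y = y.transpose(0, 3, 1, 2)
    return y if batched else y[0]


def spatial_graph_conv(features, stack: AdjacencyStack, weights) -> np.ndarray:
    """Partitioned spatial graph convolution sum_k (X A_k) W_k, per frame.

    ``features`` is (channels, frames, nodes) or batched with a leading
    sample axis; ``weights`` holds one (in, out) channel map per subset,
    shape (K, C_in, C_out).
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != stack.K:
        raise ValueError(
            f"got {weights.shape[0]} weight maps for {stack.K} adjacency subsets"
        )
    A = stack.subsets.astype(np.float64)
    return _apply_channels_first(features, lambda xl: _sgc_forward(xl, A, weights)[0])


def temporal_conv(features, kernel) -> np.ndarray:
    """1-D convolution along frames with symmetric zero padding (stride 1).

    ``kernel`` has shape (C_out, C_in, taps); frame count is preserved.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    return _apply_channels_first(features, lambda xl: _tconv_forward(xl, kernel)[0])


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer targets under probability rows."""
    p = probs[np.arange(len(y)), y]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


def tree_iter(params, prefix=()) -> Iterator[tuple[tuple, np.ndarray]]:
    """Yield (path, array) for every array in a nested dict/list container."""
    if isinstance(params, dict):
        for k in sorted(params):
            yield from tree_iter(params[k], prefix + (k,))
    elif isinstance(params, (list, tuple)):
        for i, v in enumerate(params):
            yield from tree_iter(v, prefix + (i,))
    elif params is not None:
        yield prefix, params


def _tree_get(params, path):
    node = params
    for k in path:
        node = node[k]
    return node


def _tree_set(params, path, value):
    node = params
    for k in path[:-1]:
        node = node[k]
    node[path[-1]] = value


class STGCN:
    """The classifier: parameters, forward pass and analytic gradients.

    Parameters live in ``self.params`` (trainable arrays) and ``self.state``
    (batch-norm running statistics); both are plain nested dicts of NumPy
    arrays, so snapshots for early stopping are deep copies and checkpoints
    are flat npz archives.
    """

    def __init__(
        self,
        config: ModelConfig,
        stack: AdjacencyStack,
        seed: int = 0,
        dtype=np.float32,
    ):
        if stack.K != config.partition.num_subsets:
            raise ValueError(
                f"adjacency stack has K={stack.K} subsets but the partition "
                f"config implies {config.partition.num_subsets}"
            )
        self.config = config
        self.dtype = dtype
        self.A = stack.subsets.astype(dtype)
        self.n_nodes = stack.n_nodes
        self._rng = np.random.default_rng(seed)
        self.params, self.state = self._init_params(self._rng)

    @classmethod
    def from_graph(cls, config: ModelConfig, graph, seed: int = 0, dtype=np.float32):
        return cls(config, build_adjacency_stack(graph, config.partition), seed, dtype)

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng):
        cfg = self.config
        K = self.A.shape[0]
        kt = cfg.temporal_kernel

        def he(shape, fan_in):
            lim = np.sqrt(6.0 / fan_in)
            return rng.uniform(-lim, lim, size=shape).astype(self.dtype)

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(self.dtype)

        blocks, bstate = [], []
        cin = cfg.in_channels
        for cout in cfg.block_channels:
            blocks.append(
                {
                    "W": he((K, cin, cout), fan_in=cin * K),
                    "tk": he((cout, cout, kt), fan_in=cout * kt),
                    "res": None if cin == cout else glorot((cin, cout), cin, cout),
                    "bn1_gamma": np.ones(cout, self.dtype),
                    "bn1_beta": np.zeros(cout, self.dtype),
                    "bn2_gamma": np.ones(cout, self.dtype),
                    "bn2_beta": np.zeros(cout, self.dtype),
                }
            )
            bstate.append(
                {
                    "bn1_mean": np.zeros(cout, np.float64),
                    "bn1_var": np.ones(cout, np.float64),
                    "bn2_mean": np.zeros(cout, np.float64),
                    "bn2_var": np.ones(cout, np.float64),
                }
            )
            cin = cout
        params = {
            "blocks": blocks,
            "head_W": glorot((cin, cfg.num_classes), cin, cfg.num_classes),
            "head_b": np.zeros(cfg.num_classes, self.dtype),
        }
        return params, {"blocks": bstate}

    @property
    def n_parameters(self) -> int:
        return sum(int(a.size) for _, a in tree_iter(self.params))

    def snapshot(self):
        return copy.deepcopy(self.params), copy.deepcopy(self.state)

    def restore(self, snap) -> None:
        self.params, self.state = copy.deepcopy(snap[0]), copy.deepcopy(snap[1])

    # -- forward / backward -------------------------------------------------

    def _block_forward(self, x, bp, bs, training, want_cache):
        y_sgc, fused = _sgc_forward(x, self.A, bp["W"])
        h1, c_bn1 = _bn_forward(
            y_sgc, bp["bn1_gamma"], bp["bn1_beta"], bs["bn1_mean"], bs["bn1_var"], training
        )
        r = np.maximum(h1, 0)
        t, col = _tconv_forward(r, bp["tk"])
        h2, c_bn2 = _bn_forward(
            t, bp["bn2_gamma"], bp["bn2_beta"], bs["bn2_mean"], bs["bn2_var"], training
        )
        if bp["res"] is None:
            res = x
        else:
            B, T, N, C = x.shape
            res = (x.reshape(-1, C) @ bp["res"]).reshape(B, T, N, -1)
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            u = self._rng.random(h2.shape, dtype=h2.dtype)
            out = np.empty_like(h2)
            res_c = np.ascontiguousarray(res)
            _nb_drop_res_relu(h2.ravel(), u.ravel(), keep, res_c.ravel(), out.ravel())
            drop = (u, keep)
        else:
            drop = None
            out = np.maximum(h2 + res, 0)
        cache = None
        if want_cache:
            cache = (fused, x, c_bn1, h1 > 0, col, r.shape, c_bn2, drop, out)
        return out, cache

    def _block_backward(self, dout, bp, cache):
        fused, x, c_bn1, relu1, col, r_shape, c_bn2, drop, out = cache
        if drop is not None:
            u, keep = drop
            dout_c = np.ascontiguousarray(dout)
            dpre = np.empty_like(dout_c)
            dh2 = np.empty_like(dout_c)
            _nb_drop_res_relu_bwd(
                dout_c.ravel(), out.ravel(), u.ravel(), keep, dpre.ravel(), dh2.ravel()
            )
        else:
            dpre = dout * (out > 0)
            dh2 = dpre
        if bp["res"] is None:
            dx_res, dres = dpre, None
        else:
            B, T, N, C = x.shape
            O = dpre.shape[3]
            dres = x.reshape(-1, C).T @ dpre.reshape(-1, O)
            dx_res = (dpre.reshape(-1, O) @ bp["res"].T).reshape(B, T, N, C)
        dt, dg2, db2 = _bn_backward(dh2, c_bn2)
        dr, dtk = _tconv_backward(dt, bp["tk"], col, r_shape)
        dh1 = dr * relu1
        dsgc, dg1, db1 = _bn_backward(dh1, c_bn1)
        dx, dW = _sgc_backward(dsgc, self.A, bp["W"], fused, x)
        dx += dx_res
        grads = {
            "W": dW,
            "tk": dtk,
            "res": dres,
            "bn1_gamma": dg1,
            "bn1_beta": db1,
            "bn2_gamma": dg2,
            "bn2_beta": db2,
        }
        return dx, grads

    def _forward(self, x, training, want_cache):
        x = np.asarray(x)
        if x.shape[1] != self.config.in_channels:
            raise ValueError("channel count mismatch with model config")
        if x.shape[3] != self.n_nodes:
            raise ValueError("node count mismatch with adjacency stack")
        # public layout (B, C, T, N) -> internal channels-last (B, T, N, C)
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=self.dtype)
        caches = []
        for bp, bs in zip(self.params["blocks"], self.state["blocks"]):
            h, c = self._block_forward(h, bp, bs, training, want_cache)
            caches.append(c)
        gap = h.mean(axis=(1, 2))
        logits = gap @ self.params["head_W"] + self.params["head_b"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (caches, gap, h.shape)

    def forward(self, x, training: bool = False) -> np.ndarray:
        """Class probabilities for a batch (rows sum to one)."""
        probs, _ = self._forward(x, training, want_cache=False)
        return probs

    def predict_proba(self, x, batch_size: int = 512) -> np.ndarray:
        """Evaluation-mode probabilities computed in minibatches."""
        out = []
        for start in range(0, len(x), batch_size):
            out.append(self.forward(x[start : start + batch_size], training=False))
        return np.concatenate(out, axis=0)

    def predict(self, x, classes=None, batch_size: int = 512) -> np.ndarray:
        idx = self.predict_proba(x, batch_size).argmax(axis=1)
        return idx if classes is None else np.asarray(classes)[idx]

    def loss_and_gradients(self, x, y):
        """Cross-entropy loss and analytic gradients (training mode).

        ``y`` holds class indices 0..num_classes-1. Raises on a non-finite
        loss so a diverging run aborts with a diagnostic instead of training
        on garbage.
        """
        y = np.asarray(y)
        probs, (caches, gap, h_shape) = self._forward(x, training=True, want_cache=True)
        loss = cross_entropy(probs, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss ({loss}); check learning rate and inputs"
            )
        B = len(y)
        dlogits = probs.astype(self.dtype).copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {
            "head_W": gap.T @ dlogits,
            "head_b": dlogits.sum(axis=0),
            "blocks": [None] * len(caches),
        }
        dgap = dlogits @ self.params["head_W"].T
        _, T, N, _ = h_shape
        dh = np.broadcast_to(
            dgap[:, None, None, :] / (T * N), h_shape
        ).astype(self.dtype)
        for b in range(len(caches) - 1, -1, -1):
            dh, g = self._block_backward(dh, self.params["blocks"][b], caches[b])
            grads["blocks"][b] = g
        return loss, grads

    # -- persistence --------------------------------------------------------

    def save(self, path, extra: dict | None = None) -> None:
        """Write weights, running stats and architecture metadata to one npz."""
        import json

        arrays = {}
        for p, a in tree_iter(self.params):
            arrays["param:" + "/".join(map(str, p))] = a
        for p, a in tree_iter(self.state):
            arrays["state:" + "/".join(map(str, p))] = a
        arrays["adjacency"] = self.A
        meta = {
            "num_classes": self.config.num_classes,
            "in_channels": self.config.in_channels,
            "block_channels": list(self.config.block_channels),
            "temporal_kernel": self.config.temporal_kernel,
            "dropout": self.config.dropout,
            "strategy": self.config.partition.strategy,
            "max_distance": self.config.partition.max_distance,
        }
        if extra:
            meta["extra"] = extra
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            config = ModelConfig(
                num_classes=meta["num_classes"],
                in_channels=meta["in_channels"],
                block_channels=tuple(meta["block_channels"]),
                temporal_kernel=meta["temporal_kernel"],
                dropout=meta["dropout"],
                partition=PartitionConfig(meta["strategy"], meta["max_distance"]),
            )
            stack = AdjacencyStack(np.asarray(data["adjacency"], dtype=np.float64))
            model = cls(config, stack)
            for key in data.files:
                if key.startswith(("param:", "state:")):
                    kind, path_s = key.split(":", 1)
                    parts = tuple(
                        int(s) if s.isdigit() else s for s in path_s.split("/")
                    )
                    target = model.params if kind == "param" else model.state
                    _tree_set(target, parts, np.asarray(data[key]))
            extra = meta.get("extra")
        return model, extra


class AdamOptimizer:
    """Adam with bias correction over a nested parameter tree."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {p: np.zeros_like(a) for p, a in tree_iter(params)}
        self.v = {p: np.zeros_like(a) for p, a in tree_iter(params)}

    def step(self, params, grads) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for path, g in tree_iter(grads):
            p = _tree_get(params, path)
            m = self.m[path]
            v = self.v[path]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
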