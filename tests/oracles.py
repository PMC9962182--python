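"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (queue-based BFS, explicit loops) and
shares no code with the package implementation paths it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bfs_hops(n_nodes: int, edges) -> np.ndarray:
    """All-pairs hop distances by breadth-first search; -1 if unreachable."""
    adj = {i: [] for i in range(n_nodes)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    out = np.full((n_nodes, n_nodes), -1, dtype=int)
    for src in range(n_nodes):
        out[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if out[src, v] < 0:
                    out[src, v] = out[src, u] + 1
                    q.append(v)
    return out


def is_connected(n_nodes: int, edges) -> bool:
    return (bfs_hops(n_nodes, edges) >= 0).all()


def brute_force_labels(n_nodes, edges, center, strategy, md):
    """Subset label per ordered (root, neighbour) pair, straight from the rules."""
    hops = bfs_hops(n_nodes, edges)
    labels = {}
    for i in range(n_nodes):
        for j in range(n_nodes):
            h = hops[i, j]
            if h < 0 or h > md:
                continue
            if strategy == "uni-labeling":
                labels[(i, j)] = 0
            elif strategy == "distance":
                labels[(i, j)] = int(h)
            elif strategy == "spatial-configuration":
                if hops[j, center] == hops[i, center]:
                    labels[(i, j)] = 0
                elif hops[j, center] < hops[i, center]:
                    labels[(i, j)] = 1
                else:
                    labels[(i, j)] = 2
            else:
                raise ValueError(strategy)
    return labels


def connected_graphs(max_nodes: int):
    """Yield (n, edge-tuple) for every connected labelled graph with n <= max_nodes."""
    for n in range(2, max_nodes + 1):
        all_edges = list(combinations(range(n), 2))
        for bits in range(1, 2 ** len(all_edges)):
            edges = tuple(e for k, e in enumerate(all_edges) if bits >> k & 1)
            if is_connected(n, edges):
                yield n, edges


def brute_force_spatial_conv(x, subsets, weights):
    """Per-node/per-subset double loop: out[c_out, t, n] over labelled neighbours."""
    K, N, _ = subsets.shape
    _, C, O = weights.shape
    Cx, T, Nx = x.shape
    out = np.zeros((O, T, Nx))
    for k in range(K):
        for t in range(T):
            for n in range(Nx):
                for m in range(Nx):
                    a = subsets[k, m, n]
                    if a != 0:
                        out[:, t, n] += a * (weights[k].T @ x[:, t, m])
    return out


def brute_force_temporal_conv(x, kern):
    """Naive sliding dot product along frames with symmetric zero padding."""
    O, C, kt = kern.shape
    Cx, T, N = x.shape
    pad = kt // 2
    out = np.zeros((O, T, N))
    for o in range(O):
        for t in range(T):
            for n in range(N):
                acc = 0.0
                for tau in range(kt):
                    src = t + tau - pad
                    if 0 <= src < T:
                        acc += float(kern[o, :, tau] @ x[:, src, n])
                out[o, t, n] = acc
    return out
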