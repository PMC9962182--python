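"""Skeleton graph over body-worn sensor placements and its partitioned adjacency.

The fall-detection skeleton is a small undirected graph whose nodes are the
IMU placements on the body (left ankle, right trouser pocket, waist, neck,
left wrist by default) and whose edges follow the natural anatomical chain
through the trunk. Spatial graph convolution operates on a *partition* of
each node's hop-neighbourhood into K subsets; each subset contributes one
normalized adjacency matrix, and the stack of those matrices is the kernel
support of the convolution.

Three partition strategies are supported:

``uni-labeling``
    every neighbour (including the node itself) shares one label; K = 1.
``distance``
    neighbours are labelled by their hop distance to the root node;
    K = MD + 1 where MD is the maximum neighbourhood hop distance.
``spatial-configuration``
    neighbours are labelled root / centripetal / centrifugal by comparing
    their hop distance to the skeleton's gravity-centre node against the
    root's own distance; K = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "SkeletonGraph",
    "PartitionConfig",
    "AdjacencyStack",
    "STRATEGIES",
    "build_default_graph",
    "load_graph_yaml",
    "save_graph_yaml",
    "hop_distances",
    "partition_labels",
    "build_adjacency_stack",
    "normalize_subset",
]

#: canonical strategy names
UNI = "uni-labeling"
DISTANCE = "distance"
SPATIAL = "spatial-configuration"
STRATEGIES = (UNI, DISTANCE, SPATIAL)

_STRATEGY_ALIASES = {
    "uni-labeling": UNI,
    "uni_labeling": UNI,
    "unilabeling": UNI,
    "uniform": UNI,
    "distance": DISTANCE,
    "spatial-configuration": SPATIAL,
    "spatial_configuration": SPATIAL,
    "spatial configuration": SPATIAL,
    "spatial": SPATIAL,
}


def canonical_strategy(name: str) -> str:
    try:
        return _STRATEGY_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown partition strategy {name!r}; expected one of {STRATEGIES}"
        ) from None


@dataclass(frozen=True)
class SkeletonGraph:
    """Undirected connected body graph with a designated gravity-centre node.

    Nodes are identified by position 0..N-1 in ``node_names``; ``edges`` hold
    unordered pairs of node ids, and ``center`` is the node used as the proxy
    for the skeleton's centre of gravity (the waist by default).
    """

    node_names: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    center: int

    def __post_init__(self) -> None:
        n = len(self.node_names)
        if n < 2:
            raise ValueError("skeleton needs at least 2 nodes")
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i} is not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references unknown node")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))
        if not (0 <= self.center < n):
            raise ValueError(f"center node {self.center} out of range")
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("skeleton graph must be connected")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.node_names)))
        g.add_edges_from(self.edges)
        return g

    def relabel(self, perm: Iterable[int]) -> "SkeletonGraph":
        """Apply a node permutation: new id ``perm[i]`` is old id ``i``."""
        perm = list(perm)
        names = [""] * len(perm)
        for old, new in enumerate(perm):
            names[new] = self.node_names[old]
        edges = frozenset((perm[i], perm[j]) for i, j in self.edges)
        return SkeletonGraph(tuple(names), edges, perm[self.center])


#: default placements, in sensor order S1..S5
DEFAULT_PLACEMENTS = (
    "left_ankle",
    "right_pocket",
    "waist",
    "neck",
    "left_wrist",
)
# anatomical chain ankle - thigh(pocket) - waist - neck - wrist
DEFAULT_EDGES = ((0, 1), (1, 2), (2, 3), (3, 4))
DEFAULT_CENTER = 2  # waist


def build_default_graph() -> SkeletonGraph:
    """Five-node skeleton for the default sensor placements S1..S5."""
    return SkeletonGraph(
        DEFAULT_PLACEMENTS,
        frozenset(DEFAULT_EDGES),
        DEFAULT_CENTER,
    )


def load_graph_yaml(path=None) -> SkeletonGraph:
    """Load a skeleton description from YAML (the packaged default if no path).

    The file lists ``nodes`` (ordered names), ``edges`` (pairs of names) and
    ``center`` (a node name).
    """
    if path is None:
        text = (
            resources.files("fallgcn.data").joinpath("default_skeleton.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    names = tuple(str(x) for x in doc["nodes"])
    idx = {name: i for i, name in enumerate(names)}
    edges = frozenset((idx[a], idx[b]) for a, b in doc["edges"])
    return SkeletonGraph(names, edges, idx[doc["center"]])


def save_graph_yaml(graph: SkeletonGraph, path) -> None:
    doc = {
        "nodes": list(graph.node_names),
        "edges": sorted(
            [graph.node_names[i], graph.node_names[j]] for i, j in graph.edges
        ),
        "center": graph.node_names[graph.center],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def hop_distances(graph: SkeletonGraph) -> np.ndarray:
    """All-pairs geodesic hop counts as an N x N integer matrix.

    Raises ``ValueError`` for a disconnected skeleton (the SkeletonGraph
    constructor already enforces connectivity; this guards graphs built
    through other routes).
    """
    g = graph.to_networkx()
    n = graph.n_nodes
    out = np.full((n, n), -1, dtype=np.int64)
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            out[src, dst] = d
    if (out < 0).any():
        raise ValueError("skeleton graph is disconnected")
    return out


@dataclass(frozen=True)
class PartitionConfig:
    """Neighbourhood partition hyperparameters: strategy (PS) and max hop (MD)."""

    strategy: str = SPATIAL
    max_distance: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", canonical_strategy(self.strategy))
        if self.max_distance < 1:
            raise ValueError("max_distance (MD) must be >= 1")

    @property
    def num_subsets(self) -> int:
        if self.strategy == UNI:
            return 1
        if self.strategy == DISTANCE:
            return self.max_distance + 1
        return 3

    @property
    def subset_labels(self) -> tuple[str, ...]:
        if self.strategy == UNI:
            return ("neighbourhood",)
        if self.strategy == DISTANCE:
            return tuple(f"hop-{d}" for d in range(self.max_distance + 1))
        return ("root", "centripetal", "centrifugal")


def partition_labels(
    graph: SkeletonGraph, config: PartitionConfig
) -> dict[tuple[int, int], int]:
    """Subset label for every ordered (root i, neighbour j) pair with hop <= MD.

    Pairs beyond the MD neighbourhood are absent from the mapping. Under
    spatial configuration the root's self-pair lands in subset 0 (equal
    distance to the centre), matching the root/centripetal/centrifugal rule.
    """
    hops = hop_distances(graph)
    md = config.max_distance
    labels: dict[tuple[int, int], int] = {}
    for i in range(graph.n_nodes):
        for j in range(graph.n_nodes):
            h = int(hops[i, j])
            if h > md:
                continue
            if config.strategy == UNI:
                labels[(i, j)] = 0
            elif config.strategy == DISTANCE:
                labels[(i, j)] = h
            else:
                dc_root = hops[i, graph.center]
                dc_nb = hops[j, graph.center]
                if dc_nb == dc_root:
                    labels[(i, j)] = 0
                elif dc_nb < dc_root:
                    labels[(i, j)] = 1
                else:
                    labels[(i, j)] = 2
    return labels


@dataclass
class AdjacencyStack:
    """K normalized N x N matrices, one per partition subset."""

    subsets: np.ndarray  # (K, N, N), float64
    subset_labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def K(self) -> int:
        return self.subsets.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.subsets.shape[1]


def normalize_subset(raw: np.ndarray, alpha: float = 1e-3) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} R D^{-1/2} of a 0/1 matrix.

    ``alpha`` is added to every diagonal degree entry so that rows with no
    support stay finite (and all-zero); with ``alpha=0`` empty rows are
    mapped to zero explicitly.
    """
    raw = np.asarray(raw, dtype=np.float64)
    deg = raw.sum(axis=1) + alpha
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return inv_sqrt[:, None] * raw * inv_sqrt[None, :]


def build_adjacency_stack(
    graph: SkeletonGraph, config: PartitionConfig, alpha: float = 1e-3
) -> AdjacencyStack:
    """Indicator matrix per subset, degree-normalized, stacked along axis 0."""
    labels = partition_labels(graph, config)
    n = graph.n_nodes
    k = config.num_subsets
    raw = np.zeros((k, n, n), dtype=np.float64)
    for (i, j), s in labels.items():
        raw[s, i, j] = 1.0
    out = np.stack([normalize_subset(raw[s], alpha=alpha) for s in range(k)])
    return AdjacencyStack(out, config.subset_labels)
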