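"""Weighted multiplex networks whose link weights encode homophily and awareness gaps.

A multiplex is a set of M undirected layers sharing one node set of size N.
Each node carries a base awareness score ``aw`` in [0, 1] and a homophily
attribute (scalar in [0, 1] or a categorical group label).  Link weights are

    w_ij = h_ij * |awbar_i - awbar_j| + 1        (on existing links)

where ``h_ij = 1 / (1 + delta_ij)`` is the homophily between the endpoints
(``delta_ij`` an attribute distance) and ``awbar`` the (possibly overlapping)
awareness score of each node.  Weights are therefore >= 1 wherever a link
exists and exactly 1 when the two endpoints have equal awareness.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "WeightedMultiplexNetwork",
    "generate_scale_free_multiplex",
    "compute_homophily",
    "attribute_distance",
    "compute_weights",
    "node_strength",
    "inverse_participation_ratio",
    "strength_matrix",
    "ipr_matrix",
    "load_multiplex",
    "write_multiplex",
]


class MultiplexFormatError(ValueError):
    """Raised when an edge-list or attribute file violates the format contract."""


@dataclass
class WeightedMultiplexNetwork:
    """N nodes shared across M undirected weighted layers.

    Parameters
    ----------
    n_nodes
        Number of nodes, identical in every layer.
    layers
        One symmetric ``scipy.sparse`` matrix per layer; a nonzero entry is a
        link and its value the link weight (>= 1 once weights are computed,
        1 on a freshly generated topology).
    aw
        Base awareness score per node, in [0, 1].
    attribute
        Homophily attribute per node: float array (scalar attribute) or
        object array (categorical group labels).
    awbar
        Overlapping awareness used for the current weights; set by
        :func:`compute_weights`, ``None`` on a freshly built topology.
    """

    n_nodes: int
    layers: list
    aw: np.ndarray
    attribute: np.ndarray
    awbar: np.ndarray | None = field(default=None)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __post_init__(self) -> None:
        self.layers = [sp.csr_matrix(w) for w in self.layers]
        self.aw = np.asarray(self.aw, dtype=float)
        self.attribute = np.asarray(self.attribute)
        if self.aw.shape != (self.n_nodes,):
            raise ValueError("aw must have one entry per node")
        if self.attribute.shape != (self.n_nodes,):
            raise ValueError("attribute must have one entry per node")
        if np.any((self.aw < 0) | (self.aw > 1)):
            raise ValueError("awareness scores must lie in [0, 1]")
        for w in self.layers:
            if w.shape != (self.n_nodes, self.n_nodes):
                raise ValueError("layer dimension does not match node count")
            if w.diagonal().any():
                raise ValueError("self-loops are not allowed")

    def edges(self, layer: int):
        """Return (i, j, w) arrays with i < j for the given layer."""
        coo = sp.triu(self.layers[layer], k=1).tocoo()
        return coo.row, coo.col, coo.data

    def adjacency(self, layer: int) -> sp.csr_matrix:
        """Binary adjacency of one layer (weights discarded)."""
        a = self.layers[layer].copy()
        a.data = np.ones_like(a.data)
        return a

    def copy(self) -> "WeightedMultiplexNetwork":
        return WeightedMultiplexNetwork(
            self.n_nodes,
            [w.copy() for w in self.layers],
            self.aw.copy(),
            self.attribute.copy(),
            None if self.awbar is None else self.awbar.copy(),
        )


def generate_scale_free_multiplex(
    n_nodes: int,
    n_layers: int,
    m: int,
    seed: int,
    aw: np.ndarray | None = None,
    attribute: np.ndarray | None = None,
) -> WeightedMultiplexNetwork:
    """Build M independent preferential-attachment (Barabási–Albert) layers.

    Every layer is grown over the same node set with ``m`` links per new
    node; link weights start at 1.  Per-layer seeds are spawned from the
    master ``seed``, so the call is fully deterministic.  When ``aw`` or
    ``attribute`` are not supplied they are drawn uniformly on [0, 1] from
    the same master seed (a convenience default; scenario code normally
    supplies population-derived values).
    """
    if m < 1 or n_nodes < m + 1:
        raise ValueError(f"need n_nodes >= m + 1 >= 2, got n_nodes={n_nodes}, m={m}")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    ss = np.random.SeedSequence(seed)
    layer_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_layers)]
    layers = []
    for ls in layer_seeds:
        g = nx.barabasi_albert_graph(n_nodes, m, seed=ls)
        a = nx.to_scipy_sparse_array(g, nodelist=range(n_nodes), format="csr")
        a = sp.csr_matrix(a, dtype=float)
        a.data[:] = 1.0
        layers.append(a)
    rng = np.random.default_rng(ss)
    if aw is None:
        aw = rng.uniform(0.0, 1.0, size=n_nodes)
    if attribute is None:
        attribute = rng.uniform(0.0, 1.0, size=n_nodes)
    return WeightedMultiplexNetwork(n_nodes, layers, aw, attribute)


def attribute_distance(attr_i, attr_j) -> float:
    """Distance delta_ij between two homophily attributes.

    Scalar attributes use the absolute difference; categorical labels use the
    discrete metric (0 if equal, 1 otherwise).
    """
    if isinstance(attr_i, (int, float, np.floating, np.integer)) and isinstance(
        attr_j, (int, float, np.floating, np.integer)
    ):
        return abs(float(attr_i) - float(attr_j))
    return 0.0 if attr_i == attr_j else 1.0


def compute_homophily(attr_i, attr_j, metric=attribute_distance) -> float:
    """Homophily h = 1 / (1 + delta_ij) in (0, 1]; 1 iff the attributes coincide."""
    delta = metric(attr_i, attr_j)
    if delta < 0:
        raise ValueError("attribute distance must be non-negative")
    return 1.0 / (1.0 + delta)


def _pairwise_homophily(attribute: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    if attribute.dtype.kind in "fiu":
        delta = np.abs(attribute[rows].astype(float) - attribute[cols].astype(float))
    else:
        delta = (attribute[rows] != attribute[cols]).astype(float)
    return 1.0 / (1.0 + delta)


def compute_weights(
    network: WeightedMultiplexNetwork, awbar: np.ndarray | None = None
) -> WeightedMultiplexNetwork:
    """Recompute every link weight as w_ij = h_ij * |awbar_i - awbar_j| + 1.

    ``awbar`` is the per-node overlapping awareness; by default the base
    ``aw`` (no correlated issues).  Negative overlapping awareness (possible
    under strong anti-correlation) is floored at 0 before taking the
    difference.  Topology is untouched; non-links keep weight 0.  Returns a
    new network with ``awbar`` recorded so that later rewiring can refresh
    the weights.
    """
    if awbar is None:
        awbar = network.aw
    awbar = np.asarray(awbar, dtype=float)
    if awbar.shape != (network.n_nodes,):
        raise ValueError("awbar must have one entry per node")
    aw_eff = np.maximum(awbar, 0.0)
    out = network.copy()
    for k, w in enumerate(out.layers):
        coo = w.tocoo()
        h = _pairwise_homophily(out.attribute, coo.row, coo.col)
        new = h * np.abs(aw_eff[coo.row] - aw_eff[coo.col]) + 1.0
        out.layers[k] = sp.csr_matrix(
            (new, (coo.row, coo.col)), shape=w.shape
        )
    out.awbar = awbar.copy()
    return out


def node_strength(network: WeightedMultiplexNetwork, i: int, layer: int) -> float:
    """Strength s_i = sum of link weights incident on node i in one layer."""
    if not (0 <= i < network.n_nodes):
        raise IndexError(f"node {i} out of range")
    return float(network.layers[layer][i].sum())


def inverse_participation_ratio(network: WeightedMultiplexNetwork, i: int, layer: int) -> float:
    """IPR Y_i = sum_j (w_ij / s_i)^2, in [1/k_i, 1].

    1/Y_i is the effective number of contacts carrying the node's weight:
    Y = 1/k for uniform weights, 1 for a single neighbour.  Isolated nodes
    are assigned Y = 1 (a single effective channel), the degenerate value
    that keeps downstream rate factors finite.
    """
    if not (0 <= i < network.n_nodes):
        raise IndexError(f"node {i} out of range")
    row = network.layers[layer][i]
    s = row.sum()
    if s == 0:
        return 1.0
    return float(((row.data / s) ** 2).sum())


def strength_matrix(network: WeightedMultiplexNetwork) -> np.ndarray:
    """N x M matrix of node strengths."""
    return np.column_stack(
        [np.asarray(w.sum(axis=1)).ravel() for w in network.layers]
    )


def ipr_matrix(network: WeightedMultiplexNetwork) -> np.ndarray:
    """N x M matrix of inverse participation ratios (isolated nodes -> 1)."""
    cols = []
    for w in network.layers:
        s = np.asarray(w.sum(axis=1)).ravel()
        sq = w.copy()
        sq.data = sq.data**2
        num = np.asarray(sq.sum(axis=1)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(s > 0, num / np.maximum(s, 1e-300) ** 2, 1.0)
        cols.append(y)
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# plain-text I/O
#
# Edge list: one record per undirected link, "i j layer [weight]", fields
# separated by whitespace or commas, 0-based ids, '#' comments allowed.
# Attributes: CSV with header (node_id, aw, attribute).


def load_multiplex(edge_list_path, attributes_path) -> WeightedMultiplexNetwork:
    """Load a multiplex from an edge-list file plus a node-attribute CSV."""
    attrs = pd.read_csv(attributes_path)
    for col in ("node_id", "aw", "attribute"):
        if col not in attrs.columns:
            raise MultiplexFormatError(f"attribute table lacks column {col!r}")
    attrs = attrs.sort_values("node_id").reset_index(drop=True)
    n = len(attrs)
    if not np.array_equal(attrs["node_id"].to_numpy(), np.arange(n)):
        raise MultiplexFormatError("node_id must be 0..N-1, each exactly once")
    aw = attrs["aw"].to_numpy(dtype=float)
    attribute = attrs["attribute"].to_numpy()
    try:
        attribute = attribute.astype(float)
    except (TypeError, ValueError):
        pass

    records: dict[int, dict[tuple[int, int], float]] = {}
    with open(edge_list_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (3, 4):
                raise MultiplexFormatError(f"line {ln}: expected 'i j layer [weight]'")
            i, j, layer = (int(p) for p in parts[:3])
            w = float(parts[3]) if len(parts) == 4 else 1.0
            if i == j:
                raise MultiplexFormatError(f"line {ln}: self-loop on node {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise MultiplexFormatError(f"line {ln}: unknown node in ({i}, {j})")
            if layer < 0:
                raise MultiplexFormatError(f"line {ln}: negative layer id")
            key = (min(i, j), max(i, j))
            bucket = records.setdefault(layer, {})
            if key in bucket:
                raise MultiplexFormatError(f"line {ln}: duplicate edge {key} in layer {layer}")
            bucket[key] = w
    if not records:
        raise MultiplexFormatError("edge list contains no links")
    m = max(records) + 1
    if sorted(records) != list(range(m)):
        raise MultiplexFormatError("layer ids must be contiguous from 0")
    layers = []
    for k in range(m):
        pairs = records.get(k, {})
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        vals = list(pairs.values()) * 2
        layers.append(sp.csr_matrix((vals, (rows, cols)), shape=(n, n)))
    return WeightedMultiplexNetwork(n, layers, aw, attribute)


def write_multiplex(network: WeightedMultiplexNetwork, edge_list_path, attributes_path) -> None:
    """Write the edge-list and attribute files in the dialect `load_multiplex` reads."""
    with open(edge_list_path, "w") as fh:
        for k in range(network.n_layers):
            rows, cols, vals = network.edges(k)
            for i, j, w in zip(rows, cols, vals):
                fh.write(f"{i} {j} {k} {w:.12g}\n")
    df = pd.DataFrame(
        {
            "node_id": np.arange(network.n_nodes),
            "aw": network.aw,
            "attribute": network.attribute,
        }
    )
    df.to_csv(attributes_path, index=False)
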