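"""Simultaneous node/layer centrality on a weighted multiplex, plus rewiring.

Nodes and layers are ranked together by a coupled fixed-point iteration in
the spirit of multiplex PageRank-style schemes: a node is central when it is
active in influential layers, and a layer is influential when its (weighted)
links connect central nodes.  Concretely, from uniform starts,

    X  <-  normalize( sum_a z^a W^a X + c / N )
    z^a <- normalize( sum_ij w^a_ij X_i X_j )

with damping c = 0.15 guaranteeing irreducibility.  Both score vectors are
kept normalized to sum 1.  The layer with maximal z is the "elected" layer;
its rate columns drive the transition dynamics.  The rewiring operation
perturbs the *least* central layer by detaching links at their
least-central endpoint and reattaching them uniformly at random, preserving
the link count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multiplex import WeightedMultiplexNetwork, compute_weights
from .rates import RateMatrices

__all__ = [
    "MultiplexRanking",
    "coupled_centrality",
    "elect_layer",
    "elected_rates",
    "rewire",
]

DAMPING = 0.15


@dataclass
class MultiplexRanking:
    """Node scores X (sum 1), layer scores z (sum 1) and the elected layer."""

    X: np.ndarray
    z: np.ndarray
    converged: bool
    iterations: int

    @property
    def elected_layer(self) -> int:
        # argmax with ties broken to the lowest index
        return int(np.argmax(self.z))

    def to_csv(self, nodes_path, layers_path) -> None:
        pd.DataFrame({"node_id": np.arange(len(self.X)), "X": self.X}).to_csv(
            nodes_path, index=False
        )
        pd.DataFrame({"layer_id": np.arange(len(self.z)), "z": self.z}).to_csv(
            layers_path, index=False
        )


def coupled_centrality(
    network: WeightedMultiplexNetwork,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> MultiplexRanking:
    """Fixed point of the coupled node/layer ranking iteration.

    Deterministic given the network.  Non-convergence within ``max_iter``
    returns the last iterate flagged ``converged=False``.
    """
    n, m = network.n_nodes, network.n_layers
    total = sum(w.sum() for w in network.layers)
    if total == 0:
        raise ValueError("multiplex has no links")
    X = np.full(n, 1.0 / n)
    z = np.full(m, 1.0 / m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        drive = sum(z[a] * (network.layers[a] @ X) for a in range(m))
        X_new = drive + DAMPING / n
        X_new /= X_new.sum()
        z_new = np.array([X_new @ (network.layers[a] @ X_new) for a in range(m)])
        zs = z_new.sum()
        z_new = z_new / zs if zs > 0 else np.full(m, 1.0 / m)
        delta = max(np.max(np.abs(X_new - X)), np.max(np.abs(z_new - z)))
        X, z = X_new, z_new
        if delta < tol:
            converged = True
            break
    return MultiplexRanking(X=X, z=z, converged=converged, iterations=it)


def elect_layer(ranking: MultiplexRanking) -> int:
    """Index of the most influential layer (argmax z, ties to lowest index)."""
    return ranking.elected_layer


def elected_rates(rates: RateMatrices, elected: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-node rate vectors (beta_bar, lambda_bar): the elected layer's columns."""
    if not (0 <= elected < rates.n_layers):
        raise IndexError(f"elected layer {elected} out of range")
    return rates.B[:, elected].copy(), rates.Lambda[:, elected].copy()


def rewire(
    network: WeightedMultiplexNetwork,
    fraction: float,
    ranking: MultiplexRanking,
    seed: int,
    log: list | None = None,
) -> WeightedMultiplexNetwork:
    """Rewire a fraction of the least-central links in the least central layer.

    In the layer with minimal z, the floor(f * L) links whose lower-centrality
    endpoint has the smallest X are detached at that endpoint and reattached
    to a uniformly random node, rejecting self-loops and duplicates (up to
    100 retries per link, after which the link is left in place).  The link
    count of the layer is preserved and all other layers are untouched.
    Weights are recomputed afterwards when the network carries an awareness
    assignment (``awbar`` set by a prior ``compute_weights``).

    ``log``, if given, collects (layer, old_i, old_j, new_i, new_j) tuples.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("rewiring fraction must lie in [0, 1]")
    out = network.copy()
    target = int(np.argmin(ranking.z))
    rows, cols, _ = out.edges(target)
    n_links = len(rows)
    n_rewire = int(np.floor(fraction * n_links))
    if n_rewire == 0:
        return out

    X = ranking.X
    # lower-centrality endpoint of each link, ties to the lower node index
    lo_is_row = (X[rows] < X[cols]) | ((X[rows] == X[cols]) & (rows < cols))
    detach = np.where(lo_is_row, rows, cols)
    keep = np.where(lo_is_row, cols, rows)
    order = np.lexsort((detach, X[detach]))
    chosen = order[:n_rewire]

    links = {(min(i, j), max(i, j)) for i, j in zip(rows, cols)}
    rng = np.random.default_rng(seed)
    for idx in chosen:
        old_i, old_j = int(detach[idx]), int(keep[idx])
        key = (min(old_i, old_j), max(old_i, old_j))
        if key not in links:  # already displaced by an earlier rewiring
            continue
        for _ in range(100):
            new_i = int(rng.integers(out.n_nodes))
            if new_i == old_j:
                continue
            new_key = (min(new_i, old_j), max(new_i, old_j))
            if new_key in links:
                continue
            links.discard(key)
            links.add(new_key)
            if log is not None:
                log.append((target, old_i, old_j, new_i, old_j))
            break

    n = out.n_nodes
    if links:
        r = np.fromiter((p[0] for p in links), dtype=int, count=len(links))
        c = np.fromiter((p[1] for p in links), dtype=int, count=len(links))
        import scipy.sparse as sp

        a = sp.csr_matrix(
            (np.ones(2 * len(links)), (np.r_[r, c], np.r_[c, r])), shape=(n, n)
        )
    else:  # pragma: no cover - a layer with links cannot end empty
        import scipy.sparse as sp

        a = sp.csr_matrix((n, n))
    out.layers[target] = a
    if out.awbar is not None:
        out = compute_weights(out, out.awbar)
    return out
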