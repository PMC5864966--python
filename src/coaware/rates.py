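"""Heterogeneous awareness and infection rates derived from network structure.

Every node i gets, in every layer alpha, an awareness rate and an infection
rate built from two structural factors of the weighted multiplex:

    lambda_i^a = gamma_i^a * lambda          gamma = s / (1 + s)
    beta_i^a   = psi_i^a * beta + s0         psi   = 1 / ((1 + lambda_i^a) * Y_i^a)

with ``s`` the node strength, ``Y`` the inverse participation ratio,
``lambda`` / ``beta`` the baseline rates and ``s0`` the spontaneous-contagion
probability.  The two rates are interdependent: psi is evaluated at the
node's own awareness rate, so a better-informed node is effectively less
susceptible, while 1/Y (the effective contact count) raises susceptibility.
Since psi can exceed 1, beta entries are clipped to [0, 1] to remain
per-step probabilities.

A node's *overlapping awareness* aggregates its awareness of the primary
phenomenon with phi-correlated awareness of related issues:

    awbar_i = aw_i * (1 + sum_pi phi_{1,pi})

and is what enters the link-weight definition (floored at 0 there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multiplex import WeightedMultiplexNetwork, ipr_matrix, strength_matrix

__all__ = [
    "IssueCorrelations",
    "RateParameters",
    "RateMatrices",
    "overlapping_awareness",
    "gamma_factor",
    "psi_factor",
    "build_rate_matrices",
    "homogeneous_rate_matrices",
]


@dataclass(frozen=True)
class IssueCorrelations:
    """phi-correlations between the primary phenomenon and related issues.

    ``phis`` holds phi_{1,pi} for pi = 2..T; an empty tuple means a single
    issue (T = 1).  Each phi lies in [-1, 1]: positive values model issues
    whose attention reinforces awareness of the primary phenomenon, negative
    values (e.g. prevention content vs. the contagion itself) counteract it.
    """

    phis: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "phis", tuple(float(p) for p in self.phis))
        if any(abs(p) > 1 for p in self.phis):
            raise ValueError("every phi-correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class RateParameters:
    """Baseline per-step probabilities of the coupled dynamics.

    lam    baseline awareness rate (U -> A channel)
    beta   baseline infection rate (S -> I channel)
    mu     recovery rate (I -> R)
    delta  fading rate (attention decay, A -> F branch)
    eps    overlapping-awareness rate (A -> A^pi branch)
    s      spontaneous contagion probability (contact-independent)
    """

    lam: float = 0.2
    beta: float = 0.3
    mu: float = 0.3
    delta: float = 0.3
    eps: float = 0.7
    s: float = 0.0

    def __post_init__(self):
        for name in ("lam", "beta", "mu", "delta", "eps", "s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def replace(self, **kw) -> "RateParameters":
        d = {n: getattr(self, n) for n in ("lam", "beta", "mu", "delta", "eps", "s")}
        d.update(kw)
        return RateParameters(**d)


@dataclass
class RateMatrices:
    """N x M awareness (Lambda) and infection (B) rate matrices.

    ``Psi`` keeps the un-clipped heterogeneity factor psi_i^a so that the
    analytic threshold can factor the baseline beta out of B.
    """

    Lambda: np.ndarray
    B: np.ndarray
    Psi: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.Lambda.shape[0]

    @property
    def n_layers(self) -> int:
        return self.Lambda.shape[1]

    def to_csv(self, lambda_path, beta_path) -> None:
        cols = [f"layer_{a}" for a in range(self.n_layers)]
        pd.DataFrame(self.Lambda, columns=cols).rename_axis("node_id").to_csv(lambda_path)
        pd.DataFrame(self.B, columns=cols).rename_axis("node_id").to_csv(beta_path)


def overlapping_awareness(aw, corr: IssueCorrelations | None = None):
    """awbar = aw + sum_pi phi_{1,pi} * aw, returned unclipped.

    May exceed 1 (reinforcing issues) or go negative (dominant
    anti-correlations); the weight computation floors it at 0.
    """
    if corr is None:
        corr = IssueCorrelations()
    return np.asarray(aw, dtype=float) * (1.0 + sum(corr.phis))


def gamma_factor(strength):
    """gamma = s / (1 + s): strictly increasing in strength, in [0, 1)."""
    s = np.asarray(strength, dtype=float)
    if np.any(s < 0):
        raise ValueError("strength must be non-negative")
    return s / (1.0 + s)


def psi_factor(lam_ia, Y):
    """psi = 1 / ((1 + lambda_i^a) * Y_i^a).

    Decreasing in the node's own awareness rate, increasing in the effective
    contact count 1/Y; can exceed 1 on well-connected nodes.
    """
    lam_ia = np.asarray(lam_ia, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(Y <= 0):
        raise ValueError("inverse participation ratio must be positive")
    if np.any(lam_ia < 0):
        raise ValueError("awareness rate must be non-negative")
    return 1.0 / (1.0 + lam_ia) / Y


def build_rate_matrices(
    network: WeightedMultiplexNetwork, params: RateParameters
) -> RateMatrices:
    """Full heterogeneous rate matrices from the weighted topology.

    Lambda is computed first (gamma from strengths), then B (psi from Lambda
    and the IPR) — the order matters because the infection rate depends on
    the awareness rate.  All entries are clipped to [0, 1].  Requires
    weights to have been computed (so that strengths reflect awareness and
    homophily); call :func:`coaware.multiplex.compute_weights` first.
    """
    if network.awbar is None:
        raise RuntimeError(
            "network weights have not been computed; call compute_weights first"
        )
    S = strength_matrix(network)
    Y = ipr_matrix(network)
    Lambda = np.clip(gamma_factor(S) * params.lam, 0.0, 1.0)
    Psi = psi_factor(Lambda, Y)
    B = np.clip(Psi * params.beta + params.s, 0.0, 1.0)
    return RateMatrices(Lambda=Lambda, B=B, Psi=Psi)


def homogeneous_rate_matrices(
    network: WeightedMultiplexNetwork, params: RateParameters
) -> RateMatrices:
    """Uniform baseline rates: Lambda = lam, B = beta + s everywhere.

    The comparison mode in which every node shares the same susceptibility
    and awareness rate (psi = gamma = 1 effectively; psi stored as 1 so the
    threshold machinery factors beta out consistently).
    """
    shape = (network.n_nodes, network.n_layers)
    Lambda = np.full(shape, params.lam)
    B = np.full(shape, min(params.beta + params.s, 1.0))
    return RateMatrices(Lambda=Lambda, B=B, Psi=np.ones(shape))
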