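"""Stochastic agent-based simulator of the coupled contagion-awareness dynamics.

Serves as the independent cross-check of the MMCA solver: every node holds
exactly one of the 8 joint states and all nodes are updated synchronously
from the time-t configuration, with per-node branch probabilities identical
to the MMCA one-step probability tree (awareness resolves before infection
within a step, and a node that gains awareness at step t becomes infectable
from step t+1, matching the branch structure of the probability recursion).

For very small systems the full joint Markov chain (8^N configurations) can
be evolved exactly, which turns the stochastic comparison into a
deterministic one: the only remaining discrepancy with the MMCA is its
independence (mean-field) closure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mmca import AWARE_STATES, IA, IAP, INFECTED_STATES, RA, RAP, RF, SA, SF, STATES, SU
from .rates import RateParameters

__all__ = [
    "SimConfig",
    "EnsembleResult",
    "mc_step",
    "run_simulation",
    "exact_state_distribution",
    "estimate_threshold_mc",
]


@dataclass(frozen=True)
class SimConfig:
    """Replication settings for the stochastic simulator."""

    t_max: int = 100
    n_runs: int = 100
    seed: int = 0
    infected_fraction: float = 0.01
    aware_fraction: float = 0.1

    def __post_init__(self):
        if self.infected_fraction + self.aware_fraction > 1:
            raise ValueError("initial fractions must sum to at most 1")


def _contact_probs(
    states: np.ndarray,
    beta_bar: np.ndarray,
    lam_bar: np.ndarray,
    contacts: sp.csr_matrix,
    s: float,
    leading: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(q_i, r_i) for a hard configuration: indicator version of the MMCA forms."""
    n = len(states)
    infected = np.isin(states, INFECTED_STATES).astype(float)
    aware = np.isin(states, AWARE_STATES).astype(float)
    A = contacts.tocsr()
    n_inf = A @ infected  # infected contacts per node
    lead = (1.0 - beta_bar) if leading == "rate" else np.full(n, 1.0 - s)
    q = lead * (1.0 - beta_bar) ** n_inf
    # r involves the neighbour's awareness rate, so the product is genuine
    terms = 1.0 - lam_bar[A.indices] * aware[A.indices]
    prod = np.ones(n)
    if len(terms):
        starts = np.minimum(A.indptr[:-1], len(terms) - 1)
        prod = np.multiply.reduceat(terms, starts)
        prod[A.indptr[:-1] == A.indptr[1:]] = 1.0
    r = (1.0 - lam_bar) * prod
    return np.clip(q, 0, 1), np.clip(r, 0, 1)


def _branch_distributions(
    states: np.ndarray,
    q: np.ndarray,
    r: np.ndarray,
    params: RateParameters,
) -> np.ndarray:
    """N x 8 matrix of per-node next-state probabilities given the configuration."""
    n = len(states)
    mu, delta, eps = params.mu, params.delta, params.eps
    D = np.zeros((n, 8))
    su = states == SU
    D[su, SU] = r[su]
    D[su, SF] = (1 - r[su]) * delta
    D[su, SA] = (1 - r[su]) * (1 - delta)
    sa = states == SA
    D[sa, SA] = q[sa]
    D[sa, IA] = (1 - q[sa]) * (1 - eps)
    D[sa, IAP] = (1 - q[sa]) * eps * (1 - mu)
    D[sa, RAP] = (1 - q[sa]) * eps * mu
    ia = states == IA
    D[ia, IA] = 1 - mu
    D[ia, RF] = mu * delta
    D[ia, RAP] = mu * eps * (1 - delta)
    D[ia, RA] = mu * (1 - delta) * (1 - eps)
    iap = states == IAP
    D[iap, IAP] = 1 - mu
    D[iap, RAP] = mu
    for terminal in (SF, RA, RAP, RF):
        mask = states == terminal
        D[mask, terminal] = 1.0
    return D


def mc_step(
    states: np.ndarray,
    beta_bar: np.ndarray,
    lam_bar: np.ndarray,
    params: RateParameters,
    contacts: sp.csr_matrix,
    rng: np.random.Generator,
    leading: str = "rate",
) -> np.ndarray:
    """One synchronous stochastic update of a hard configuration."""
    q, r = _contact_probs(states, beta_bar, lam_bar, contacts, params.s, leading)
    D = _branch_distributions(states, q, r, params)
    u = rng.random(len(states))
    cum = np.cumsum(D, axis=1)
    return (u[:, None] < cum).argmax(axis=1)


def _initial_configuration(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_inf = int(round(cfg.infected_fraction * n))
    n_aw = int(round(cfg.aware_fraction * n))
    states = np.full(n, SU)
    order = rng.permutation(n)
    states[order[:n_inf]] = IA
    states[order[n_inf : n_inf + n_aw]] = SA
    return states


@dataclass
class EnsembleResult:
    """State-count trajectories of every replicate plus ensemble summaries."""

    counts: np.ndarray  # n_runs x (t_max+1) x 8
    n_nodes: int

    @property
    def densities(self) -> np.ndarray:
        return self.counts / self.n_nodes

    def mean(self) -> np.ndarray:
        """(t_max+1) x 8 ensemble-mean state densities."""
        return self.densities.mean(axis=0)

    def stderr(self) -> np.ndarray:
        n = self.counts.shape[0]
        return self.densities.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(self.mean())

    def rho_I(self, include_overlapping: bool = False) -> np.ndarray:
        m = self.mean()
        return m[:, IA] + (m[:, IAP] if include_overlapping else 0.0)

    def to_frame(self) -> pd.DataFrame:
        runs, steps, _ = self.counts.shape
        rows = []
        for run in range(runs):
            for t in range(steps):
                for k, name in enumerate(STATES):
                    rows.append(
                        {"run": run, "t": t, "state": name, "count": int(self.counts[run, t, k])}
                    )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        m, se = self.mean(), self.stderr()
        rows = []
        for t in range(m.shape[0]):
            for k, name in enumerate(STATES):
                rows.append(
                    {"t": t, "state": name, "mean": m[t, k], "stderr": se[t, k]}
                )
        return pd.DataFrame(rows)


def run_simulation(
    contacts: sp.csr_matrix,
    beta_bar: np.ndarray,
    lam_bar: np.ndarray,
    params: RateParameters,
    sim: SimConfig,
    leading: str = "rate",
) -> EnsembleResult:
    """Independent replicate trajectories; deterministic given ``sim.seed``.

    Each replicate uses its own RNG substream spawned from the master seed
    by run index, so results are reproducible and independent of n_runs
    ordering.
    """
    n = contacts.shape[0]
    counts = np.zeros((sim.n_runs, sim.t_max + 1, 8), dtype=int)
    for run in range(sim.n_runs):
        rng = np.random.default_rng([sim.seed, run])
        states = _initial_configuration(n, sim, rng)
        counts[run, 0] = np.bincount(states, minlength=8)
        for t in range(1, sim.t_max + 1):
            states = mc_step(states, beta_bar, lam_bar, params, contacts, rng, leading)
            counts[run, t] = np.bincount(states, minlength=8)
    return EnsembleResult(counts=counts, n_nodes=n)


def exact_state_distribution(
    contacts: sp.csr_matrix,
    beta_bar: np.ndarray,
    lam_bar: np.ndarray,
    params: RateParameters,
    initial_states: np.ndarray,
    t_max: int,
    leading: str = "rate",
) -> np.ndarray:
    """Exact per-node state marginals of the joint chain, (t_max+1) x N x 8.

    Enumerates all 8^N configurations (use only for N <= ~6).  Because the
    synchronous update factorizes over nodes given the configuration, the
    one-step kernel is a product of per-node branch distributions; evolving
    the full joint distribution therefore captures all correlations the
    MMCA closure discards.
    """
    n = contacts.shape[0]
    configs = np.array(list(itertools.product(range(8), repeat=n)), dtype=int)
    n_cfg = len(configs)
    # per-config per-node branch distributions
    kernels = np.zeros((n_cfg, n, 8))
    for c, cfg in enumerate(configs):
        q, r = _contact_probs(cfg, beta_bar, lam_bar, contacts, params.s, leading)
        kernels[c] = _branch_distributions(cfg, q, r, params)

    index_of = {tuple(cfg): k for k, cfg in enumerate(configs)}
    dist = np.zeros(n_cfg)
    dist[index_of[tuple(initial_states)]] = 1.0

    powers = 8 ** np.arange(n - 1, -1, -1)
    target_idx = configs @ powers  # lexicographic index of each config

    marginals = np.zeros((t_max + 1, n, 8))

    def record(t, d):
        for c in range(n_cfg):
            if d[c] > 0:
                for i in range(n):
                    marginals[t, i, configs[c, i]] += d[c]

    record(0, dist)
    for t in range(1, t_max + 1):
        new = np.zeros(n_cfg)
        active = np.where(dist > 1e-300)[0]
        for c in active:
            # joint transition probability to every configuration: product
            # over nodes of the per-node branch probability
            probs = kernels[c][np.arange(n)[:, None], configs.T].prod(axis=0)
            new += dist[c] * probs
        dist = new
        record(t, dist)
    return marginals


def estimate_threshold_mc(
    contacts: sp.csr_matrix,
    rates_for_beta,
    lam_bar: np.ndarray,
    params: RateParameters,
    beta_grid: np.ndarray,
    sim: SimConfig,
    outbreak_excess: float = 0.05,
) -> float:
    """Empirical threshold from stochastic runs.

    Smallest beta on the (increasing) grid whose ensemble-mean final
    cumulative-infected fraction exceeds the seeded fraction by
    ``outbreak_excess``.  Runs use the onset kernel (the standalone
    contagion channel carries only the spontaneous probability s), matching
    the analytic threshold's regime.  A grid that is entirely sub- or
    super-critical returns the corresponding boundary value with a warning.
    """
    beta_grid = np.sort(np.asarray(beta_grid, dtype=float))
    ever_infected = [IA, IAP, RA, RAP, RF]

    def attack(beta: float) -> float:
        beta_bar = np.asarray(rates_for_beta(beta), dtype=float)
        res = run_simulation(
            contacts, beta_bar, lam_bar, params.replace(beta=float(beta), s=0.0),
            sim, leading="spontaneous",
        )
        final = res.mean()[-1]
        return float(final[ever_infected].sum())

    floor = sim.infected_fraction + outbreak_excess
    lo, hi = 0, len(beta_grid) - 1
    if attack(beta_grid[lo]) > floor:
        warnings.warn("entire beta grid is super-critical; returning lower boundary")
        return float(beta_grid[lo])
    if attack(beta_grid[hi]) <= floor:
        warnings.warn("entire beta grid is sub-critical; returning upper boundary")
        return float(beta_grid[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if attack(beta_grid[mid]) > floor:
            hi = mid
        else:
            lo = mid
    return float(beta_grid[hi])
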