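"""Scenario presets: synthetic populations and the three canonical experiments.

The synthetic population emulates the statistical structure of a
communication-classified social-media cohort: nodes fall into awareness
tiers (classes of how openly the primary phenomenon is discussed, with a
decreasing awareness gradient), belong to one of two groups (a geographic
homophily proxy whose group-level popularity factor scales awareness), and
carry a phase tag — pre-event or post-event — realised as a trend
multiplier on awareness that emulates the attention surge after a widely
publicised event.  The class proportions and awareness levels shipped as
defaults are illustrative, not calibrated to any corpus.

Experiments:

* ``run_correlation_timeseries`` — infected-density trajectories for a
  positively and an anti-correlated secondary issue (phi = +/-0.8) under
  three attention regimes, from both the MMCA and the stochastic simulator.
* ``run_phase_rewiring`` — phase diagrams over (lambda, beta) before and
  after centrality-guided rewiring, for both correlation signs, with
  homogeneous and heterogeneous threshold curves.
* ``run_population_scatter`` — per-node (lambda_i, beta_i, awbar_i) records
  for the synthetic population in both phases and both correlation signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import coupled_centrality, elected_rates, rewire
from .mmca import contact_matrix, phase_diagram, run_mmca
from .montecarlo import SimConfig, run_simulation
from .multiplex import compute_weights, generate_scale_free_multiplex
from .rates import (
    IssueCorrelations,
    RateParameters,
    build_rate_matrices,
    overlapping_awareness,
)

__all__ = [
    "SyntheticPopulation",
    "DEFAULT_CLASS_PROPORTIONS",
    "DEFAULT_CLASS_AWARENESS",
    "generate_population",
    "run_correlation_timeseries",
    "run_phase_rewiring",
    "run_population_scatter",
]

# Illustrative 7-tier communication-class configuration: proportions of the
# population per class and the class-level base awareness, decreasing from
# the most openly communicative tier to the most withdrawn (and hence most
# vulnerable) one.
DEFAULT_CLASS_PROPORTIONS = (0.30, 0.22, 0.16, 0.12, 0.09, 0.07, 0.04)
DEFAULT_CLASS_AWARENESS = (0.90, 0.78, 0.65, 0.52, 0.40, 0.28, 0.15)
#: group-level popularity factors for the two homophily groups
DEFAULT_GROUP_POPULARITY = (1.0, 0.85)


@dataclass
class SyntheticPopulation:
    """Per-node class tier, awareness score, group label and phase tag."""

    classes: np.ndarray  # tier index per node, 0 = highest awareness
    aw: np.ndarray  # composed awareness score in [0, 1]
    group: np.ndarray  # 0 or 1
    phase: str  # "pre" or "post"

    @property
    def n_nodes(self) -> int:
        return len(self.classes)

    def vulnerable_mask(self, n_tiers_from_bottom: int = 2) -> np.ndarray:
        """Nodes in the lowest-awareness tiers (the most vulnerable)."""
        cutoff = self.classes.max() - n_tiers_from_bottom + 1
        return self.classes >= cutoff


def generate_population(
    n_nodes: int = 400,
    class_proportions=DEFAULT_CLASS_PROPORTIONS,
    class_awareness_levels=DEFAULT_CLASS_AWARENESS,
    group_split: float = 0.5,
    trend_pre: float = 0.8,
    trend_post: float = 1.2,
    seed: int = 0,
    group_popularity=DEFAULT_GROUP_POPULARITY,
) -> tuple[SyntheticPopulation, SyntheticPopulation]:
    """Draw a population and return its (pre-event, post-event) variants.

    Classes are assigned multinomially with the given proportions; each
    node's awareness composes three measures — its class-based level, the
    popularity factor of its group and the phase trend multiplier — and is
    clipped to [0, 1].  The two phase variants share classes and groups and
    differ only through the trend multiplier.
    """
    props = np.asarray(class_proportions, dtype=float)
    levels = np.asarray(class_awareness_levels, dtype=float)
    if props.ndim != 1 or len(props) != len(levels):
        raise ValueError("proportions and awareness levels must align")
    if abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("class proportions must be a probability vector")
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("class awareness levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    classes = rng.choice(len(props), size=n_nodes, p=props)
    group = (rng.random(n_nodes) >= group_split).astype(int)
    pop_factor = np.asarray(group_popularity, dtype=float)[group]
    base = levels[classes] * pop_factor

    def phase(trend, tag):
        return SyntheticPopulation(
            classes=classes.copy(),
            aw=np.clip(base * trend, 0.0, 1.0),
            group=group.copy(),
            phase=tag,
        )

    return phase(trend_pre, "pre"), phase(trend_post, "post")


@dataclass
class ScenarioConfig:
    """Resolved settings shared by the experiment runners."""

    n_nodes: int = 1000
    n_layers: int = 3
    m: int = 2
    seed: int = 1
    params: RateParameters = field(default_factory=RateParameters)
    phi: float = 0.8
    rewire_fraction: float = 0.2


def _weighted_network(cfg: ScenarioConfig, phi: float):
    net = generate_scale_free_multiplex(cfg.n_nodes, cfg.n_layers, cfg.m, cfg.seed)
    awbar = overlapping_awareness(net.aw, IssueCorrelations((phi,)))
    return compute_weights(net, awbar)


def _elected_setup(net, params):
    ranking = coupled_centrality(net)
    rm = build_rate_matrices(net, params)
    beta_bar, lam_bar = elected_rates(rm, ranking.elected_layer)
    contacts = contact_matrix(net, ranking.elected_layer)
    return ranking, rm, beta_bar, lam_bar, contacts


#: the three attention regimes of the time-evolution experiment
TIMESERIES_REGIMES = {
    "high_attention": dict(mu=0.3, delta=0.3, eps=0.7),
    "fast_fading": dict(mu=0.3, delta=0.7, eps=0.3),
    "fast_recovery_fading": dict(mu=0.7, delta=0.7, eps=0.3),
}


def run_correlation_timeseries(
    cfg: ScenarioConfig,
    t_max: int = 100,
    n_runs: int = 50,
    regimes: dict | None = None,
) -> pd.DataFrame:
    """rho^I(t) for phi = +/-|phi| under each attention regime (MMCA + MC)."""
    regimes = TIMESERIES_REGIMES if regimes is None else regimes
    rows = []
    for regime, over in regimes.items():
        for phi in (-abs(cfg.phi), abs(cfg.phi)):
            params = cfg.params.replace(**over)
            net = _weighted_network(cfg, phi)
            _, _, beta_bar, lam_bar, contacts = _elected_setup(net, params)
            res = run_mmca(
                contacts, beta_bar, lam_bar, params, t_max=t_max, tol=0.0
            )
            for t, rho in zip(res.times, res.rho_I):
                rows.append(
                    {"regime": regime, "phi": phi, "method": "mmca", "t": int(t), "rho_I": rho}
                )
            if n_runs > 0:
                sim = SimConfig(t_max=t_max, n_runs=n_runs, seed=cfg.seed)
                ens = run_simulation(contacts, beta_bar, lam_bar, params, sim)
                for t, rho in enumerate(ens.rho_I()):
                    rows.append(
                        {"regime": regime, "phi": phi, "method": "mc", "t": t, "rho_I": rho}
                    )
    return pd.DataFrame(rows)


def run_phase_rewiring(
    cfg: ScenarioConfig,
    lam_grid=None,
    beta_grid=None,
    t_max: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase grids for +/-phi, pre/post rewiring, with both threshold curves.

    Returns (long-format grid frame, threshold summary frame).
    """
    lam_grid = np.asarray([cfg.params.lam] if lam_grid is None else lam_grid, float)
    beta_grid = (
        np.arange(0.01, 0.51, 0.01) if beta_grid is None else np.asarray(beta_grid, float)
    )
    grid_rows, thr_rows = [], []
    for phi in (-abs(cfg.phi), abs(cfg.phi)):
        net = _weighted_network(cfg, phi)
        ranking = coupled_centrality(net)
        nets = {
            "pre": net,
            "post": rewire(net, cfg.rewire_fraction, ranking, seed=cfg.seed + 1),
        }
        for stage, network in nets.items():
            for mode in ("heterogeneous", "homogeneous"):
                pg = phase_diagram(
                    network, cfg.params, lam_grid, beta_grid, mode=mode, t_max=t_max
                )
                f = pg.to_frame()
                f["phi"] = phi
                f["stage"] = stage
                grid_rows.append(f)
                for lam, emp, ana in zip(
                    pg.lam_grid, pg.empirical_beta_c, pg.analytic_beta_c
                ):
                    thr_rows.append(
                        {
                            "phi": phi,
                            "stage": stage,
                            "mode": mode,
                            "lambda": lam,
                            "empirical_beta_c": emp,
                            "analytic_beta_c": ana,
                        }
                    )
    return pd.concat(grid_rows, ignore_index=True), pd.DataFrame(thr_rows)


def run_population_scatter(
    cfg: ScenarioConfig,
    population_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Per-node (lambda_i, beta_i, awbar_i, class, phase) records.

    The synthetic population's awareness feeds the multiplex weights; the
    elected-layer rate columns are recorded per node for the positively
    correlated (phi > 0, reinforcing issue) and anti-correlated (phi < 0,
    counteracting issue) scenarios in both phases.
    """
    kw = dict(n_nodes=400, seed=cfg.seed)
    kw.update(population_kwargs or {})
    pre, post = generate_population(**kw)
    rows = []
    for pop in (pre, post):
        for phi in (-abs(cfg.phi), abs(cfg.phi)):
            net = generate_scale_free_multiplex(
                pop.n_nodes, cfg.n_layers, cfg.m, cfg.seed,
                aw=pop.aw, attribute=pop.group.astype(float),
            )
            awbar = overlapping_awareness(pop.aw, IssueCorrelations((phi,)))
            net = compute_weights(net, awbar)
            ranking, rm, beta_bar, lam_bar, _ = _elected_setup(net, cfg.params)
            for i in range(pop.n_nodes):
                rows.append(
                    {
                        "node_id": i,
                        "phase": pop.phase,
                        "phi": phi,
                        "lambda_i": lam_bar[i],
                        "beta_i": beta_bar[i],
                        "awbar_i": awbar[i],
                        "class_tier": int(pop.classes[i]),
                        "group": int(pop.group[i]),
                        "vulnerable": bool(pop.vulnerable_mask()[i]),
                    }
                )
    return pd.DataFrame(rows)
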