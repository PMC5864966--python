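"""Dynamic microscopic Markov chain (MMCA) solver for the coupled dynamics.

Each node carries a probability vector over the 8 reachable joint states

    SU, SA, SF, IA, IA^pi, RA, RA^pi, RF

(susceptible/infected/recovered x unaware/aware/faded/overlapping-aware;
the combinations IU, IF, SA^pi and FA^pi are unreachable and never
represented).  One synchronous step uses two per-node contact
probabilities on the elected layer's adjacency:

    q_i = (1 - beta_bar_i) * prod_j [1 - a_ji * p_j^I * beta_bar_i]
    r_i = (1 - lam_bar_i)  * prod_j [1 - a_ji * p_j^A * lam_bar_j]

(q: not being infected, r: staying unaware; note the deliberate asymmetry —
q applies the focal node's rate inside the product, r the neighbour's) and
then branches each state's mass through the one-step probability tree:
unaware nodes that gain awareness either engage (SA, prob 1-delta) or fade
(SF); engaged susceptibles get infected with 1-q and route a fraction eps
into the overlapping-awareness branch; infected recover with mu.

Two step modes are provided.  ``verbatim`` applies the branching equations
exactly as stated, under which terminal states do not retain their own mass
and probability leaks when iterated.  ``conserving`` (default) additionally
lets the absorbing states SF, RA, RA^pi, RF keep their mass and lets IA^pi
persist with probability 1-mu (recovering into RA^pi), so that every row of
the state matrix sums to 1 at all times.

The leading (1 - beta_bar_i) factor of q makes infection possible without
any infected contact, i.e. it doubles as a spontaneous-contagion channel.
Near the contagion onset this standalone channel is excluded by the
threshold derivation itself, so threshold detection and phase diagrams use
``leading="spontaneous"``, which replaces the leading factor by (1 - s)
(the explicit spontaneous-contagion probability, 0 by default); the step
equations keep the stated form under the default ``leading="rate"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .multiplex import WeightedMultiplexNetwork
from .rates import RateMatrices, RateParameters

__all__ = [
    "STATES",
    "MMCAState",
    "MMCAResult",
    "PhaseGrid",
    "contact_matrix",
    "not_infected_prob",
    "stay_unaware_prob",
    "mmca_step",
    "run_mmca",
    "order_parameter",
    "awareness_steady_state",
    "contagion_threshold",
    "empirical_threshold",
    "phase_diagram",
]

STATES = ("SU", "SA", "SF", "IA", "IA_pi", "RA", "RA_pi", "RF")
SU, SA, SF, IA, IAP, RA, RAP, RF = range(8)

#: states whose occupants count as "aware" contacts for the awareness process
AWARE_STATES = (SA, IA, RA)
#: states whose occupants count as infectious contacts
INFECTED_STATES = (IA, IAP)


@dataclass
class MMCAState:
    """Per-node probability matrix P (N x 8) at time t; rows sum to 1."""

    P: np.ndarray
    t: int = 0

    @property
    def n_nodes(self) -> int:
        return self.P.shape[0]

    def densities(self) -> np.ndarray:
        """Mean probability of each of the 8 states across nodes."""
        return self.P.mean(axis=0)


@dataclass
class MMCAResult:
    """Trajectory of mean state densities plus the final state."""

    times: np.ndarray
    densities: np.ndarray  # T x 8
    rho_I: np.ndarray
    steady_state: MMCAState
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times):
            for s, name in enumerate(STATES):
                rows.append({"t": int(t), "state": name, "density": self.densities[k, s]})
        return pd.DataFrame(rows)


def initial_state(
    n_nodes: int,
    infected_fraction: float = 0.01,
    aware_fraction: float = 0.1,
) -> MMCAState:
    """Uniform initial condition over the three admissible start states.

    Every node receives probability ``infected_fraction`` of IA,
    ``aware_fraction`` of SA and the remainder of SU.
    """
    if infected_fraction + aware_fraction > 1:
        raise ValueError("initial fractions must sum to at most 1")
    P = np.zeros((n_nodes, 8))
    P[:, IA] = infected_fraction
    P[:, SA] = aware_fraction
    P[:, SU] = 1.0 - infected_fraction - aware_fraction
    return MMCAState(P=P, t=0)


def contact_matrix(
    network: WeightedMultiplexNetwork,
    elected: int,
    union: bool = False,
) -> sp.csr_matrix:
    """Binary contact adjacency: the elected layer (default) or all layers merged."""
    if union:
        a = sum(network.adjacency(k) for k in range(network.n_layers))
        a = sp.csr_matrix(a)
        a.data = np.ones_like(a.data)
        return a
    return network.adjacency(elected)


def _row_products(indptr: np.ndarray, vals: np.ndarray, n_rows: int) -> np.ndarray:
    """Per-row product of ``vals`` over a CSR structure (empty rows -> 1)."""
    if len(vals) == 0:
        return np.ones(n_rows)
    starts = np.minimum(indptr[:-1], len(vals) - 1)
    out = np.multiply.reduceat(vals, starts)
    out[indptr[:-1] == indptr[1:]] = 1.0
    return out


def not_infected_prob(
    P: np.ndarray,
    beta_bar: np.ndarray,
    contacts: sp.csr_matrix,
    s: float = 0.0,
    leading: str = "rate",
) -> np.ndarray:
    """q_i: probability of each node not being infected this step.

    ``leading="rate"`` uses the stated leading factor (1 - beta_bar_i);
    ``leading="spontaneous"`` uses (1 - s), the contact-independent
    contagion probability, which restores a true threshold when s = 0.
    """
    n = P.shape[0]
    pI = P[:, IA] + P[:, IAP]
    A = contacts.tocsr()
    rows = np.repeat(np.arange(n), np.diff(A.indptr))
    terms = 1.0 - beta_bar[rows] * pI[A.indices]
    prod = _row_products(A.indptr, terms, n)
    lead = (1.0 - beta_bar) if leading == "rate" else (1.0 - s) * np.ones(n)
    return np.clip(lead * prod, 0.0, 1.0)


def stay_unaware_prob(
    P: np.ndarray,
    lam_bar: np.ndarray,
    contacts: sp.csr_matrix,
) -> np.ndarray:
    """r_i: probability of an unaware node staying unaware this step."""
    n = P.shape[0]
    pA = P[:, SA] + P[:, IA] + P[:, RA]
    A = contacts.tocsr()
    terms = 1.0 - lam_bar[A.indices] * pA[A.indices]
    prod = _row_products(A.indptr, terms, n)
    return np.clip((1.0 - lam_bar) * prod, 0.0, 1.0)


def mmca_step(
    state: MMCAState,
    beta_bar: np.ndarray,
    lam_bar: np.ndarray,
    params: RateParameters,
    contacts: sp.csr_matrix,
    mode: str = "conserving",
    leading: str = "rate",
) -> MMCAState:
    """One synchronous probability update.

    ``mode="conserving"`` (default) keeps each row a probability
    distribution (terminal states retain their mass; IA^pi persists with
    1-mu and recovers into RA^pi); ``mode="verbatim"`` applies the stated
    branching only, without the added persistence terms.
    """
    if mode not in ("conserving", "verbatim"):
        raise ValueError(f"unknown mode {mode!r}")
    P = state.P
    mu, delta, eps = params.mu, params.delta, params.eps
    q = not_infected_prob(P, beta_bar, contacts, s=params.s, leading=leading)
    r = stay_unaware_prob(P, lam_bar, contacts)

    pSU, pSA, pIA, pIAP = P[:, SU], P[:, SA], P[:, IA], P[:, IAP]
    new = np.zeros_like(P)
    new[:, SU] = r * pSU
    new[:, SA] = q * pSA + (1 - r) * (1 - delta) * pSU
    new[:, SF] = delta * (1 - r) * pSU
    new[:, IA] = (1 - q) * (1 - eps) * pSA + (1 - mu) * pIA
    new[:, IAP] = eps * (1 - q) * (1 - mu) * pSA
    new[:, RA] = mu * (1 - delta) * (1 - eps) * pIA
    new[:, RAP] = mu * eps * (1 - q) * pSA + mu * eps * (1 - delta) * pIA
    new[:, RF] = mu * delta * pIA

    if mode == "conserving":
        new[:, SF] += P[:, SF]
        new[:, RA] += P[:, RA]
        new[:, RAP] += P[:, RAP] + mu * pIAP
        new[:, RF] += P[:, RF]
        new[:, IAP] += (1 - mu) * pIAP
        rowsum = new.sum(axis=1)
        if np.max(np.abs(rowsum - 1.0)) > 1e-9:
            raise FloatingPointError(
                f"probability row sum deviates by {np.max(np.abs(rowsum - 1.0)):.3e}"
            )
    return MMCAState(P=new, t=state.t + 1)


def order_parameter(state: MMCAState, include_overlapping: bool = False) -> float:
    """rho^I: mean infected-aware probability (optionally including IA^pi)."""
    rho = state.P[:, IA].mean()
    if include_overlapping:
        rho += state.P[:, IAP].mean()
    return float(rho)


def run_mmca(
    contacts: sp.csr_matrix,
    beta_bar: np.ndarray,
    lam_bar: np.ndarray,
    params: RateParameters,
    initial: MMCAState | None = None,
    infected_fraction: float = 0.01,
    aware_fraction: float = 0.1,
    t_max: int = 5000,
    tol: float = 1e-8,
    mode: str = "conserving",
    leading: str = "rate",
    include_overlapping: bool = False,
) -> MMCAResult:
    """Iterate the MMCA until the max-norm change drops below ``tol``.

    Records the mean density of every state and rho^I at each step.
    """
    n = contacts.shape[0]
    state = initial if initial is not None else initial_state(
        n, infected_fraction, aware_fraction
    )
    times = [state.t]
    dens = [state.densities()]
    rho = [order_parameter(state, include_overlapping)]
    converged = False
    for _ in range(t_max):
        nxt = mmca_step(state, beta_bar, lam_bar, params, contacts, mode, leading)
        delta = np.max(np.abs(nxt.P - state.P))
        state = nxt
        times.append(state.t)
        dens.append(state.densities())
        rho.append(order_parameter(state, include_overlapping))
        if delta < tol:
            converged = True
            break
    return MMCAResult(
        times=np.asarray(times),
        densities=np.asarray(dens),
        rho_I=np.asarray(rho),
        steady_state=state,
        converged=converged,
    )


def awareness_steady_state(
    contacts: sp.csr_matrix,
    lam_bar: np.ndarray,
    aware_fraction: float = 0.1,
    t_max: int = 5000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Steady-state p^SA of the awareness-only process (beta = s = 0, delta = 0).

    This is the awareness distribution entering the threshold matrix H: near
    the contagion onset the fading rate is negligible and no infection has
    yet occurred, so awareness relaxes on the contact graph alone.
    """
    n = contacts.shape[0]
    params = RateParameters(lam=0, beta=0, mu=0, delta=0, eps=0, s=0)
    res = run_mmca(
        contacts,
        beta_bar=np.zeros(n),
        lam_bar=lam_bar,
        params=params,
        infected_fraction=0.0,
        aware_fraction=aware_fraction,
        t_max=t_max,
        tol=tol,
    )
    return res.steady_state.P[:, SA].copy()


def _largest_real_eigenvalue(H0: sp.spmatrix) -> float:
    n = H0.shape[0]
    if n <= 300:
        vals = np.linalg.eigvals(H0.toarray())
    else:
        try:
            vals = sp.linalg.eigs(
                H0.tocsc().astype(float), k=1, which="LR", return_eigenvectors=False
            )
        except Exception:  # ARPACK can fail on tiny/defective problems
            vals = np.linalg.eigvals(H0.toarray())
    return float(np.max(vals.real))


def contagion_threshold(
    contacts: sp.csr_matrix,
    psi_bar: np.ndarray,
    params: RateParameters,
    p_sa: np.ndarray | None = None,
    lam_bar: np.ndarray | None = None,
) -> float:
    """Analytic contagion threshold beta_c = mu / Lambda_max(H0).

    H0 has entries h_ij = (1 - eps) * psi_bar_i * p_i^SA * a_ij on the
    contact adjacency, i.e. the linearized infection operator with the
    baseline beta factored out of the elected rates (beta_bar = psi_bar *
    beta).  ``p_sa`` defaults to the awareness-only steady state computed
    from ``lam_bar``.  An empty or sub-critical operator (Lambda_max <= 0)
    yields +inf.
    """
    if p_sa is None:
        if lam_bar is None:
            raise ValueError("provide either p_sa or lam_bar")
        p_sa = awareness_steady_state(contacts, lam_bar)
    scale = (1.0 - params.eps) * psi_bar * p_sa
    H0 = sp.diags(scale) @ contacts
    if H0.nnz == 0:
        return np.inf
    lam_max = _largest_real_eigenvalue(H0)
    if lam_max <= 0:
        return np.inf
    return params.mu / lam_max


_EVER_INFECTED = (IA, IAP, RA, RAP, RF)


def _outbreak(
    contacts,
    beta_bar,
    lam_bar,
    params,
    p_sa_state,
    seed_fraction: float,
    floor: float,
    t_max: int,
) -> bool:
    """Does a small infected seed produce a macroscopic outbreak?

    Outbreak = the cumulative ever-infected probability mass (the order
    parameter with a genuine steady state under recovery dynamics) exceeds
    the seeded mass by more than ``floor``.  Below the threshold the excess
    is O(seed / (1 - R)), above it O(R - 1); with seed << floor the
    detector flips within a fraction of a grid step of the true onset.
    """
    P0 = p_sa_state.P * (1.0 - seed_fraction)
    P0[:, IA] += seed_fraction
    state = MMCAState(P=P0, t=0)
    for _ in range(t_max):
        state = mmca_step(
            state, beta_bar, lam_bar, params, contacts,
            mode="conserving", leading="spontaneous",
        )
        cum = state.P[:, _EVER_INFECTED].sum(axis=1).mean()
        if cum - seed_fraction > floor:
            return True
        if state.P[:, (IA, IAP)].sum(axis=1).mean() < seed_fraction * 1e-6:
            return False
    return False


def empirical_threshold(
    contacts: sp.csr_matrix,
    rates_for_beta,
    lam_bar: np.ndarray,
    params: RateParameters,
    beta_grid: np.ndarray,
    seed_fraction: float = 1e-5,
    floor: float = 1e-3,
    t_max: int = 2000,
) -> float:
    """Smallest baseline beta on the grid whose MMCA run outbreaks.

    ``rates_for_beta(beta)`` must return the per-node elected infection
    rates at baseline ``beta`` (e.g. ``lambda b: np.clip(psi_bar * b, 0, 1)``).
    The run starts from the awareness-only steady state seeded with a small
    uniform infected probability and uses the onset kernel (spontaneous
    leading factor, fading switched off), matching the regime in which the
    analytic threshold is derived.  Outbreak = the cumulative infected mass
    exceeding the seed by ``floor`` (see ``_outbreak``).  Uses bisection on
    the grid (outbreak is monotone in beta); returns ``beta_grid[-1]`` if
    even the largest beta stays subcritical and ``beta_grid[0]`` if the
    smallest already outbreaks.
    """
    beta_grid = np.sort(np.asarray(beta_grid, dtype=float))
    onset_params = params.replace(delta=0.0, s=0.0)
    # relax awareness to its steady state once, reused for every beta
    n = contacts.shape[0]
    res = run_mmca(
        contacts,
        beta_bar=np.zeros(n),
        lam_bar=lam_bar,
        params=onset_params.replace(beta=0.0),
        infected_fraction=0.0,
        aware_fraction=0.1,
        t_max=5000,
        tol=1e-10,
    )
    p_sa_state = res.steady_state

    def hit(k: int) -> bool:
        beta = beta_grid[k]
        beta_bar = np.asarray(rates_for_beta(beta), dtype=float)
        return _outbreak(
            contacts, beta_bar, lam_bar, onset_params.replace(beta=beta),
            p_sa_state, seed_fraction, floor, t_max,
        )

    lo, hi = 0, len(beta_grid) - 1
    if hit(lo):
        return float(beta_grid[lo])
    if not hit(hi):
        return float(beta_grid[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if hit(mid):
            hi = mid
        else:
            lo = mid
    return float(beta_grid[hi])


@dataclass
class PhaseGrid:
    """Peak infected density over a (lambda, beta) grid plus threshold curves.

    ``rho`` holds, for each (lambda, beta) pair, the supremum of rho^I over
    the trajectory (the order parameter of the outbreak; it coincides with
    the stationary value whenever one exists, and is the natural outbreak
    measure for these recovery dynamics, under which the infected density is
    transient).
    """

    lam_grid: np.ndarray
    beta_grid: np.ndarray
    rho: np.ndarray  # len(lam_grid) x len(beta_grid)
    empirical_beta_c: np.ndarray  # per lambda
    analytic_beta_c: np.ndarray  # per lambda
    mode: str = "heterogeneous"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.lam_grid):
            for j, beta in enumerate(self.beta_grid):
                rows.append(
                    {"lambda": lam, "beta": beta, "rho_I": self.rho[i, j], "mode": self.mode}
                )
        return pd.DataFrame(rows)


def phase_diagram(
    network: WeightedMultiplexNetwork,
    params: RateParameters,
    lam_grid: np.ndarray,
    beta_grid: np.ndarray,
    mode: str = "heterogeneous",
    ranking=None,
    seed_fraction: float = 1e-5,
    floor: float = 1e-3,
    t_max: int = 2000,
) -> PhaseGrid:
    """Sweep baseline (lambda, beta) and record outbreak sizes and thresholds.

    For every lambda the rate matrices are rebuilt (heterogeneous mode) or
    set uniform (homogeneous mode), the elected layer's columns extracted,
    and for every beta an MMCA run from a small seed is performed with the
    onset kernel; ``rho[i, j]`` is the trajectory's peak rho^I.  The
    empirical threshold per lambda is the smallest beta whose cumulative
    infected mass exceeds the seed by ``floor`` (the steady-state outbreak
    order parameter); the analytic curve is mu / Lambda_max(H0).
    """
    from .centrality import coupled_centrality, elected_rates
    from .rates import build_rate_matrices, homogeneous_rate_matrices

    lam_grid = np.asarray(lam_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if lam_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if ranking is None:
        ranking = coupled_centrality(network)
    elected = ranking.elected_layer
    contacts = contact_matrix(network, elected)
    n_lam, n_beta = len(lam_grid), len(beta_grid)
    rho = np.zeros((n_lam, n_beta))
    emp = np.full(n_lam, np.nan)
    ana = np.full(n_lam, np.nan)
    for i, lam in enumerate(lam_grid):
        p = params.replace(lam=float(lam))
        if mode == "heterogeneous":
            rm = build_rate_matrices(network, p)
        elif mode == "homogeneous":
            rm = homogeneous_rate_matrices(network, p)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        _, lam_bar = elected_rates(rm, elected)
        psi_bar = rm.Psi[:, elected]
        p_sa = awareness_steady_state(contacts, lam_bar)
        ana[i] = contagion_threshold(contacts, psi_bar, p, p_sa=p_sa)
        onset = p.replace(delta=0.0, s=0.0)
        P_aw = np.zeros((network.n_nodes, 8))
        res_aw = run_mmca(
            contacts, np.zeros(network.n_nodes), lam_bar,
            onset.replace(beta=0.0), infected_fraction=0.0,
            aware_fraction=0.1, t_max=5000, tol=1e-10,
        )
        cum_excess = np.zeros(n_beta)
        for j, beta in enumerate(beta_grid):
            beta_bar = np.clip(psi_bar * beta + p.s, 0.0, 1.0)
            P0 = res_aw.steady_state.P * (1.0 - seed_fraction)
            P0[:, IA] += seed_fraction
            run = run_mmca(
                contacts, beta_bar, lam_bar, onset.replace(beta=float(beta)),
                initial=MMCAState(P=P0, t=0), t_max=t_max, tol=1e-8,
                leading="spontaneous",
            )
            rho[i, j] = float(run.rho_I.max())
            cum_excess[j] = float(
                run.densities[-1, list(_EVER_INFECTED)].sum() - seed_fraction
            )
        above = np.where(cum_excess > floor)[0]
        emp[i] = beta_grid[above[0]] if above.size else np.nan
    return PhaseGrid(
        lam_grid=lam_grid,
        beta_grid=beta_grid,
        rho=rho,
        empirical_beta_c=emp,
        analytic_beta_c=ana,
        mode=mode,
    )
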