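"""MMCA probability recursion, order parameter, thresholds and phase grids."""

import numpy as np
import pytest
import scipy.sparse as sp

import coaware as ca
from coaware.mmca import (
    IA,
    IAP,
    RAP,
    SA,
    SU,
    MMCAState,
    initial_state,
    not_infected_prob,
    stay_unaware_prob,
)

from _oracles import random_valid_state, reference_step


class TestContactProbabilities:
    def test_zero_rate_gives_certainty(self, path3):
        P = initial_state(3).P
        q = not_infected_prob(P, np.zeros(3), path3)
        assert np.allclose(q, 1.0)
        r = stay_unaware_prob(P, np.zeros(3), path3)
        assert np.allclose(r, 1.0)

    def test_leading_factor_without_infected_neighbours(self, path3):
        P = np.zeros((3, 8))
        P[:, SU] = 1.0  # nobody infected
        q = not_infected_prob(P, np.full(3, 0.3), path3)
        assert np.allclose(q, 0.7)

    def test_single_certain_infected_neighbour(self):
        adj = sp.csr_matrix(np.array([[0, 1], [1, 0]], float))
        P = np.zeros((2, 8))
        P[0, SU] = 1.0
        P[1, IA] = 1.0
        q = not_infected_prob(P, np.array([0.5, 0.5]), adj)
        assert q[0] == pytest.approx(0.25)  # (1-0.5) * (1-0.5)

    def test_isolated_node_stays_unaware_with_own_rate(self):
        adj = sp.csr_matrix((1, 1))
        P = np.zeros((1, 8))
        P[0, SU] = 1.0
        r = stay_unaware_prob(P, np.array([0.4]), adj)
        assert r[0] == pytest.approx(0.6)

    def test_neighbour_rate_enters_awareness_product(self):
        adj = sp.csr_matrix(np.array([[0, 1], [1, 0]], float))
        P = np.zeros((2, 8))
        P[0, SU] = 1.0
        P[1, SA] = 1.0
        r = stay_unaware_prob(P, np.array([0.5, 0.5]), adj)
        assert r[0] == pytest.approx(0.25)

    def test_spontaneous_leading_mode(self, path3):
        P = np.zeros((3, 8))
        P[:, SU] = 1.0
        q = not_infected_prob(P, np.full(3, 0.3), path3, s=0.0, leading="spontaneous")
        assert np.allclose(q, 1.0)


class TestStep:
    def test_matches_symbolic_substitution(self, path3):
        rng = np.random.default_rng(0)
        params = ca.RateParameters(lam=0.3, beta=0.4, mu=0.25, delta=0.2, eps=0.6, s=0.05)
        for mode in ("conserving", "verbatim"):
            P = random_valid_state(rng, 3)
            bb, lb = rng.random(3), rng.random(3)
            got = ca.mmca_step(MMCAState(P=P, t=0), bb, lb, params, path3, mode=mode)
            want = reference_step(P, bb, lb, params, path3.toarray(), mode=mode)
            assert np.abs(got.P - want).max() < 1e-12

    def test_eps_zero_blocks_overlapping_states(self, path3):
        rng = np.random.default_rng(1)
        P = random_valid_state(rng, 3)
        P[:, [IAP, RAP]] = 0.0
        P /= P.sum(axis=1, keepdims=True)
        params = ca.RateParameters(eps=0.0)
        st = ca.mmca_step(MMCAState(P=P, t=0), rng.random(3), rng.random(3), params, path3)
        assert np.all(st.P[:, IAP] == 0.0)
        assert np.all(st.P[:, RAP] == 0.0)

    def test_delta_zero_from_all_unaware(self, path3):
        P = np.zeros((3, 8))
        P[:, SU] = 1.0
        lb = np.array([0.4, 0.4, 0.4])
        params = ca.RateParameters(delta=0.0, beta=0.0, s=0.0)
        r = stay_unaware_prob(P, lb, path3)
        st = ca.mmca_step(MMCAState(P=P, t=0), np.zeros(3), lb, params, path3)
        assert np.allclose(st.P[:, SA], 1 - r)
        assert np.allclose(st.P[:, SU], r)
        other = [i for i in range(8) if i not in (SU, SA)]
        assert np.allclose(st.P[:, other], 0.0)

    def test_conserving_rows_sum_to_one(self, path3):
        rng = np.random.default_rng(2)
        P = random_valid_state(rng, 3)
        st = MMCAState(P=P, t=0)
        params = ca.RateParameters()
        for _ in range(50):
            st = ca.mmca_step(st, rng.random(3), rng.random(3), params, path3)
            assert np.abs(st.P.sum(axis=1) - 1).max() < 1e-9

    def test_verbatim_mode_leaks_terminal_mass(self, path3):
        P = np.zeros((3, 8))
        P[:, 7] = 1.0  # all mass recovered-faded
        st = ca.mmca_step(
            MMCAState(P=P, t=0), np.zeros(3), np.zeros(3), ca.RateParameters(), path3,
            mode="verbatim",
        )
        assert st.P.sum() == pytest.approx(0.0)


class TestRun:
    def test_no_infection_source_stays_clean(self, path3):
        params = ca.RateParameters(beta=0.0, s=0.0)
        res = ca.run_mmca(path3, np.zeros(3), np.full(3, 0.3), params, infected_fraction=0.0)
        assert np.all(res.rho_I == 0.0)

    def test_instant_recovery_extinguishes(self, path3):
        params = ca.RateParameters(mu=1.0, eps=0.0, beta=0.0, s=0.0)
        res = ca.run_mmca(path3, np.zeros(3), np.zeros(3), params, infected_fraction=0.5, aware_fraction=0.0)
        assert res.rho_I[0] == pytest.approx(0.5)
        assert res.rho_I[-1] == pytest.approx(0.0, abs=1e-12)

    def test_trajectory_well_formed(self, elected):
        _, _, bb, lb, contacts = elected
        res = ca.run_mmca(contacts, bb, lb, ca.RateParameters(), t_max=100)
        assert np.all((res.densities >= -1e-12) & (res.densities <= 1 + 1e-12))
        assert np.allclose(res.densities.sum(axis=1), 1.0, atol=1e-9)
        frame = res.to_frame()
        assert set(frame.columns) == {"t", "state", "density"}

    def test_epsilon_reduction_over_full_run(self, elected):
        _, _, bb, lb, contacts = elected
        res = ca.run_mmca(contacts, bb, lb, ca.RateParameters(eps=0.0), t_max=200)
        assert np.all(res.densities[:, [IAP, RAP]] == 0.0)


class TestOrderParameter:
    def test_values(self):
        P = np.zeros((4, 8))
        st = MMCAState(P=P, t=0)
        assert ca.order_parameter(st) == 0.0
        P[:, IA] = 0.2
        assert ca.order_parameter(st) == pytest.approx(0.2)
        P[:, IA] = [1, 0, 0, 0]
        assert ca.order_parameter(st) == pytest.approx(0.25)

    def test_inclusive_variant(self):
        P = np.zeros((2, 8))
        P[:, IA] = 0.1
        P[:, IAP] = 0.3
        st = MMCAState(P=P, t=0)
        assert ca.order_parameter(st) == pytest.approx(0.1)
        assert ca.order_parameter(st, include_overlapping=True) == pytest.approx(0.4)


class TestThreshold:
    def test_two_by_two(self):
        adj = sp.csr_matrix(np.array([[0, 1], [1, 0]], float))
        params = ca.RateParameters(mu=0.3, eps=0.0)
        # psi_bar * p_sa = 0.5 gives H0 = [[0, .5], [.5, 0]]
        bc = ca.contagion_threshold(adj, np.full(2, 0.5), params, p_sa=np.ones(2))
        assert bc == pytest.approx(0.6)

    def test_star_k14(self):
        a = np.zeros((5, 5))
        a[0, 1:] = 1
        a[1:, 0] = 1
        adj = sp.csr_matrix(a)
        params = ca.RateParameters(mu=0.2, eps=0.0)
        bc = ca.contagion_threshold(adj, np.ones(5), params, p_sa=np.ones(5))
        assert bc == pytest.approx(0.1)  # Lambda_max = sqrt(4)

    def test_full_overlap_suppresses_contagion(self, path3):
        params = ca.RateParameters(mu=0.3, eps=1.0)
        bc = ca.contagion_threshold(path3, np.ones(3), params, p_sa=np.ones(3))
        assert bc == np.inf

    def test_empty_contact_graph(self):
        adj = sp.csr_matrix((3, 3))
        bc = ca.contagion_threshold(adj, np.ones(3), ca.RateParameters(), p_sa=np.ones(3))
        assert bc == np.inf

    def test_threshold_monotone_in_eps(self, elected):
        ranking, rm, _, lb, contacts = elected
        psi = rm.Psi[:, ranking.elected_layer]
        p_sa = ca.awareness_steady_state(contacts, lb)
        prev = 0.0
        for eps in (0.0, 0.3, 0.6, 0.9):
            bc = ca.contagion_threshold(
                contacts, psi, ca.RateParameters(eps=eps), p_sa=p_sa
            )
            assert bc >= prev
            prev = bc

    def test_analytic_neglects_overlap_channel(self, elected):
        """For eps > 0 the eigenvalue formula ignores the infectious IA^pi
        state and therefore overestimates the dynamic onset."""
        ranking, rm, _, lb, contacts = elected
        psi = rm.Psi[:, ranking.elected_layer]
        params = ca.RateParameters(eps=0.7, delta=0.0)
        bc = ca.contagion_threshold(contacts, psi, params, lam_bar=lb)
        grid = np.arange(0.002, 0.2, 0.002)
        emp = ca.empirical_threshold(
            contacts, lambda b: np.clip(psi * b, 0, 1), lb, params, grid
        )
        assert emp <= bc + 1e-12


class TestPhaseDiagram:
    def test_single_cell(self, small_net):
        pg = ca.phase_diagram(small_net, ca.RateParameters(), [0.2], [0.1])
        assert pg.rho.shape == (1, 1)
        assert 0.0 <= pg.rho[0, 0] <= 1.0

    def test_zero_beta_column_is_clean(self, small_net):
        pg = ca.phase_diagram(small_net, ca.RateParameters(s=0.0), [0.2], [0.0, 0.2])
        assert pg.rho[0, 0] <= 1e-4 + 1e-12  # only the seed, which decays

    def test_rho_monotone_in_beta(self, small_net):
        pg = ca.phase_diagram(
            small_net, ca.RateParameters(eps=0.3), [0.2], np.arange(0.02, 0.2, 0.03)
        )
        assert np.all(np.diff(pg.rho[0]) >= -1e-6)

    def test_empty_grid_rejected(self, small_net):
        with pytest.raises(ValueError):
            ca.phase_diagram(small_net, ca.RateParameters(), [], [0.1])
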