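"""Fixed-point solver and discrete-event simulator of the G-Network core."""

import numpy as np
import pytest

from gnetox.network import (
    DegenerateNetworkError,
    RNNetwork,
    simulate_network,
    solve_fixed_point,
)


def single_cell(Lambda, lam, r):
    z = np.zeros((1, 1))
    return RNNetwork(z, z, [Lambda], [lam], [r])


def random_stable_net(rng, n):
    wp = rng.uniform(0, 0.3, (n, n))
    wm = rng.uniform(0, 0.3, (n, n))
    np.fill_diagonal(wp, 0)
    np.fill_diagonal(wm, 0)
    Lam = rng.uniform(0, 0.3, n)
    lam = rng.uniform(0, 0.3, n)
    r = np.maximum(1.0, (wp + wm).sum(axis=1) + 0.1)
    return RNNetwork(wp, wm, Lam, lam, r)


class TestSolveFixedPoint:
    def test_single_cell_closed_form(self):
        ss = solve_fixed_point(single_cell(0.4, 0.1, 1.0))
        assert ss.q[0] == pytest.approx(0.4 / 1.1, abs=1e-10)
        assert ss.converged and ss.stable

    def test_no_excitation_source_gives_zero(self):
        rng = np.random.default_rng(3)
        n = 4
        wm = rng.uniform(0, 0.5, (n, n))
        np.fill_diagonal(wm, 0)
        net = RNNetwork(np.zeros((n, n)), wm, np.zeros(n),
                        rng.uniform(0, 1, n), wm.sum(axis=1) + 1.0)
        assert np.all(solve_fixed_point(net).q == 0)

    def test_feed_forward_cascade_matches_direct_evaluation(self):
        # upper-triangular wiring: q computable cell by cell in order
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            wp = np.triu(rng.uniform(0, 0.4, (n, n)), k=1)
            wm = np.triu(rng.uniform(0, 0.4, (n, n)), k=1)
            Lam = rng.uniform(0, 0.5, n)
            lam = rng.uniform(0, 0.3, n)
            r = (wp + wm).sum(axis=1) + rng.uniform(0.5, 1.5, n)
            net = RNNetwork(wp, wm, Lam, lam, r)
            q = np.zeros(n)
            for i in range(n):
                num = Lam[i] + q @ wp[:, i]
                den = r[i] + lam[i] + q @ wm[:, i]
                q[i] = min(1.0, num / den)
            ss = solve_fixed_point(net, tol=1e-14)
            np.testing.assert_allclose(ss.q, q, atol=1e-10)

    def test_monotone_in_exogenous_rates(self):
        # On excitatory-coupled networks (no inhibitory synapses) the fixed
        # point is a monotone system: every q is non-decreasing in any
        # Lambda(i) and non-increasing in any lam(i).  (With inhibitory
        # synapses componentwise monotonicity fails: raising one cell's
        # excitation raises the inhibition it sends onward.)
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_stable_net(rng, 3)
            net.w_minus[:] = 0.0
            net.r = np.maximum(1.0, net.w_plus.sum(axis=1) + 0.1)
            base = solve_fixed_point(net, tol=1e-12).q
            for i in range(3):
                up = RNNetwork(net.w_plus, net.w_minus, net.Lambda.copy(),
                               net.lam, net.r)
                up.Lambda[i] += 0.1
                assert np.all(solve_fixed_point(up, tol=1e-12).q >= base - 1e-9)
                dn = RNNetwork(net.w_plus, net.w_minus, net.Lambda,
                               net.lam.copy(), net.r)
                dn.lam[i] += 0.1
                assert np.all(solve_fixed_point(dn, tol=1e-12).q <= base + 1e-9)

    def test_own_cell_monotone_in_own_rates(self):
        # in the general (inhibitory-coupled) case, a cell's own q still
        # responds monotonically to its own exogenous rates
        rng = np.random.default_rng(13)
        for _ in range(5):
            net = random_stable_net(rng, 3)
            base = solve_fixed_point(net, tol=1e-12).q
            for i in range(3):
                up = RNNetwork(net.w_plus, net.w_minus, net.Lambda.copy(),
                               net.lam, net.r)
                up.Lambda[i] += 0.1
                assert solve_fixed_point(up, tol=1e-12).q[i] >= base[i] - 1e-9
                dn = RNNetwork(net.w_plus, net.w_minus, net.Lambda,
                               net.lam.copy(), net.r)
                dn.lam[i] += 0.1
                assert solve_fixed_point(dn, tol=1e-12).q[i] <= base[i] + 1e-9

    def test_unstable_network_flagged_and_clamped(self):
        ss = solve_fixed_point(single_cell(5.0, 0.0, 1.0))
        assert ss.q[0] == 1.0
        assert not ss.stable

    def test_degenerate_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_fixed_point(single_cell(0.4, 0.0, 0.0))  # r = 0
        with pytest.raises(ValueError):
            solve_fixed_point(single_cell(np.nan, 0.0, 1.0))
        with pytest.raises(ValueError):
            solve_fixed_point(single_cell(-0.1, 0.0, 1.0))
        with pytest.raises(ValueError):
            solve_fixed_point(single_cell(0.4, 0.1, 1.0), tol=0.0)

    def test_self_loop_rejected(self):
        w = np.array([[0.2]])
        net = RNNetwork(w, np.zeros((1, 1)), [0.1], [0.0], [1.0])
        with pytest.raises(ValueError, match="self-loop"):
            solve_fixed_point(net)


class TestSimulateNetwork:
    def test_no_excitation_gives_zero_occupancy(self):
        net = single_cell(0.0, 0.3, 1.0)
        sim = simulate_network(net, horizon=500.0, seed=0)
        assert np.all(sim.occupancy == 0)

    def test_mm1_occupancy(self):
        # single cell, Lambda=0.5, r=1: birth-death chain with rho = 0.5
        net = single_cell(0.5, 0.0, 1.0)
        sim = simulate_network(net, horizon=1e5, seed=4)
        assert abs(sim.occupancy[0] - 0.5) <= 3 * sim.stderr[0]

    def test_two_cell_chain_matches_solver(self):
        # cell 0 excites cell 1
        wp = np.array([[0.0, 0.4], [0.0, 0.0]])
        wm = np.zeros((2, 2))
        net = RNNetwork(wp, wm, [0.5, 0.1], [0.0, 0.1], [1.0, 1.0])
        ss = solve_fixed_point(net)
        sim = simulate_network(net, horizon=1e5, seed=5)
        assert np.all(np.abs(ss.q - sim.occupancy) <= 3 * sim.stderr)

    def test_zero_total_event_rate_rejected(self):
        net = single_cell(0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="event rate"):
            simulate_network(net, horizon=100.0, seed=0)


def test_network_yaml_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    net = random_stable_net(rng, 3)
    net.input_cells = (0, 1)
    net.output_cell = 2
    path = tmp_path / "net.yaml"
    net.to_yaml(path)
    back = RNNetwork.from_yaml(path)
    np.testing.assert_allclose(back.w_plus, net.w_plus)
    np.testing.assert_allclose(back.r, net.r)
    assert back.input_cells == (0, 1)
    assert back.output_cell == 2
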