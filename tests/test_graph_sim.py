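"""Graph-Ising Metropolis dynamics and the edge-removal protocol."""

import itertools

import numpy as np
import pytest

from isingbrain import (
    Connectome,
    SimConfig,
    edge_removal_experiment,
    er_connectome,
    metropolis_run,
    pmf,
    read_connectome,
    write_connectome,
)
from isingbrain.synchrony import empirical_moments


def exact_synchrony_marginal(g: Connectome, j_edge: float):
    """Oracle: exact Boltzmann marginal of synchrony by full enumeration."""
    weights = {}
    for config in itertools.product([-1, 1], repeat=g.n_nodes):
        spins = np.array(config)
        logw = j_edge * sum(spins[i] * spins[j] for i, j in g.edges)
        s = spins.sum() / g.n_nodes
        weights[s] = weights.get(s, 0.0) + np.exp(logw)
    total = sum(weights.values())
    return {s: w / total for s, w in weights.items()}


def empirical_hist(series, n_nodes):
    grid = np.arange(-n_nodes, n_nodes + 1, 2) / n_nodes
    counts = {s: 0 for s in np.round(grid, 12)}
    for v in np.round(series, 12):
        counts[v] += 1
    return {s: c / len(series) for s, c in counts.items()}


class TestErConnectome:
    def test_density_extremes(self):
        full = er_connectome(10, 1.0, 0)
        assert full.n_edges == 45 and full.avg_degree == 9.0
        empty = er_connectome(10, 0.0, 0)
        assert empty.n_edges == 0

    def test_expected_edge_count(self):
        counts = [er_connectome(64, 0.40, seed).n_edges for seed in range(20)]
        # binomial(2016, 0.4): mean 806.4, sd ~22; the 20-seed mean is ~5x tighter
        assert abs(np.mean(counts) - 0.40 * 2016) < 25

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            er_connectome(10, 1.5, 0)

    def test_connectome_validation(self):
        with pytest.raises(ValueError):
            Connectome(4, [(0, 0)])  # self-loop
        with pytest.raises(ValueError):
            Connectome(4, [(0, 7)])  # out of range
        g = Connectome(4, [(2, 0), (0, 2), (1, 3)])  # dedup + ordering
        assert g.n_edges == 2

    def test_csr_adjacency(self):
        g = Connectome(4, [(0, 1), (1, 2), (0, 3)])
        indptr, indices = g.adjacency_csr()
        neigh = {i: sorted(indices[indptr[i]:indptr[i + 1]]) for i in range(4)}
        assert neigh == {0: [1, 3], 1: [0, 2], 2: [1], 3: [0]}


class TestMetropolis:
    def test_free_spins_match_binomial(self):
        g = er_connectome(32, 0.5, 3)
        cfg = SimConfig(seed=3, lam0=0.0, n_steps=4000, flips_per_step=320)
        s = metropolis_run(g, cfg)
        mom = empirical_moments(s)
        # m2 = 1/32 with MC standard error ~ sqrt(2)/32/sqrt(T)
        assert mom.m2 == pytest.approx(1 / 32, abs=4 * np.sqrt(2) / 32 / np.sqrt(4000))

    def test_series_on_parity_grid(self):
        g = er_connectome(15, 0.3, 7)
        s = metropolis_run(g, SimConfig(seed=7, n_steps=200, flips_per_step=150, lam0=5.0))
        scaled = s * 15
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)
        assert np.all((np.round(scaled).astype(int) - 15) % 2 == 0)

    def test_reproducible_given_seed(self):
        g = er_connectome(20, 0.4, 11)
        cfg = SimConfig(seed=11, n_steps=100, flips_per_step=100, lam0=10.0)
        np.testing.assert_array_equal(metropolis_run(g, cfg), metropolis_run(g, cfg))

    def test_complete_graph_matches_meanfield_pmf(self):
        # per-edge coupling 2*lam/n^2 on the complete graph must sample the
        # exact mean-field magnetization distribution
        n, lam = 10, 5.0
        g = er_connectome(n, 1.0, 0)
        cfg = SimConfig(seed=21, lam0=lam, n_steps=20000, flips_per_step=100,
                        burn_in=500)
        series = metropolis_run(g, cfg)
        hist = empirical_hist(series, n)
        d = pmf(n, lam)
        tvd = 0.5 * sum(
            abs(hist[np.round(s, 12)] - p)
            for s, p in zip(d.synchrony_grid, d.probs)
        )
        assert tvd < 0.05

    def test_detailed_balance_on_tiny_graph(self):
        # stationary distribution on an arbitrary 6-node graph matches the
        # exact Boltzmann synchrony marginal by enumeration
        g = er_connectome(6, 0.5, 5)
        j_edge = 2.0 * 4.0 / 36
        cfg = SimConfig(seed=5, lam0=4.0, n_steps=30000, flips_per_step=30,
                        burn_in=500)
        series = metropolis_run(g, cfg)
        oracle = exact_synchrony_marginal(g, j_edge)
        hist = empirical_hist(series, 6)
        tvd = 0.5 * sum(abs(hist.get(round(s, 12), 0.0) - p)
                        for s, p in oracle.items())
        assert tvd < 0.05

    def test_binder_cumulant_orders_across_critical_coupling(self):
        # disordered phase: U = 1 - m4/(3 m2^2) ~ 0; ordered phase: U -> 2/3
        n = 16
        g = er_connectome(n, 1.0, 0)
        for lam, lo, hi in [(2.0, -0.2, 0.15), (24.0, 0.45, 0.7)]:
            cfg = SimConfig(seed=9, lam0=lam, n_steps=8000, flips_per_step=160,
                            burn_in=500)
            mom = empirical_moments(metropolis_run(g, cfg))
            u = 1 - mom.m4 / (3 * mom.m2**2)
            assert lo < u < hi, f"lam={lam}: U={u}"

    def test_zero_delta_always_accepted(self):
        # with no edges every proposal has dlogW = 0 and must be accepted:
        # successive synchrony steps then perform an unbiased spin-flip walk
        g = Connectome(12, np.empty((0, 2), dtype=int))
        cfg = SimConfig(seed=2, lam0=86.0, n_steps=2000, flips_per_step=120)
        s = metropolis_run(g, cfg)
        assert empirical_moments(s).m2 == pytest.approx(1 / 12, rel=0.25)


class TestEdgeRemoval:
    def test_zero_rounds_single_record(self):
        g = er_connectome(16, 0.5, 1)
        cfg = SimConfig(seed=1, lam0=8.0, n_steps=100, flips_per_step=64,
                        removal_rounds=0)
        traj = edge_removal_experiment(g, cfg)
        assert len(traj.records) == 1
        assert np.isnan(traj.spearman_rho)

    def test_edge_counts_conserved(self):
        g = er_connectome(20, 0.6, 2)
        cfg = SimConfig(seed=2, lam0=8.0, n_steps=50, flips_per_step=40,
                        removal_batch=4, removal_rounds=6)
        traj = edge_removal_experiment(g, cfg)
        expected = g.n_edges - 4 * np.arange(7)
        np.testing.assert_array_equal(traj.records["n_edges"], expected)
        np.testing.assert_allclose(
            traj.records["avg_degree"], 2 * expected / 20
        )

    def test_truncates_when_graph_exhausted(self):
        g = er_connectome(8, 0.5, 3)  # ~14 edges
        cfg = SimConfig(seed=3, lam0=8.0, n_steps=30, flips_per_step=16,
                        removal_batch=6, removal_rounds=50)
        with pytest.warns(UserWarning):
            traj = edge_removal_experiment(g, cfg)
        assert len(traj.records) < 51
        assert traj.records["n_edges"].iloc[-1] < 6

    def test_removal_raises_pseg(self):
        # shortened protocol: pruning a supercritical system toward the
        # disordered phase drives Pseg up as average degree falls
        g = er_connectome(32, 0.5, 4)
        cfg = SimConfig(seed=4, lam0=40.0, n_steps=400, flips_per_step=320,
                        removal_batch=15, removal_rounds=12)
        traj = edge_removal_experiment(g, cfg)
        assert traj.spearman_rho < -0.8
        assert traj.records["pseg"].iloc[-1] > traj.records["pseg"].iloc[0]


def test_connectome_io_roundtrip(tmp_path):
    g = er_connectome(12, 0.4, 9)
    adj = tmp_path / "adj.tsv"
    edg = tmp_path / "edges.tsv"
    write_connectome(g, adj, fmt="adjacency")
    write_connectome(g, edg, fmt="edgelist")
    for back in (read_connectome(adj), read_connectome(edg)):
        np.testing.assert_array_equal(back.edges, g.edges)
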