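"""Synthetic generator: determinism, stated rates, regime properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from netcontagion import (
    DirectedNetwork,
    SimConfig,
    generate_dataset,
    generate_networks,
    generate_population,
    simulate_influence_attribute,
    simulate_norm_answers,
    simulate_reports,
    simulate_selection_reports,
)


class TestGeneratePopulation:
    def test_reporter_count_and_zones(self):
        cfg = SimConfig(zone_sizes=(50, 50), reporter_fraction=0.5)
        pop = generate_population(cfg, seed=0)
        assert len(pop) == 100
        assert pop["is_reporter"].sum() == 50
        assert set(pop["zone"]) == {1, 2}

    def test_deterministic(self):
        cfg = SimConfig(zone_sizes=(40, 30))
        a = generate_population(cfg, seed=7)
        b = generate_population(cfg, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_gender_ratio_within_binomial_band(self):
        cfg = SimConfig(zone_sizes=(5000, 5000), gender_ratio=1.0)
        pop = generate_population(cfg, seed=1)
        n_men = (pop["gender"] == "man").sum()
        lo, hi = stats.binom.interval(0.99, 10000, 0.5)
        assert lo <= n_men <= hi

    def test_zone_too_small(self):
        with pytest.raises(ValueError):
            SimConfig(zone_sizes=(1, 50))


class TestGenerateNetworks:
    def test_within_zone_mixing(self):
        cfg = SimConfig(zone_sizes=(100, 100), within_zone_mixing=0.95,
                        mean_degree=4)
        pop = generate_population(cfg, seed=2)
        net = generate_networks(pop, cfg, seed=3, layers=("chatting",))["chatting"]
        zones = pop["zone"].to_numpy()
        ii, jj = np.nonzero(net.adjacency)
        assert (zones[ii] == zones[jj]).mean() >= 0.90

    def test_zero_density(self):
        cfg = SimConfig(zone_sizes=(20, 20), mean_degree=0.0)
        pop = generate_population(cfg, seed=0)
        nets = generate_networks(pop, cfg, seed=0)
        assert all(net.tie_count == 0 for net in nets.values())

    def test_all_kin(self):
        cfg = SimConfig(zone_sizes=(30,), kin_fraction=1.0, mean_degree=3)
        pop = generate_population(cfg, seed=0)
        net = generate_networks(pop, cfg, seed=1, layers=("respect",))["respect"]
        assert (net.kin == net.adjacency).all()

    def test_reciprocity_tracks_parameter(self):
        cfg = SimConfig(zone_sizes=(150, 150), mean_degree=5, reciprocity=0.45)
        pop = generate_population(cfg, seed=4)
        net = generate_networks(pop, cfg, seed=5, layers=("advice",))["advice"]
        adj = net.adjacency
        recip = (adj & adj.T).sum() / adj.sum()
        assert abs(recip - 0.45) < 0.06


class TestSimulateReports:
    def _net(self, rng, n=60, p=0.1):
        adj = rng.random((n, n)) < p
        np.fill_diagonal(adj, False)
        return DirectedNetwork([f"x{i}" for i in range(n)], adjacency=adj)

    def test_noiseless_identity(self, rng):
        net = self._net(rng)
        rep = simulate_reports(net, set(net.roster), 1.0, 0.0, cap=None, seed=0)
        r_out, r_in, _, _ = rep.to_matrices(net.roster)
        assert (r_out == net.adjacency).all()
        assert (r_in == net.adjacency).all()

    def test_no_sensitivity_no_true_reports(self, rng):
        net = self._net(rng)
        rep = simulate_reports(net, set(net.roster), 0.0, 0.0, cap=None, seed=0)
        assert len(rep.out_reports) == 0 and len(rep.in_reports) == 0

    def test_reported_count_within_binomial_band(self, rng):
        net = self._net(np.random.default_rng(0), n=250, p=0.162)
        ties = net.tie_count
        assert ties > 9000  # enough volume for a tight band
        rep = simulate_reports(net, set(net.roster), 0.8, 0.0, cap=None, seed=1)
        lo, hi = stats.binom.interval(0.99, ties, 0.8)
        assert lo <= len(rep.out_reports) <= hi

    def test_cap_enforced(self, rng):
        net = self._net(rng, n=40, p=0.5)
        rep = simulate_reports(net, set(net.roster), 1.0, 0.0, cap=5, seed=2)
        per_ego = rep.out_reports.groupby("ego").size()
        assert per_ego.max() <= 5

    def test_nonreporters_silent(self, rng):
        net = self._net(rng)
        rep = simulate_reports(net, {net.roster[0]}, 1.0, 0.0, cap=None, seed=3)
        assert set(rep.out_reports["ego"]) <= {net.roster[0]}


class TestInfluenceRegime:
    def test_zero_contagion_matches_logistic_closed_form(self):
        """With theta_contagion = 0 outcomes are independent logistic:
        prevalence matches the closed form at n = 5000 within MC error."""
        cfg = SimConfig(zone_sizes=(5000,), mean_degree=3)
        pop = generate_population(cfg, seed=0)
        net = generate_networks(pop, cfg, seed=1, layers=("chatting",))["chatting"]
        theta0 = -2.0
        y = simulate_influence_attribute(
            net, None, {"intercept": theta0, "contagion_direct": 0.0},
            burn_in=50, seed=2)
        p = expit(theta0)
        se = np.sqrt(p * (1 - p) / 5000)
        assert abs(y.mean() - p) < 4 * se

    def test_contagion_raises_within_clique_concordance(self):
        """Two 12-cliques: strong contagion makes outcomes cluster by
        clique relative to the theta = 0 baseline."""
        n = 24
        adj = np.zeros((n, n), dtype=bool)
        adj[:12, :12] = True
        adj[12:, 12:] = True
        np.fill_diagonal(adj, False)
        net = DirectedNetwork([f"c{i}" for i in range(n)], adjacency=adj)

        def concordance(theta_c, seed):
            vals = []
            for s in range(20):
                y = simulate_influence_attribute(
                    net, None, {"intercept": 0.0, "contagion_direct": theta_c},
                    burn_in=80, seed=seed + s)
                for blk in (y[:12], y[12:]):
                    vals.append(max(blk.mean(), 1 - blk.mean()))
            return np.mean(vals)

        assert concordance(1.0, 100) > concordance(0.0, 200) + 0.1

    def test_empty_network_iid(self):
        net = DirectedNetwork([f"z{i}" for i in range(2000)])
        y = simulate_influence_attribute(
            net, None, {"intercept": 0.0, "contagion_direct": 5.0},
            burn_in=5, seed=0)
        assert abs(y.mean() - 0.5) < 0.05

    def test_nonfinite_theta_rejected(self):
        net = DirectedNetwork(["a", "b"])
        with pytest.raises(ValueError):
            simulate_influence_attribute(net, None, {"intercept": np.inf},
                                         burn_in=1, seed=0)


class TestSelectionRegime:
    def test_flat_blocks_independent_of_preference(self):
        cfg = SimConfig(zone_sizes=(64,), mean_degree=5, lambda1=1.0,
                        lambda0=0.0, sr_sd=0.0, dyad_sd=0.0)
        rng = np.random.default_rng(0)
        y = (rng.random(64) < 0.5).astype(int)
        _, truth = simulate_selection_reports(y, None, np.zeros((2, 2)), cfg,
                                              seed=1)
        table = np.zeros((2, 2))
        totals = np.zeros((2, 2))
        for i in range(64):
            for j in range(64):
                if i != j:
                    table[y[i], y[j]] += truth.adjacency[i, j]
                    totals[y[i], y[j]] += 1
        contingency = np.column_stack([table.ravel(),
                                       (totals - table).ravel()])
        _, pval, _, _ = stats.chi2_contingency(contingency)
        assert pval > 0.01

    def test_pro_pro_offset_raises_rate(self):
        cfg = SimConfig(zone_sizes=(64,), mean_degree=4, sr_sd=0.0, dyad_sd=0.0)
        rng = np.random.default_rng(1)
        y = (rng.random(64) < 0.5).astype(int)
        B = np.array([[0.0, 0.0], [0.0, 2.0]])
        _, truth = simulate_selection_reports(y, None, B, cfg, seed=2)
        rates = {}
        for a in range(2):
            for b in range(2):
                mask = np.outer(y == a, y == b) & ~np.eye(64, dtype=bool)
                rates[(a, b)] = truth.adjacency[mask].mean()
        assert rates[(1, 1)] == max(rates.values())

    def test_zero_density_intercept(self):
        cfg = SimConfig(zone_sizes=(30,), mean_degree=0.0, lambda1=1.0,
                        lambda0=0.0)
        y = np.zeros(30, dtype=int)
        _, truth = simulate_selection_reports(y, None, np.zeros((2, 2)), cfg,
                                              seed=0)
        assert truth.tie_count == 0


class TestNormAnswers:
    def test_modal_report_tracks_prevalence(self):
        y = np.ones(4000, dtype=int)
        cfg = SimConfig()
        out = simulate_norm_answers(y, 0.10, cfg, seed=0, p_zero_pro=0.0)
        counts = out["empirical_expectation_men"].value_counts()
        assert counts.idxmax() == 10

    def test_anti_forced_zero(self):
        y = np.zeros(200, dtype=int)
        out = simulate_norm_answers(y, 0.10, SimConfig(), seed=0,
                                    p_zero_anti=1.0)
        assert (out["empirical_expectation_men"] == 0).all()
        assert (out["empirical_expectation_women"] == 0).all()

    def test_deciles_are_multiples_of_ten(self, rng):
        y = (rng.random(500) < 0.3).astype(int)
        out = simulate_norm_answers(y, 0.3, SimConfig(), seed=1)
        for col in ("empirical_expectation_men", "empirical_expectation_women"):
            assert set(out[col] % 10) == {0}


class TestGenerateDataset:
    def test_deterministic_end_to_end(self):
        cfg = SimConfig(zone_sizes=(25, 25), mean_degree=2)
        a = generate_dataset(cfg, seed=9)
        b = generate_dataset(cfg, seed=9)
        pd.testing.assert_frame_equal(a["population"], b["population"])
        pd.testing.assert_frame_equal(a["nominations"], b["nominations"])
        assert (a["truth"]["y"] == b["truth"]["y"]).all()

    def test_schema_round_trips_through_reader(self, tmp_path):
        from netcontagion import read_tables, write_tables

        cfg = SimConfig(zone_sizes=(25, 25), mean_degree=2)
        data = generate_dataset(cfg, seed=3)
        write_tables(data["population"], data["nominations"],
                     tmp_path / "r.csv", tmp_path / "n.csv")
        resp, noms = read_tables(tmp_path / "r.csv", tmp_path / "n.csv")
        assert len(resp) == 50
        assert set(noms["generator"]) <= {
            "chatting", "respect", "borrow_out", "borrow_in",
            "advice_out", "advice_in"}
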