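"""Latent-network estimation: noiseless limit, enumeration oracle,
threshold rule, deterministic baselines."""

import numpy as np
import pandas as pd
import pytest

from netcontagion import (
    DirectedNetwork,
    DoubleSampledReports,
    baseline_intersection,
    baseline_union,
    fit_latent_network,
    threshold_ties,
)
from netcontagion.latent_network import LatentNetworkModel
from netcontagion.synthetic_data import (SimConfig, generate_networks,
                                         generate_population, simulate_reports)

from oracles import latent_posterior_enumeration


def reports_from_rows(out_rows, in_rows, reporters):
    cols = ["ego", "generator", "alter", "kin", "relationship"]
    mk = lambda rows, gen: pd.DataFrame(
        [(e, gen, a, False, "x") for e, a in rows], columns=cols)
    return DoubleSampledReports(mk(out_rows, "advice_out"),
                                mk(in_rows, "advice_in"), set(reporters))


class TestNoiselessLimit:
    def test_rho_one_on_reports_prior_elsewhere(self):
        roster = ["a", "b", "c", "d"]
        rep = reports_from_rows([("a", "b")], [("b", "c")], roster)
        # in-report by b about c: tie c -> b
        est = fit_latent_network(rep, roster, seed=0, lambda1=1.0, lambda0=0.0,
                                 iterations=400, burn_in=100)
        assert est.rho_[0, 1] == 1.0
        assert est.rho_[2, 1] == 1.0
        # a fully contradicted pair (both eligible, nobody reported) ~ 0
        assert est.rho_[0, 2] < 0.05

    def test_reconstructs_true_network_exactly(self):
        cfg = SimConfig(zone_sizes=(40,), mean_degree=3)
        pop = generate_population(cfg, seed=1)
        net = generate_networks(pop, cfg, seed=2, layers=("advice",))["advice"]
        rep = simulate_reports(net, set(net.roster), 1.0, 0.0, cap=None, seed=3)
        est = fit_latent_network(rep, net.roster, seed=4, lambda1=1.0,
                                 lambda0=0.0, iterations=400, burn_in=100)
        assert est.binarized_.ties() == net.ties()


class TestEnumerationOracle:
    def test_four_node_posterior_matches_brute_force(self):
        """Gibbs posterior rho equals the exact posterior computed by
        summing over all 2^12 latent networks (fixed rates/mutuality)."""
        roster = ["a", "b", "c", "d"]
        rep = reports_from_rows(
            out_rows=[("a", "b"), ("b", "a"), ("c", "d")],
            in_rows=[("b", "a"), ("d", "a")],
            reporters=roster)
        lam1, lam0, alpha, beta = 0.85, 0.05, -1.5, 1.0
        est = fit_latent_network(rep, roster, seed=7, lambda1=lam1,
                                 lambda0=lam0, alpha=alpha, beta=beta,
                                 iterations=60000, burn_in=2000)
        r_out, r_in, e_out, e_in = rep.to_matrices(roster)
        k_mat = r_out.astype(int) + r_in.astype(int)
        m_mat = e_out.astype(int) + e_in.astype(int)
        exact = latent_posterior_enumeration(k_mat, m_mat, lam1, lam0,
                                             alpha, beta)
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs(est.rho_[off] - exact[off])) < 0.015

    def test_monotonicity_adding_confirming_report(self):
        """An extra confirming report never decreases rho (exact
        posteriors on the enumerable fixture)."""
        roster = ["a", "b", "c", "d"]
        base = reports_from_rows([("a", "b")], [], roster)
        more = reports_from_rows([("a", "b")], [("b", "a")], roster)
        lam1, lam0, alpha, beta = 0.8, 0.05, -1.0, 0.5
        posts = []
        for rep in (base, more):
            r_out, r_in, e_out, e_in = rep.to_matrices(roster)
            posts.append(latent_posterior_enumeration(
                r_out.astype(int) + r_in.astype(int),
                e_out.astype(int) + e_in.astype(int),
                lam1, lam0, alpha, beta))
        assert posts[1][0, 1] >= posts[0][0, 1]


class TestThreshold:
    def _estimate(self, eta):
        est = LatentNetworkModel()
        est.rho_ = np.array([[0.0, 0.05, 0.2], [0.9, 0.0, 0.0],
                             [0.0, 0.0, 0.0]])
        est.eta_est_ = eta
        est.roster_ = ["a", "b", "c"]
        return est

    def test_formula_endpoints(self):
        est0 = self._estimate(0.0)
        threshold_ties(est0)
        assert est0.t_rho_ == pytest.approx(0.10)
        est1 = self._estimate(1.0)
        threshold_ties(est1)
        assert est1.t_rho_ == pytest.approx(0.43)

    def test_threshold_selects_ties(self):
        est = self._estimate(0.3)  # t = 0.199
        net = threshold_ties(est)
        assert est.t_rho_ == pytest.approx(0.199)
        assert net.ties() == {("a", "c"), ("b", "a")}  # 0.2 and 0.9 only

    def test_eta_out_of_range_rejected(self):
        est = self._estimate(1.2)
        with pytest.raises(ValueError):
            threshold_ties(est)


class TestBaselines:
    def test_union_vs_intersection_single_report(self):
        roster = ["a", "b"]
        rep = reports_from_rows([("a", "b")], [], roster)
        assert baseline_union(rep, roster).ties() == {("a", "b")}
        assert baseline_intersection(rep, roster).tie_count == 0

    def test_both_sides_reported(self):
        roster = ["a", "b"]
        rep = reports_from_rows([("a", "b")], [("b", "a")], roster)
        assert baseline_union(rep, roster).ties() == {("a", "b")}
        assert baseline_intersection(rep, roster).ties() == {("a", "b")}

    @pytest.mark.parametrize("seed", range(4))
    def test_intersection_subset_of_union(self, seed):
        cfg = SimConfig(zone_sizes=(30,), mean_degree=3)
        pop = generate_population(cfg, seed=seed)
        net = generate_networks(pop, cfg, seed=seed + 1,
                                layers=("advice",))["advice"]
        reporters = set(pop.loc[pop["is_reporter"], "id"].astype(str))
        rep = simulate_reports(net, reporters, 0.7, 0.01, cap=10,
                               seed=seed + 2)
        assert (baseline_intersection(rep, net.roster).ties()
                <= baseline_union(rep, net.roster).ties())


class TestFitBehaviour:
    def test_empty_reports_rejected(self):
        rep = reports_from_rows([], [], ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            fit_latent_network(rep, ["a", "b"])

    def test_discrimination_on_noisy_reports(self):
        """Mean rho over true ties exceeds mean rho over non-ties
        (lambda1 = 0.8, lambda0 = 0.002, n = 300, fixed seed)."""
        cfg = SimConfig(zone_sizes=(150, 150), mean_degree=5, lambda1=0.8,
                        lambda0=0.002)
        pop = generate_population(cfg, seed=21)
        net = generate_networks(pop, cfg, seed=22, layers=("advice",))["advice"]
        reporters = set(pop.loc[pop["is_reporter"], "id"].astype(str))
        rep = simulate_reports(net, reporters, cfg.lambda1, cfg.lambda0,
                               cap=10, seed=23, zones=pop["zone"].to_numpy())
        est = fit_latent_network(rep, net.roster, seed=24, iterations=600,
                                 burn_in=200)
        off = ~np.eye(net.n, dtype=bool)
        true_ties = net.adjacency & off
        non_ties = ~net.adjacency & off
        assert est.rho_[true_ties].mean() > est.rho_[non_ties].mean() + 0.3

    def test_converges_to_union_in_low_noise_limit(self):
        """As lambda0 -> 0 and lambda1 -> 1 the thresholded latent network
        converges to the union of reports."""
        cfg = SimConfig(zone_sizes=(60,), mean_degree=3)
        pop = generate_population(cfg, seed=31)
        net = generate_networks(pop, cfg, seed=32, layers=("advice",))["advice"]
        reporters = set(pop.loc[pop["is_reporter"], "id"].astype(str))
        rep = simulate_reports(net, reporters, 0.98, 0.0005, cap=None, seed=33)
        est = fit_latent_network(rep, net.roster, seed=34, lambda1=0.98,
                                 lambda0=0.0005, iterations=600, burn_in=200)
        assert est.binarized_.ties() == baseline_union(rep, net.roster).ties()

    def test_reporters_scope_restricts_roster(self):
        roster = ["a", "b", "c"]
        rep = reports_from_rows([("a", "b")], [], ["a", "b"])
        est = fit_latent_network(rep, roster, seed=0, scope="reporters",
                                 iterations=200, burn_in=50)
        assert est.roster_ == ["a", "b"]

    def test_deterministic_given_seed(self):
        roster = ["a", "b", "c"]
        rep = reports_from_rows([("a", "b"), ("b", "c")], [("c", "a")], roster)
        a = fit_latent_network(rep, roster, seed=3, iterations=300, burn_in=50)
        b = fit_latent_network(rep, roster, seed=3, iterations=300, burn_in=50)
        assert np.array_equal(a.rho_, b.rho_)
        assert a.eta_est_ == b.eta_est_
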