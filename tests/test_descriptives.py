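"""Descriptives: overlap, structure, centrality, norms, prevalence."""

import numpy as np
import pandas as pd
import pytest

from netcontagion import (
    DirectedNetwork,
    SimConfig,
    centrality_profile,
    classify_norms,
    jaccard_overlap,
    network_summary,
    prevalence_table,
)
from netcontagion.synthetic_data import (generate_networks,
                                         generate_population,
                                         simulate_reports, generate_dataset)

from oracles import (betweenness_loops, harmonic_centrality_loops,
                     network_summary_loops)


def noms_for(ego_alters, generator="chatting"):
    rows = [{"ego": e, "generator": generator, "alter": a, "kin": False,
             "relationship": "x"} for e, alters in ego_alters.items()
            for a in alters]
    return pd.DataFrame(rows)


class TestJaccard:
    def test_half_overlap(self):
        noms = pd.concat([noms_for({"e": ["a", "b", "c"]}, "chatting"),
                          noms_for({"e": ["b", "c", "d"]}, "respect")])
        mean, per = jaccard_overlap(noms, "chatting", "respect")
        assert mean == pytest.approx(0.5)
        assert per["e"] == pytest.approx(0.5)

    @pytest.mark.parametrize("alters_b, expected", [
        (["a", "b", "c"], 1.0),
        (["x", "y"], 0.0),
    ])
    def test_identical_and_disjoint(self, alters_b, expected):
        noms = pd.concat([noms_for({"e": ["a", "b", "c"]}, "chatting"),
                          noms_for({"e": alters_b}, "respect")])
        assert jaccard_overlap(noms, "chatting", "respect")[0] == expected

    def test_symmetric_and_bounded(self, rng):
        rows = []
        for e in "pqrs":
            for gen in ("chatting", "respect"):
                alters = rng.choice(list("abcdefgh"),
                                    size=rng.integers(1, 5), replace=False)
                rows.append(noms_for({e: list(alters)}, gen))
        noms = pd.concat(rows)
        ab, _ = jaccard_overlap(noms, "chatting", "respect")
        ba, _ = jaccard_overlap(noms, "respect", "chatting")
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0

    def test_no_common_respondents_undefined(self):
        noms = pd.concat([noms_for({"e1": ["a"]}, "chatting"),
                          noms_for({"e2": ["a"]}, "respect")])
        mean, per = jaccard_overlap(noms, "chatting", "respect")
        assert np.isnan(mean) and len(per) == 0

    def test_unmatched_alters_ignored(self):
        noms = pd.concat([noms_for({"e": ["a", "UNMATCHED"]}, "chatting"),
                          noms_for({"e": ["a"]}, "respect")])
        assert jaccard_overlap(noms, "chatting", "respect")[0] == 1.0


class TestNetworkSummary:
    def test_three_cycle(self):
        net = DirectedNetwork.from_ties(
            ["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")])
        s = network_summary(net)
        assert s["reciprocity"] == 0.0
        assert s["transitivity"] == 1.0
        assert s["density"] == pytest.approx(3 / 6)
        assert s["isolates"] == 0

    def test_mutual_dyad(self):
        net = DirectedNetwork.from_ties(["a", "b", "c"],
                                        [("a", "b"), ("b", "a")])
        s = network_summary(net)
        assert s["reciprocity"] == 1.0
        assert s["isolates"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle_on_random_30_node(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        adj = rng.random((n, n)) < 0.08
        np.fill_diagonal(adj, False)
        net = DirectedNetwork([f"v{i}" for i in range(n)], adjacency=adj)
        got = network_summary(net)
        want = network_summary_loops(adj, n)
        for key, val in want.items():
            if isinstance(val, float) and np.isnan(val):
                assert np.isnan(got[key])
            else:
                assert got[key] == pytest.approx(val), key

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            network_summary(DirectedNetwork([]))

    def test_reciprocity_biased_down_under_half_reporting(self):
        """Reconstructing from half the roster's reports can only lose
        reciprocated pairs, never gain them."""
        cfg = SimConfig(zone_sizes=(60,), mean_degree=4, reciprocity=0.6)
        pop = generate_population(cfg, seed=3)
        net = generate_networks(pop, cfg, seed=4, layers=("chatting",))["chatting"]
        full = simulate_reports(net, set(net.roster), 1.0, 0.0, cap=None,
                                seed=5, generator_pair=("chatting", "unused"))
        half = simulate_reports(net, set(net.roster[:30]), 1.0, 0.0, cap=None,
                                seed=6, generator_pair=("chatting", "unused"))

        def observed(rep):
            r_out, _, _, _ = rep.to_matrices(net.roster)
            return network_summary(DirectedNetwork(net.roster, adjacency=r_out))

        assert observed(half)["reciprocity"] <= observed(full)["reciprocity"]


class TestCentrality:
    def test_star_in_degree(self):
        ties = [(f"s{i}", "hub") for i in range(5)]
        net = DirectedNetwork.from_ties(["hub"] + [f"s{i}" for i in range(5)],
                                        ties)
        table = centrality_profile(net)
        assert table.loc["hub", "in_degree"] == 5
        assert (table.loc[[f"s{i}" for i in range(5)], "in_degree"] == 0).all()

    def test_path_betweenness(self):
        net = DirectedNetwork.from_ties(["a", "b", "c"],
                                        [("a", "b"), ("b", "c")])
        table = centrality_profile(net)
        assert table.loc["b", "betweenness"] == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle_on_12_nodes(self, seed):
        rng = np.random.default_rng(seed + 50)
        n = 12
        adj = rng.random((n, n)) < 0.22
        np.fill_diagonal(adj, False)
        net = DirectedNetwork([f"v{i}" for i in range(n)], adjacency=adj)
        table = centrality_profile(net)
        harm = harmonic_centrality_loops(adj, n)
        bet = betweenness_loops(adj, n)
        assert np.allclose(table["harmonic"].to_numpy(), harm)
        assert np.allclose(table["betweenness"].to_numpy(), bet)

    def test_group_means_by_preference(self, small_network):
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        _, means = centrality_profile(small_network, y)
        assert set(means.index) <= {"pro", "anti"}


class TestClassifyNorms:
    def test_all_flags_false(self, toy_respondents):
        row = toy_respondents.iloc[[1]]  # men 0, women 0, disapprove
        flags, _ = classify_norms(row)
        r = flags.iloc[0]
        assert not r["empirical_expectation_present"]
        assert not r["perceived_support_ge_10"]
        assert not r["normative_approval"]
        assert not r["bicchieri_joint"]

    def test_joint_criterion(self, toy_respondents):
        row = toy_respondents.iloc[[0]]  # men 10, women 0, approve
        flags, _ = classify_norms(row)
        assert bool(flags.iloc[0]["bicchieri_joint"])

    def test_joint_implies_support(self, toy_respondents):
        flags, _ = classify_norms(toy_respondents)
        assert (~flags["bicchieri_joint"] | flags["perceived_support_ge_10"]).all()

    def test_out_of_range_decile_rejected(self, toy_respondents):
        bad = toy_respondents.copy()
        bad.loc[0, "empirical_expectation_men"] = 15
        with pytest.raises(ValueError):
            classify_norms(bad)

    def test_hand_built_aggregates(self):
        """20-row table with known counts: aggregates match hand tallies."""
        rows = []
        for k in range(20):
            pro = k < 5  # 5 pro, 15 anti
            rows.append({
                "id": f"h{k}", "zone": 1 if k < 10 else 2, "age": 30,
                "gender": "man", "education": "none",
                "community_role": "no_role", "religion": "muslim",
                "pref_daughter": "yes" if pro else "no",
                "pref_daughter_in_law": "no", "is_reporter": True,
                # pro: men decile 10; anti: 0.  women always 0
                "empirical_expectation_men": 10 if pro else 0,
                "empirical_expectation_women": 0,
                # 2 of the pro respondents approve, everyone else disapproves
                "normative_expectation": "approve" if k < 2 else "disapprove",
            })
        df = pd.DataFrame(rows)
        flags, agg = classify_norms(df)
        assert flags["bicchieri_joint"].sum() == 2
        by_pref = agg["by_preference"]
        assert by_pref.loc["pro", "pct_zero_men"] == 0.0
        assert by_pref.loc["anti", "pct_zero_men"] == 100.0
        assert by_pref.loc["pro", "pct_approve"] == pytest.approx(40.0)
        assert by_pref.loc["pro", "pct_pro_bicchieri_joint"] == pytest.approx(40.0)
        assert agg["overall"]["pct_zero_women"] == 100.0
        assert agg["by_zone"].loc[1, "n"] == 10


class TestPrevalenceTable:
    def test_ten_percent_zone(self):
        rows = []
        for k in range(10):
            rows.append({
                "id": f"z{k}", "zone": 1, "age": 20 + k,
                "gender": "man" if k < 5 else "woman",
                "education": "some_secondary_plus" if k == 0 else "none",
                "community_role": "no_role", "religion": "muslim",
                "pref_daughter": "yes" if k == 0 else "no",
                "pref_daughter_in_law": "no", "is_reporter": True,
                "empirical_expectation_men": 0,
                "empirical_expectation_women": 0,
                "normative_expectation": "disapprove",
            })
        t = prevalence_table(pd.DataFrame(rows))
        assert t.loc[1, "pct_pro"] == pytest.approx(10.0)
        assert t.loc[1, "gender_ratio"] == pytest.approx(1.0)
        assert t.loc[1, "pct_some_secondary_plus"] == pytest.approx(10.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            prevalence_table(pd.DataFrame(columns=["pref_daughter"]))

    def test_zone_ordering_follows_configured_intercepts(self):
        """Prevalence ordering across zones reproduces the configured
        ordering at n = 1000 per zone."""
        cfg = SimConfig(zone_sizes=(1000, 1000, 1000),
                        zone_prevalence=(0.12, 0.06, 0.014), mean_degree=2)
        data = generate_dataset(cfg, seed=11)
        t = prevalence_table(data["population"])
        assert t.loc[1, "pct_pro"] > t.loc[2, "pct_pro"] > t.loc[3, "pct_pro"]
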