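"""Layer-overlap, structure, centrality and norm-expectation descriptives.

Covers the descriptive surface of the analysis: Jaccard overlap between
name generators, per-layer structural characteristics (ties, density,
reciprocity, transitivity, isolates), centrality profiles by preference
class, per-zone preference prevalence, and the classification of
empirical/normative expectations culminating in the Bicchieri joint
criterion (perceiving >= 10% support *and* expecting approval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import UNMATCHED, DirectedNetwork, classify_preference

VALID_DECILES = set(range(0, 101, 10))


def jaccard_overlap(nominations: pd.DataFrame, generator_a: str, generator_b: str,
                    pooled: bool = False):
    """Jaccard similarity of the matched alter sets elicited by two
    name generators.

    By default (ego-wise) the coefficient |A_i ∩ B_i| / |A_i ∪ B_i| is
    computed per respondent i who nominated at least one matched alter
    under *both* generators, and the mean over those respondents is
    returned along with the per-respondent Series.  With ``pooled=True``
    a single coefficient over the pooled alter sets is returned instead.

    Returns ``(mean_or_pooled, per_respondent)``; NaN and an empty Series
    when no respondent used both generators.
    """
    sets = {}
    for gen in (generator_a, generator_b):
        sub = nominations[(nominations["generator"] == gen)
                          & (nominations["alter"] != UNMATCHED)]
        sets[gen] = sub.groupby(sub["ego"].astype(str))["alter"].apply(set)
    a, b = sets[generator_a], sets[generator_b]
    if pooled:
        pa = set().union(*a) if len(a) else set()
        pb = set().union(*b) if len(b) else set()
        union = pa | pb
        return (len(pa & pb) / len(union) if union else np.nan,
                pd.Series(dtype=float))
    both = sorted(set(a.index) & set(b.index))
    vals = pd.Series(
        {e: len(a[e] & b[e]) / len(a[e] | b[e]) for e in both}, dtype=float)
    return (float(vals.mean()) if len(vals) else np.nan), vals


def network_summary(network: DirectedNetwork, roster=None) -> pd.Series:
    """Structural characteristics of one layer.

    ties      number of directed ties
    density   ties / (n (n-1))
    reciprocity   share of ties whose reverse tie also exists
    transitivity  global clustering of the symmetrized graph
                  (closed 2-paths / all 2-paths)
    isolates  roster members with zero in- and out-degree
    """
    if roster is not None and list(roster) != network.roster:
        network = _reindex(network, roster)
    n = network.n
    if n == 0:
        raise ValueError("empty roster")
    adj = network.adjacency
    ties = int(adj.sum())
    density = ties / (n * (n - 1)) if n > 1 else 0.0
    reciprocity = float((adj & adj.T).sum() / ties) if ties else np.nan
    xp = (adj | adj.T).astype(np.int64)
    two_paths = int((xp @ xp).sum() - np.trace(xp @ xp))
    closed = int(np.trace(xp @ xp @ xp))
    transitivity = closed / two_paths if two_paths else np.nan
    isolates = int(((adj.sum(axis=0) + adj.sum(axis=1)) == 0).sum())
    return pd.Series({"ties": ties, "density": density,
                      "reciprocity": reciprocity, "transitivity": transitivity,
                      "isolates": isolates})


def _reindex(network: DirectedNetwork, roster) -> DirectedNetwork:
    roster = [str(r) for r in roster]
    out = DirectedNetwork(roster, layer=network.layer)
    for (i, j) in network.ties():
        if i in out._index and j in out._index:
            out.adjacency[out.index_of(i), out.index_of(j)] = True
    return out


def centrality_profile(network: DirectedNetwork, attributes=None):
    """Per-node centralities: in/out degree, directed shortest-path
    betweenness, and harmonic centrality (sum over other nodes of the
    inverse directed distance to the node; unreachable pairs contribute 0).

    If ``attributes`` (binary preference vector in roster order) is given,
    also returns group means per preference class:
    ``(table, group_means)``; otherwise just the table.
    """
    import networkx as nx

    g = network.to_networkx()
    bet = nx.betweenness_centrality(g, normalized=False)
    harm = nx.harmonic_centrality(g)
    table = pd.DataFrame({
        "in_degree": pd.Series(network.in_degree(), index=network.roster),
        "out_degree": pd.Series(network.out_degree(), index=network.roster),
        "betweenness": pd.Series(bet),
        "harmonic": pd.Series(harm),
    }).loc[network.roster]
    if attributes is None:
        return table
    y = np.asarray(attributes, dtype=int)
    table = table.assign(preference=np.where(y == 1, "pro", "anti"))
    group_means = table.groupby("preference").mean(numeric_only=True)
    return table, group_means


def classify_norms(respondents: pd.DataFrame):
    """Per-respondent norm-expectation flags and zone/preference aggregates.

    Flags per respondent:

    * ``empirical_expectation_present`` — any nonzero decile for men or women
    * ``perceived_support_ge_10`` — men or women decile >= 10
    * ``normative_approval`` — answered "approve"
    * ``bicchieri_joint`` — support >= 10% AND approval (the joint social
      norm criterion)

    Returns ``(flags, aggregates)`` where aggregates hold, per zone and
    per preference class, the share stating 0% for men / for women, the
    share per normative category, and the share of pro respondents
    meeting the joint criterion.
    """
    men = pd.to_numeric(respondents["empirical_expectation_men"])
    women = pd.to_numeric(respondents["empirical_expectation_women"])
    for col in (men, women):
        bad = ~col.isin(VALID_DECILES)
        if bad.any():
            raise ValueError(f"out-of-range decile value(s): "
                             f"{sorted(col[bad].unique())[:5]}")
    pref = respondents.apply(
        lambda r: classify_preference(r["pref_daughter"], r["pref_daughter_in_law"]),
        axis=1)
    flags = pd.DataFrame({
        "id": respondents["id"].astype(str),
        "zone": respondents["zone"],
        "preference": pref,
        "empirical_expectation_present": (men > 0) | (women > 0),
        "perceived_support_ge_10": (men >= 10) | (women >= 10),
        "normative_approval": respondents["normative_expectation"] == "approve",
    })
    flags["bicchieri_joint"] = (flags["perceived_support_ge_10"]
                                & flags["normative_approval"])

    def _agg(df, resp):
        m = pd.to_numeric(resp["empirical_expectation_men"])
        w = pd.to_numeric(resp["empirical_expectation_women"])
        norm = resp["normative_expectation"]
        pro = df["preference"] == "pro"
        return pd.Series({
            "n": len(df),
            "pct_zero_men": 100 * (m == 0).mean(),
            "pct_zero_women": 100 * (w == 0).mean(),
            "pct_approve": 100 * (norm == "approve").mean(),
            "pct_disapprove": 100 * (norm == "disapprove").mean(),
            "pct_none_business": 100 * (norm == "none_of_their_business").mean(),
            "pct_pro_bicchieri_joint": (
                100 * df.loc[pro, "bicchieri_joint"].mean() if pro.any() else np.nan),
        })

    resp = respondents.reset_index(drop=True)
    flags_r = flags.reset_index(drop=True)
    by_zone = pd.DataFrame({
        z: _agg(flags_r[resp["zone"] == z], resp[resp["zone"] == z])
        for z in sorted(resp["zone"].unique())}).T
    by_pref = pd.DataFrame({
        p: _agg(flags_r[flags_r["preference"] == p],
                resp[(flags_r["preference"] == p).to_numpy()])
        for p in ("pro", "anti")}).T
    overall = _agg(flags_r, resp).rename("overall")
    aggregates = {"by_zone": by_zone, "by_preference": by_pref,
                  "overall": overall}
    return flags, aggregates


def prevalence_table(respondents: pd.DataFrame) -> pd.DataFrame:
    """Per-zone sample size, gender ratio (men per woman), median age,
    share with some secondary education or beyond, and share pro."""
    if len(respondents) == 0:
        raise ValueError("empty respondent table")
    if respondents["pref_daughter"].isna().all():
        raise ValueError("preference column is empty")
    pref = respondents.apply(
        lambda r: classify_preference(r["pref_daughter"], r["pref_daughter_in_law"]),
        axis=1)
    df = respondents.assign(_pro=(pref == "pro"))
    rows = {}
    for z, zdf in df.groupby("zone"):
        men = (zdf["gender"] == "man").sum()
        women = (zdf["gender"] == "woman").sum()
        rows[z] = {
            "n": len(zdf),
            "gender_ratio": men / women if women else np.inf,
            "median_age": float(zdf["age"].median()),
            "pct_some_secondary_plus":
                100 * (zdf["education"] == "some_secondary_plus").mean(),
            "pct_pro": 100 * zdf["_pro"].mean(),
        }
    return pd.DataFrame(rows).T
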