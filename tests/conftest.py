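import numpy as np
import pandas as pd
import pytest

from netcontagion import DirectedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_network(rng):
    """Random 10-node directed network with kin flags."""
    n = 10
    adj = rng.random((n, n)) < 0.3
    np.fill_diagonal(adj, False)
    kin = (rng.random((n, n)) < 0.4) & adj
    return DirectedNetwork([f"p{i}" for i in range(n)], adjacency=adj, kin=kin)


@pytest.fixture
def toy_respondents():
    rows = []
    for k, (pd_, pdl, zone, men, women, norm) in enumerate([
        ("yes", "yes", 1, 10, 0, "approve"),
        ("no", "yes", 1, 0, 0, "disapprove"),
        ("no", "no", 2, 20, 10, "none_of_their_business"),
    ]):
        rows.append({
            "id": f"r{k}", "age": 30 + k, "gender": "woman" if k % 2 else "man",
            "education": "some_primary", "zone": zone, "community_role": "no_role",
            "religion": "muslim", "pref_daughter": pd_,
            "pref_daughter_in_law": pdl, "is_reporter": True,
            "empirical_expectation_men": men,
            "empirical_expectation_women": women,
            "normative_expectation": norm,
        })
    return pd.DataFrame(rows)


@pytest.fixture
def toy_nominations():
    return pd.DataFrame([
        {"ego": "r0", "generator": "chatting", "alter": "r1", "kin": True,
         "relationship": "brother"},
        {"ego": "r0", "generator": "chatting", "alter": "r2", "kin": False,
         "relationship": "friend"},
        {"ego": "r1", "generator": "advice_in", "alter": "r2", "kin": False,
         "relationship": "friend"},
        {"ego": "r2", "generator": "respect", "alter": "UNMATCHED", "kin": False,
         "relationship": "friend"},
    ])
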