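"""Data model for socio-centric survey networks.

Respondent and nomination tables are plain :class:`pandas.DataFrame` objects
with documented column schemas (see :data:`RESPONDENT_COLUMNS` and
:data:`NOMINATION_COLUMNS`); per-layer directed networks are stored as a
dense boolean adjacency over an ordered roster.  Row order of the roster
defines the vector index order used by every downstream model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an alter who could not be matched to a roster id.
UNMATCHED = "UNMATCHED"

#: The six name generators.  ``borrow_in`` / ``advice_in`` are the
#: "who would come to you" sides of the two double-sampled pairs.
GENERATORS = (
    "chatting",
    "respect",
    "borrow_out",
    "borrow_in",
    "advice_out",
    "advice_in",
)

#: Generators whose reports describe the relation from the alter's side:
#: a report "B would come to me (A)" is evidence for the directed tie B -> A.
IN_DIRECTION = frozenset({"borrow_in", "advice_in"})

#: The double-sampled generator pairs, keyed by latent-layer name.
DOUBLE_SAMPLED = {"money": ("borrow_out", "borrow_in"), "advice": ("advice_out", "advice_in")}

RESPONDENT_COLUMNS = [
    "id",
    "age",
    "gender",
    "education",
    "zone",
    "community_role",
    "religion",
    "pref_daughter",
    "pref_daughter_in_law",
    "is_reporter",
    "empirical_expectation_men",
    "empirical_expectation_women",
    "normative_expectation",
]

NOMINATION_COLUMNS = ["ego", "generator", "alter", "kin", "relationship"]

EDUCATION_LEVELS = ("none", "some_primary", "completed_primary", "some_secondary_plus")
NORMATIVE_LEVELS = ("approve", "disapprove", "none_of_their_business")


class DirectedNetwork:
    """A directed network over an ordered roster, with kin flags on ties.

    Parameters
    ----------
    roster : sequence of str
        Ordered respondent ids; index order defines all vector orders.
    adjacency : (n, n) bool array, optional
        ``adjacency[i, j]`` is True iff the tie i -> j exists. Zero diagonal.
    kin : (n, n) bool array, optional
        Kin flag per tie (only meaningful where ``adjacency`` is True).
    layer : str
        Label of the layer this network represents.
    """

    def __init__(self, roster, adjacency=None, kin=None, layer=""):
        self.roster = [str(r) for r in roster]
        n = len(self.roster)
        if len(set(self.roster)) != n:
            raise ValueError("roster contains duplicate ids")
        if adjacency is None:
            adjacency = np.zeros((n, n), dtype=bool)
        adjacency = np.asarray(adjacency, dtype=bool).copy()
        if adjacency.shape != (n, n):
            raise ValueError(f"adjacency shape {adjacency.shape} != ({n}, {n})")
        np.fill_diagonal(adjacency, False)
        self.adjacency = adjacency
        if kin is None:
            kin = np.zeros((n, n), dtype=bool)
        self.kin = np.asarray(kin, dtype=bool).copy() & adjacency
        self.layer = layer
        self._index = {r: i for i, r in enumerate(self.roster)}

    # -- construction ----------------------------------------------------
    @classmethod
    def from_ties(cls, roster, ties, kin_ties=(), layer=""):
        """Build from an iterable of ``(ego_id, alter_id)`` pairs."""
        net = cls(roster, layer=layer)
        kin_ties = set(kin_ties)
        for i, j in ties:
            a, b = net._index[str(i)], net._index[str(j)]
            if a == b:
                raise ValueError(f"self-tie on {i}")
            net.adjacency[a, b] = True
            if (i, j) in kin_ties:
                net.kin[a, b] = True
        return net

    # -- basic queries ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def tie_count(self) -> int:
        return int(self.adjacency.sum())

    def ties(self):
        """Return the tie set as ``{(ego_id, alter_id), ...}``."""
        ii, jj = np.nonzero(self.adjacency)
        return {(self.roster[i], self.roster[j]) for i, j in zip(ii, jj)}

    def index_of(self, rid) -> int:
        return self._index[str(rid)]

    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def in_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def symmetrized(self) -> np.ndarray:
        """The undirected ``x+`` adjacency: max(x_ij, x_ji)."""
        return self.adjacency | self.adjacency.T

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.roster)
        for (i, j) in sorted(self.ties()):
            g.add_edge(i, j, kin=bool(self.kin[self._index[i], self._index[j]]))
        return g

    def write_graphml(self, path):
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def __repr__(self):  # pragma: no cover - debugging aid
        return (
            f"DirectedNetwork(layer={self.layer!r}, n={self.n}, "
            f"ties={self.tie_count})"
        )


@dataclass
class DoubleSampledReports:
    """Raw nominations for the two sides of a double-sampled generator.

    ``out_reports`` come from the "who would you go to" side and
    ``in_reports`` from the "who would come to you" side; each is a
    nomination DataFrame restricted to one generator.  ``reporter_set``
    holds the ids of everyone who was able to report.
    """

    out_reports: pd.DataFrame
    in_reports: pd.DataFrame
    reporter_set: set = field(default_factory=set)

    def __post_init__(self):
        self.reporter_set = {str(r) for r in self.reporter_set}
        for df in (self.out_reports, self.in_reports):
            egos = set(df["ego"].astype(str))
            bad = egos - self.reporter_set
            if bad:
                raise ValueError(
                    f"report ego(s) not in reporter_set: {sorted(bad)[:5]}"
                )

    def to_matrices(self, roster):
        """Evidence and eligibility matrices over ordered pairs of ``roster``.

        Returns ``(r_out, r_in, e_out, e_in)`` boolean (n, n) arrays where
        ``r_out[i, j]`` means reporter i named j on the out side (evidence
        for tie i -> j), ``r_in[i, j]`` means reporter j named i on the in
        side (evidence for the same tie i -> j after direction reversal),
        and ``e_out`` / ``e_in`` mark which reports could have been made.
        """
        roster = [str(r) for r in roster]
        index = {r: k for k, r in enumerate(roster)}
        n = len(roster)
        r_out = np.zeros((n, n), dtype=bool)
        r_in = np.zeros((n, n), dtype=bool)
        for _, row in self.out_reports.iterrows():
            ego, alter = str(row["ego"]), str(row["alter"])
            if alter == UNMATCHED or ego not in index or alter not in index:
                continue
            if ego == alter:
                continue
            r_out[index[ego], index[alter]] = True
        for _, row in self.in_reports.iterrows():
            ego, alter = str(row["ego"]), str(row["alter"])
            if alter == UNMATCHED or ego not in index or alter not in index:
                continue
            if ego == alter:
                continue
            # ego says: alter would come to me  =>  tie alter -> ego
            r_in[index[alter], index[ego]] = True
        is_rep = np.array([r in self.reporter_set for r in roster])
        e_out = np.repeat(is_rep[:, None], n, axis=1)  # i reports i->j
        e_in = np.repeat(is_rep[None, :], n, axis=0)  # j reports i->j
        np.fill_diagonal(e_out, False)
        np.fill_diagonal(e_in, False)
        return r_out, r_in, e_out, e_in


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required column(s): {missing}")


def read_tables(respondent_path, nomination_path):
    """Read the respondent and nomination CSV tables.

    UNMATCHED alters are retained but flagged (``alter == 'UNMATCHED'``).
    Malformed rows (non-numeric age, age < 15, out-of-range deciles) are
    dropped and reported with their 1-based data line numbers.

    Raises
    ------
    ValueError
        If a required column is missing, or a respondent id is duplicated.
    """
    resp = pd.read_csv(respondent_path, dtype={"id": str})
    noms = pd.read_csv(nomination_path, dtype={"ego": str, "alter": str})
    _check_columns(resp, RESPONDENT_COLUMNS, "respondent")
    _check_columns(noms, NOMINATION_COLUMNS, "nomination")

    dup = resp["id"][resp["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate respondent id: {dup.iloc[0]!r}")

    bad_lines = []
    age = pd.to_numeric(resp["age"], errors="coerce")
    ok = age.notna() & (age >= 15)
    for col in ("empirical_expectation_men", "empirical_expectation_women"):
        dec = pd.to_numeric(resp[col], errors="coerce")
        ok &= dec.isna() | (dec.isin(range(0, 101, 10)))
    if not ok.all():
        bad_lines = [int(i) + 2 for i in resp.index[~ok]]  # +2: header + 1-based
        logger.warning(
            "dropping %d malformed respondent row(s) at line(s) %s",
            len(bad_lines), bad_lines[:20],
        )
        resp = resp[ok].reset_index(drop=True)
    resp = resp.assign(
        age=pd.to_numeric(resp["age"]).astype(int),
        zone=pd.to_numeric(resp["zone"]).astype(int),
        is_reporter=resp["is_reporter"].astype(bool),
    )

    bad_gen = ~noms["generator"].isin(GENERATORS)
    if bad_gen.any():
        lines = [int(i) + 2 for i in noms.index[bad_gen]]
        logger.warning(
            "dropping %d nomination row(s) with unknown generator at line(s) %s",
            bad_gen.sum(), lines[:20],
        )
        noms = noms[~bad_gen].reset_index(drop=True)
    noms = noms.assign(kin=noms["kin"].astype(bool))

    n_unmatched = int((noms["alter"] == UNMATCHED).sum())
    if n_unmatched:
        logger.info("%d nominations have UNMATCHED alters", n_unmatched)
    return resp, noms


def write_tables(respondents: pd.DataFrame, nominations: pd.DataFrame,
                 respondent_path, nomination_path):
    """Write the two tables as UTF-8 CSV with header rows (round-trips
    through :func:`read_tables`)."""
    respondents.to_csv(respondent_path, index=False)
    nominations.to_csv(nomination_path, index=False)


# ---------------------------------------------------------------------------
# preference outcome
# ---------------------------------------------------------------------------

def classify_preference(pref_daughter: str, pref_daughter_in_law: str) -> str:
    """Classify a respondent as ``'pro'`` or ``'anti'`` the practice.

    A respondent is pro iff they answered yes to wanting the practice for
    either a hypothetical daughter or a daughter-in-law; anti iff they
    answered no to both.

    Raises
    ------
    ValueError
        If either answer is missing or not yes/no.
    """
    answers = []
    for a in (pref_daughter, pref_daughter_in_law):
        if a is None or (isinstance(a, float) and np.isnan(a)):
            raise ValueError("missing preference answer")
        a = str(a).strip().lower()
        if a not in ("yes", "no"):
            raise ValueError(f"preference answer must be yes/no, got {a!r}")
        answers.append(a)
    return "pro" if "yes" in answers else "anti"


def preference_vector(respondents: pd.DataFrame, roster=None) -> np.ndarray:
    """Binary outcome vector Y (1 = pro) aligned to ``roster`` order.

    Respondents with a missing answer are excluded: their entry is set to
    0 and the exclusion is logged (models should be run on complete rows).
    """
    df = respondents.set_index(respondents["id"].astype(str))
    if roster is None:
        roster = list(df.index)
    y = np.zeros(len(roster), dtype=np.int8)
    n_excluded = 0
    for k, rid in enumerate(roster):
        row = df.loc[str(rid)]
        try:
            y[k] = 1 if classify_preference(
                row["pref_daughter"], row["pref_daughter_in_law"]) == "pro" else 0
        except ValueError:
            n_excluded += 1
    if n_excluded:
        logger.warning("%d respondent(s) excluded for missing preference answers",
                       n_excluded)
    return y


# ---------------------------------------------------------------------------
# layer construction
# ---------------------------------------------------------------------------

def build_layer(nominations: pd.DataFrame, generator: str, roster) -> DirectedNetwork:
    """Build one layer's directed network from matched nominations.

    For out-direction generators a nomination ego->alter yields the tie
    ego -> alter.  For the in-direction side of a double-sampled pair
    ("who would come to you") the reported relation is reversed, so the
    tie always points from the giver of the relationship: a report by A
    that "B would come to A" yields the tie B -> A.

    UNMATCHED and off-roster alters are dropped (count logged); duplicate
    nominations collapse to a single tie.  A tie is flagged kin if any
    nomination producing it was kin-labelled.
    """
    if generator not in GENERATORS:
        raise ValueError(f"unknown generator {generator!r}")
    sub = nominations[nominations["generator"] == generator]
    net = DirectedNetwork(roster, layer=generator)
    dropped = 0
    for _, row in sub.iterrows():
        ego, alter = str(row["ego"]), str(row["alter"])
        if alter == UNMATCHED or alter not in net._index or ego not in net._index:
            dropped += 1
            continue
        if ego == alter:
            dropped += 1
            continue
        if generator in IN_DIRECTION:
            a, b = net.index_of(alter), net.index_of(ego)
        else:
            a, b = net.index_of(ego), net.index_of(alter)
        net.adjacency[a, b] = True
        if bool(row.get("kin", False)):
            net.kin[a, b] = True
    if dropped:
        logger.info("build_layer(%s): dropped %d unmatched/off-roster nominations",
                    generator, dropped)
    return net


def split_kin(network: DirectedNetwork):
    """Partition a network's ties into a kin layer and a non-kin layer.

    Returns ``(kin_network, nonkin_network)`` on the same roster; the two
    tie sets are disjoint and their union is the input tie set.
    """
    kin_net = DirectedNetwork(network.roster, adjacency=network.kin,
                              kin=network.kin, layer=network.layer + "_kin")
    nonkin_adj = network.adjacency & ~network.kin
    nonkin_net = DirectedNetwork(network.roster, adjacency=nonkin_adj,
                                 layer=network.layer + "_nonkin")
    return kin_net, nonkin_net
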