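"""Synthetic populations, multi-layer networks, capped noisy name-generator
reports, and preference vectors under known regimes.

The generator emulates the study design the package targets: ~9
administrative zones of unequal size, roughly half of respondents sampled
as network reporters, up to 10 nominations per name generator, six name
generators (chatting and respect single-sampled; money-borrowing and
marriage-advice double-sampled), kin-labelled ties that cluster strongly
within zone, a low-prevalence binary preference (~1-12% per zone, driven
by zone-specific intercepts rather than demographics), and Bernoulli
reporting error (missed true ties with rate 1 - lambda1, spurious
nominations with rate lambda0, false positives confined to the
reporter's own zone).

Three regimes give known ground truth for downstream models:

* ``influence``: the preference vector is a draw from the ALAAM joint
  distribution on a fixed network, with a chosen contagion coefficient;
* ``selection``: preferences are independent, and the advice layer is
  drawn from the dyadic block + social-relations generative model with a
  chosen preference-combination offset matrix;
* ``null``: contagion coefficient zero / flat blocks — the two are
  distributionally indistinguishable null cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_data import DirectedNetwork, DoubleSampledReports

logger = logging.getLogger(__name__)

#: Default per-zone pro-preference shares, spanning the observed 1-12% range.
DEFAULT_ZONE_PREVALENCE = (0.121, 0.09, 0.07, 0.055, 0.04, 0.03, 0.023, 0.018, 0.014)

#: Normative-expectation answer probabilities conditional on own preference
#: (approve, disapprove, none_of_their_business), mirroring the observed split.
NORMATIVE_PROBS = {
    1: (0.031, 0.778, 0.191),
    0: (0.004, 0.905, 0.091),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults encode the conditions the generator emulates; sizes are
    scaled down from the field study so simulation-heavy checks stay
    cheap, without changing rates or proportions.
    """

    zone_sizes: tuple = (120, 110, 100, 90, 80, 70, 60, 50, 40)
    age_range: tuple = (15, 80)
    gender_ratio: float = 1.0  # men per woman
    education_probs: tuple = (0.24, 0.46, 0.12, 0.18)  # none..some_secondary_plus
    religion_probs: tuple = (("muslim", 0.94), ("orthodox", 0.058), ("other", 0.002))
    community_role_prob: float = 0.037
    mean_degree: float = 4.0  # expected latent out-degree per layer
    within_zone_mixing: float = 0.95
    kin_fraction: float = 0.45
    reciprocity: float = 0.45  # share of ties whose reverse tie exists
    reporter_fraction: float = 0.5
    nomination_cap: int = 10
    lambda1: float = 0.8  # reporting sensitivity
    lambda0: float = 0.002  # per-pair false-positive rate (within zone)
    regime: str = "null"  # {"null", "influence", "selection"}
    theta_contagion: float = 0.5  # influence regime
    block_matrix: tuple = ((1.5, 0.0), (0.0, 0.0))  # [focal pref][target pref] log-odds
    base_prevalence: float = 0.06
    zone_prevalence: tuple = DEFAULT_ZONE_PREVALENCE
    sr_sd: float = 0.4  # sender/receiver random-effect SD (selection regime)
    dyad_sd: float = 0.3  # dyadic random-effect SD
    dyad_reciprocity: float = 0.5  # correlation of (d_ij, d_ji)

    def __post_init__(self):
        if any(z < 2 for z in self.zone_sizes):
            raise ValueError("every zone size must be >= 2")
        if self.nomination_cap < 1:
            raise ValueError("nomination_cap must be >= 1")
        for p in (self.reporter_fraction, self.lambda1, self.lambda0,
                  self.within_zone_mixing, self.kin_fraction, self.reciprocity):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability parameter out of [0, 1]: {p}")

    @property
    def n(self) -> int:
        return int(sum(self.zone_sizes))

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Draw a respondent table with covariates and reporter flags.

    Reporter flags go to ``floor(reporter_fraction * n)`` respondents
    chosen uniformly at random.  Preference and norm-expectation columns
    are placeholders until :func:`generate_dataset` fills them.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    zones = np.repeat(np.arange(1, len(config.zone_sizes) + 1), config.zone_sizes)
    p_man = config.gender_ratio / (1.0 + config.gender_ratio)
    gender = np.where(rng.random(n) < p_man, "man", "woman")
    lo, hi = config.age_range
    # right-skewed ages: median near 30, bounded to the stated range
    age = np.clip(lo + rng.gamma(2.2, 8.5, size=n).astype(int), lo, hi)
    edu_levels = ("none", "some_primary", "completed_primary", "some_secondary_plus")
    education = rng.choice(edu_levels, size=n, p=np.asarray(config.education_probs))
    rel_names = [r for r, _ in config.religion_probs]
    rel_p = np.asarray([p for _, p in config.religion_probs])
    religion = rng.choice(rel_names, size=n, p=rel_p / rel_p.sum())
    role = np.where(rng.random(n) < config.community_role_prob, "role", "no_role")
    reporters = np.zeros(n, dtype=bool)
    reporters[rng.choice(n, size=int(config.reporter_fraction * n), replace=False)] = True
    ids = [f"r{k:05d}" for k in range(n)]
    return pd.DataFrame({
        "id": ids,
        "age": age,
        "gender": gender,
        "education": education,
        "zone": zones,
        "community_role": role,
        "religion": religion,
        "pref_daughter": "no",
        "pref_daughter_in_law": "no",
        "is_reporter": reporters,
        "empirical_expectation_men": 0,
        "empirical_expectation_women": 0,
        "normative_expectation": "disapprove",
    })


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _dyad_tie_draw(p, r, shape, rng):
    """Sample dyad states with ordered-pair tie probability ``p`` and
    reciprocated-tie share ``r``.  Returns (tie_ab, tie_ba) boolean arrays.

    P(mutual) = p*r, P(a->b only) = P(b->a only) = p*(1-r), so the
    marginal tie rate is p and the share of ties reciprocated is r.
    """
    p_mut = p * r
    p_asym = p * (1.0 - r)
    u = rng.random(shape)
    mut = u < p_mut
    ab_only = (u >= p_mut) & (u < p_mut + p_asym)
    ba_only = (u >= p_mut + p_asym) & (u < p_mut + 2 * p_asym)
    return mut | ab_only, mut | ba_only


def generate_networks(population: pd.DataFrame, config: SimConfig, seed: int = 0,
                      layers=("chatting", "respect", "money", "advice")):
    """Draw the true directed network per layer.

    Ties cluster within zone (``within_zone_mixing`` of each node's
    expected degree stays inside its zone); a ``kin_fraction`` of dyads
    is kin-flagged symmetrically; reciprocated-tie share follows
    ``config.reciprocity``.
    """
    rng = np.random.default_rng(seed)
    roster = list(population["id"].astype(str))
    zones = population["zone"].to_numpy()
    n = len(roster)
    if config.mean_degree > config.nomination_cap:
        warnings.warn("requested density implies out-degrees above the "
                      "nomination cap; reports will truncate", UserWarning,
                      stacklevel=2)
    nets = {}
    iu, ju = np.triu_indices(n, 1)
    same_zone = zones[iu] == zones[ju]
    zone_size = pd.Series(zones).value_counts().to_dict()
    # per-pair probabilities giving each node ~mean_degree expected ties,
    # a within_zone_mixing share of them inside its own zone
    sz = np.array([zone_size[z] for z in zones])
    p_within_node = config.within_zone_mixing * config.mean_degree / np.maximum(sz - 1, 1)
    p_between_node = ((1 - config.within_zone_mixing) * config.mean_degree
                      / np.maximum(n - sz, 1))
    p_within = np.minimum(np.sqrt(p_within_node[iu] * p_within_node[ju]), 1.0)
    p_between = np.minimum(np.sqrt(p_between_node[iu] * p_between_node[ju]), 1.0)
    p_pair = np.where(same_zone, p_within, p_between)
    for li, layer in enumerate(layers):
        tie_ab, tie_ba = _dyad_tie_draw(p_pair, config.reciprocity,
                                        len(iu), rng)
        adj = np.zeros((n, n), dtype=bool)
        adj[iu[tie_ab], ju[tie_ab]] = True
        adj[ju[tie_ba], iu[tie_ba]] = True
        kin_dyad = rng.random(len(iu)) < config.kin_fraction
        kin = np.zeros((n, n), dtype=bool)
        kin[iu[kin_dyad], ju[kin_dyad]] = True
        kin[ju[kin_dyad], iu[kin_dyad]] = True
        nets[layer] = DirectedNetwork(roster, adjacency=adj, kin=kin & adj,
                                      layer=layer)
        within_share = _within_zone_share(nets[layer], zones)
        logger.info("layer %s: %d ties, %.3f within zone", layer,
                    nets[layer].tie_count, within_share)
    return nets


def _within_zone_share(network: DirectedNetwork, zones) -> float:
    ii, jj = np.nonzero(network.adjacency)
    if len(ii) == 0:
        return float("nan")
    return float(np.mean(zones[ii] == zones[jj]))


# ---------------------------------------------------------------------------
# attributes
# ---------------------------------------------------------------------------

def zone_intercepts(population: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-respondent logit intercepts reproducing the configured
    per-zone prevalence (recycled if there are more zones than values)."""
    zp = list(config.zone_prevalence)
    zones = population["zone"].to_numpy()
    uniq = sorted(set(zones))
    lookup = {z: zp[k % len(zp)] for k, z in enumerate(uniq)}
    return logit(np.array([lookup[z] for z in zones]))


def influence_attributes(population: pd.DataFrame, network: DirectedNetwork,
                         config: SimConfig, seed: int = 0,
                         theta_contagion=None) -> np.ndarray:
    """Draw the preference vector for the influence (or null) regime.

    Zone-specific intercepts are set so the configured per-zone
    prevalences remain mean-field fixed points under the contagion
    strength: each intercept is lowered by theta times the expected
    number of positive neighbours (theta * mean symmetrized degree *
    target prevalence), which exactly cancels the average contagion
    boost at the target prevalence.  With theta = 0 this reduces to
    plain logit-prevalence intercepts.
    """
    theta_c = (config.theta_contagion if theta_contagion is None
               else float(theta_contagion))
    offs = zone_intercepts(population, config)
    if theta_c:
        d_plus = float(network.symmetrized().sum(axis=1).mean())
        offs = offs - theta_c * d_plus * expit(offs)
    return simulate_influence_attribute(
        network, offs[:, None], {"contagion_direct": theta_c, "cov0": 1.0},
        burn_in=300, seed=seed)


def simulate_influence_attribute(network: DirectedNetwork, covariates, theta,
                                 burn_in: int = 200, seed: int = 0) -> np.ndarray:
    """One draw of the preference vector from the ALAAM joint distribution
    after ``burn_in`` full Gibbs sweeps.

    ``theta`` maps statistic names to coefficients (an ``offsets`` entry,
    a per-node array, may be supplied via covariates instead).
    """
    from .alaam import StatisticConfig, gibbs_sample

    contagion = tuple(v.replace("contagion_", "") for v in theta
                      if str(v).startswith("contagion_")) or ("direct",)
    cfg = StatisticConfig(contagion=tuple(sorted(set(contagion) | {"direct"},
                                                 key=str)))
    return gibbs_sample(theta, network, covariates, cfg, sweeps=1,
                        burn_in=burn_in, seed=seed)[0]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def simulate_reports(true_network: DirectedNetwork, reporters, lambda1: float,
                     lambda0: float, cap=10, seed: int = 0,
                     generator_pair=("advice_out", "advice_in"),
                     zones=None) -> DoubleSampledReports:
    """Emit double-sampled reports of a true network.

    Each reporter reports each of their true out-ties (out side) / in-ties
    (in side) with probability ``lambda1`` and each non-tie with
    probability ``lambda0``; false positives are confined to the
    reporter's zone when ``zones`` is given (cross-zone ties are rare in
    the emulated design).  If more than ``cap`` nominations survive for
    one (reporter, generator), a uniform random subset of size ``cap`` is
    kept.  Non-reporters emit nothing.
    """
    if not (0.0 <= lambda1 <= 1.0 and 0.0 <= lambda0 <= 1.0):
        raise ValueError("lambda1 and lambda0 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    roster = true_network.roster
    n = true_network.n
    reporters = {str(r) for r in reporters}
    rep_mask = np.array([r in reporters for r in roster])
    adj = true_network.adjacency
    kin = true_network.kin
    zones = None if zones is None else np.asarray(zones)
    out_rows, in_rows = [], []
    gen_out, gen_in = generator_pair
    cap = np.inf if cap is None else int(cap)
    for i in range(n):
        if not rep_mask[i]:
            continue
        eligible_fp = np.ones(n, dtype=bool)
        eligible_fp[i] = False
        if zones is not None:
            eligible_fp &= zones == zones[i]
        # out side: reports about ties i -> j
        true_j = np.nonzero(adj[i])[0]
        hit = true_j[rng.random(len(true_j)) < lambda1]
        fp_pool = np.nonzero(eligible_fp & ~adj[i])[0]
        fps = fp_pool[rng.random(len(fp_pool)) < lambda0]
        named = np.concatenate([hit, fps])
        if len(named) > cap:
            named = rng.choice(named, size=int(cap), replace=False)
        for j in named:
            out_rows.append((roster[i], gen_out, roster[j],
                             bool(kin[i, j] or kin[j, i]), "unspecified"))
        # in side: reports about ties j -> i ("who would come to me")
        true_j = np.nonzero(adj[:, i])[0]
        hit = true_j[rng.random(len(true_j)) < lambda1]
        fp_pool = np.nonzero(eligible_fp & ~adj[:, i])[0]
        fps = fp_pool[rng.random(len(fp_pool)) < lambda0]
        named = np.concatenate([hit, fps])
        if len(named) > cap:
            named = rng.choice(named, size=int(cap), replace=False)
        for j in named:
            in_rows.append((roster[i], gen_in, roster[j],
                            bool(kin[j, i] or kin[i, j]), "unspecified"))
    cols = ["ego", "generator", "alter", "kin", "relationship"]
    return DoubleSampledReports(
        out_reports=pd.DataFrame(out_rows, columns=cols),
        in_reports=pd.DataFrame(in_rows, columns=cols),
        reporter_set=reporters,
    )


def simulate_selection_reports(attributes, covariates, block_matrix,
                               config: SimConfig, seed: int = 0,
                               zones=None):
    """Draw a latent advice layer from the dyadic selection model, then
    emit double-sampled reports of it.

    logit P(tie i->j) = intercept + B[y_i, y_j] + s_i + r_j + d_ij with
    bivariate-normal sender/receiver effects, reciprocity-correlated dyad
    effects, and the block offset matrix indexed by the two preferences.
    Returns ``(reports, truth_network)``.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(attributes, dtype=int)
    n = len(y)
    roster = [f"r{k:05d}" for k in range(n)]
    B = np.asarray(block_matrix, dtype=float)
    intercept = float(logit(min(max(config.mean_degree / max(n - 1, 1), 1e-6), 0.5)))
    s = rng.normal(0.0, config.sr_sd, size=n)
    r = rng.normal(0.0, config.sr_sd, size=n)
    iu, ju = np.triu_indices(n, 1)
    cov = config.dyad_reciprocity * config.dyad_sd ** 2
    L = np.linalg.cholesky([[config.dyad_sd ** 2, cov], [cov, config.dyad_sd ** 2]]) \
        if config.dyad_sd > 0 else np.zeros((2, 2))
    d_pair = rng.standard_normal((len(iu), 2)) @ L.T
    logit_ab = intercept + B[y[iu], y[ju]] + s[iu] + r[ju] + d_pair[:, 0]
    logit_ba = intercept + B[y[ju], y[iu]] + s[ju] + r[iu] + d_pair[:, 1]
    tie_ab = rng.random(len(iu)) < expit(logit_ab)
    tie_ba = rng.random(len(iu)) < expit(logit_ba)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[tie_ab], ju[tie_ab]] = True
    adj[ju[tie_ba], iu[tie_ba]] = True
    truth = DirectedNetwork(roster, adjacency=adj, layer="advice")
    reports = simulate_reports(truth, set(roster), config.lambda1, config.lambda0,
                               cap=config.nomination_cap,
                               seed=int(rng.integers(2 ** 31)), zones=zones)
    return reports, truth


# ---------------------------------------------------------------------------
# norm-expectation answers
# ---------------------------------------------------------------------------

def simulate_norm_answers(attributes, zone_prevalence, config: SimConfig,
                          seed: int = 0, zones=None,
                          p_zero_anti: float = 0.82, p_zero_pro: float = 0.35):
    """Draw empirical-expectation deciles and normative-expectation answers.

    Anti respondents mostly report 0%; pro respondents mostly report the
    decile nearest their zone's true prevalence (emulating the observed
    pattern that pro respondents better track zone-level views).  The
    normative answer is categorical conditional on own preference.

    Returns a DataFrame with columns ``empirical_expectation_men``,
    ``empirical_expectation_women`` and ``normative_expectation``.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(attributes, dtype=int)
    n = len(y)
    if zones is None:
        zones = np.ones(n, dtype=int)
    zones = np.asarray(zones)
    zp = dict(zone_prevalence) if not np.isscalar(zone_prevalence) else None
    out = {}
    for col in ("empirical_expectation_men", "empirical_expectation_women"):
        dec = np.zeros(n, dtype=int)
        for k in range(n):
            prev = (zone_prevalence if zp is None else zp[zones[k]])
            nearest = int(round(prev * 10)) * 10
            p_zero = p_zero_anti if y[k] == 0 else p_zero_pro
            if rng.random() < p_zero:
                dec[k] = 0
            else:
                jitter = rng.choice([-10, 0, 0, 10])
                dec[k] = int(np.clip(max(nearest, 10) + jitter, 0, 100))
        out[col] = dec
    cats = ("approve", "disapprove", "none_of_their_business")
    norm = [rng.choice(cats, p=NORMATIVE_PROBS[int(v)]) for v in y]
    out["normative_expectation"] = norm
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig, seed: int = 0) -> dict:
    """Generate a full synthetic survey: population, true networks,
    nomination table (all six generators, capped and noisy), and ground
    truth.  Fully deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2 ** 31, size=8)
    population = generate_population(config, int(seeds[0]))
    networks = generate_networks(population, config, int(seeds[1]))
    zones = population["zone"].to_numpy()
    roster = list(population["id"].astype(str))

    base_net = networks["chatting"]
    theta_c = config.theta_contagion if config.regime == "influence" else 0.0
    y = influence_attributes(population, base_net, config, seed=int(seeds[2]),
                             theta_contagion=theta_c)

    if config.regime == "selection":
        y = (rng.random(len(roster))
             < np.array([config.base_prevalence] * len(roster))).astype(np.int8)
        _, truth = simulate_selection_reports(
            y, None, config.block_matrix, config, seed=int(seeds[3]), zones=zones)
        networks["advice"] = truth  # same id scheme as the population roster

    population = population.assign(
        pref_daughter=np.where(y == 1, "yes", "no"),
        pref_daughter_in_law="no",
    )
    zone_prev = {int(z): float(y[zones == z].mean()) for z in sorted(set(zones))}
    norms = simulate_norm_answers(y, zone_prev, config, seed=int(seeds[4]),
                                  zones=zones)
    for c in norms.columns:
        population[c] = norms[c].to_numpy()

    reporters = set(population.loc[population["is_reporter"], "id"].astype(str))
    nominations = []
    pair_names = {"money": ("borrow_out", "borrow_in"),
                  "advice": ("advice_out", "advice_in")}
    reports_by_layer = {}
    for k, (layer, net) in enumerate(networks.items()):
        if layer in pair_names:
            rep = simulate_reports(net, reporters, config.lambda1, config.lambda0,
                                   cap=config.nomination_cap,
                                   seed=int(seeds[5]) + k,
                                   generator_pair=pair_names[layer], zones=zones)
            reports_by_layer[layer] = rep
            nominations.append(rep.out_reports)
            nominations.append(rep.in_reports)
        else:
            rep = simulate_reports(net, reporters, config.lambda1, config.lambda0,
                                   cap=config.nomination_cap,
                                   seed=int(seeds[5]) + k,
                                   generator_pair=(layer, layer + "_in"),
                                   zones=zones)
            nominations.append(rep.out_reports)
    nominations = pd.concat(nominations, ignore_index=True)
    return {
        "population": population,
        "networks": networks,
        "reports": reports_by_layer,
        "nominations": nominations,
        "truth": {
            "y": y,
            "theta_contagion": theta_c,
            "zone_prevalence": zone_prev,
            "regime": config.regime,
        },
    }
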