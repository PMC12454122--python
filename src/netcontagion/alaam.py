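"""Autologistic actor-attribute models (ALAAM) for binary node attributes.

The ALAAM is an exponential-family model for a binary attribute vector y
conditional on a fixed, exogenous network:

    P(y | theta) = exp(theta . s(y)) / Z(theta)

where s(y) collects the sufficient statistics: an intercept (sum of y),
activity (sum of y_i * outdeg_i), popularity (sum of y_i * indeg_i),
covariate main effects (sum of y_i * c_i), and contagion terms counting
attribute-concordant structures on the network.  Two tied actors'
attributes are conditionally dependent; untied actors' are independent
given the rest.  All contagion statistics are computed on the
symmetrized adjacency x+_ij = max(x_ij, x_ji), i.e. over unordered pairs:

    direct           sum_{i<j} y_i y_j x+_ij
    reciprocal       sum_{i<j} y_i y_j x_ij x_ji
    indirect         sum_{i<j} y_i y_j [x+_ij = 0][exists k: x+_ik = x+_kj = 1]
    closed_indirect  sum_{i<j} y_i y_j [x+_ij = 1][exists k: x+_ik = x+_kj = 1]
    transitive       number of unordered triads with all three members
                     attribute-positive and all three x+ ties present

Z(theta) is intractable beyond ~15 nodes, so posteriors over theta are
sampled with the exchange algorithm: each Metropolis step draws an
auxiliary attribute vector from the model at the proposed theta (by Gibbs
sampling) so that the unknown normalizing constants cancel from the
acceptance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

from .core_data import DirectedNetwork

CONTAGION_VARIANTS = ("direct", "reciprocal", "indirect", "closed_indirect", "transitive")


@dataclass(frozen=True)
class StatisticConfig:
    """Which contagion statistics a model includes, and on which ties.

    ``direct`` must be enabled whenever any other contagion variant is
    (statistical hierarchy: the higher-order counts nest the direct one).
    """

    contagion: tuple = ("direct",)
    tie_scope: str = "all"  # {"all", "kin", "nonkin"} — informational label
    include_degrees: bool = True  # activity/popularity lower-order terms

    def __post_init__(self):
        bad = set(self.contagion) - set(CONTAGION_VARIANTS)
        if bad:
            raise ValueError(f"unknown contagion variant(s): {sorted(bad)}")
        if self.contagion and "direct" not in self.contagion:
            raise ValueError("'direct' contagion must be enabled when any "
                             "other contagion variant is (hierarchy)")
        object.__setattr__(self, "contagion", tuple(self.contagion))


def _as_cov_matrix(covariates, n):
    """Normalize covariates to (matrix, names)."""
    if covariates is None:
        return np.zeros((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return c, [f"cov{k}" for k in range(c.shape[1])]


def pair_matrices(network: DirectedNetwork, config: StatisticConfig):
    """Symmetric 0/1 pair matrices M_v with M_v[i,j] = 1 iff the unordered
    pair {i, j} is counted by contagion variant v when both are positive."""
    x = network.adjacency
    xp = x | x.T
    need_two_path = any(v in config.contagion for v in ("indirect", "closed_indirect"))
    if need_two_path:
        xi = xp.astype(np.int32)
        two_path = ((xi @ xi) > 0) & ~np.eye(network.n, dtype=bool)
    out = {}
    for v in config.contagion:
        if v == "direct":
            m = xp
        elif v == "reciprocal":
            m = x & x.T
        elif v == "indirect":
            m = two_path & ~xp
        elif v == "closed_indirect":
            m = two_path & xp
        else:  # transitive is triadic, handled via the triangle list
            continue
        out[v] = m.astype(np.float64)
        np.fill_diagonal(out[v], 0.0)
    return out


class _Workspace:
    """Caches everything expensive that depends only on (network,
    covariates, config): pair matrices, triangle list, degrees, names."""

    def __init__(self, network: DirectedNetwork, covariates, config: StatisticConfig):
        self.network = network
        self.config = config
        self.n = network.n
        self.C, self.cov_names = _as_cov_matrix(covariates, network.n)
        if self.C.shape[0] != network.n:
            raise ValueError("covariate rows do not match roster size")
        self.outdeg = network.out_degree().astype(float)
        self.indeg = network.in_degree().astype(float)
        # per-node main-effect columns beyond the intercept
        self.node_terms = []
        if config.include_degrees:
            self.node_terms += [("activity", self.outdeg),
                                ("popularity", self.indeg)]
        self.node_terms += list(zip(self.cov_names, self.C.T))
        self.names = (["intercept"] + [t[0] for t in self.node_terms]
                      + [f"contagion_{v}" for v in config.contagion])
        self.mats = pair_matrices(network, config)
        self.pairwise = [v for v in config.contagion if v != "transitive"]
        self.M = (np.stack([self.mats[v] for v in self.pairwise])
                  if self.pairwise else np.zeros((0, self.n, self.n)))
        self.has_transitive = "transitive" in config.contagion
        self.asym = network.symmetrized().astype(np.uint8)
        if self.has_transitive:
            xp = self.asym.astype(bool)
            n = self.n
            self.triangles = np.array(
                [(i, j, k) for i in range(n) for j in range(i + 1, n)
                 for k in range(j + 1, n) if xp[i, j] and xp[j, k] and xp[i, k]],
                dtype=int).reshape(-1, 3)

    def theta_vector(self, theta):
        return _theta_vector(theta, self.names)

    def stats(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        vals = [y.sum()] + [y @ vec for _, vec in self.node_terms]
        for v in self.config.contagion:
            if v == "transitive":
                t = self.triangles
                vals.append(float((y[t[:, 0]] * y[t[:, 1]] * y[t[:, 2]]).sum())
                            if len(t) else 0.0)
            else:
                vals.append(0.5 * y @ self.mats[v] @ y)
        return np.asarray(vals, dtype=float)

    def stats_series(self, y) -> pd.Series:
        return pd.Series(self.stats(y), index=self.names)

    def split_theta(self, th):
        """(base vector, pairwise contagion coefs, transitive coef)."""
        base = th[0] * np.ones(self.n)
        for k, (_, vec) in enumerate(self.node_terms):
            base = base + th[1 + k] * vec
        k0 = 1 + len(self.node_terms)
        theta_m = np.empty(len(self.pairwise))
        theta_t = 0.0
        for idx, v in enumerate(self.config.contagion):
            coef = th[k0 + idx]
            if v == "transitive":
                theta_t = coef
            else:
                theta_m[self.pairwise.index(v)] = coef
        return base.astype(float), theta_m, float(theta_t)

    def gibbs(self, th, sweeps, seed, burn_in=0, thin=1, init=None):
        base, theta_m, theta_t = self.split_theta(th)
        y = (np.zeros(self.n, dtype=np.int8) if init is None
             else np.asarray(init, dtype=np.int8).copy())
        seed = int(seed) % (2 ** 31)
        if burn_in:
            _gibbs_kernel(base, self.M, theta_m, theta_t, self.asym, y,
                          burn_in, 0, np.empty((0, self.n), dtype=np.int8), seed)
        n_rec = sweeps // thin
        out = np.empty((n_rec, self.n), dtype=np.int8)
        _gibbs_kernel(base, self.M, theta_m, theta_t, self.asym, y,
                      n_rec * thin, thin, out, (seed + 1) % (2 ** 31))
        return out


def statistic_names(network, covariates, config):
    _, cov_names = _as_cov_matrix(covariates, network.n)
    deg = ["activity", "popularity"] if config.include_degrees else []
    return (["intercept"] + deg + cov_names
            + [f"contagion_{v}" for v in config.contagion])


def compute_statistics(y, network: DirectedNetwork, covariates=None,
                       config: StatisticConfig = StatisticConfig()) -> pd.Series:
    """Evaluate the enabled sufficient statistics s(y).

    ``y`` is a binary vector aligned to the network roster; ``covariates``
    is an optional (n, p) matrix or DataFrame of main-effect columns.
    """
    y = np.asarray(y, dtype=np.int8)
    if y.shape != (network.n,):
        raise ValueError(f"y has shape {y.shape}, roster has {network.n} members")
    ws = _Workspace(network, covariates, config)
    return ws.stats_series(y)


def _theta_vector(theta, names):
    """Accept a dict/Series keyed by statistic name, or an aligned vector."""
    if isinstance(theta, (dict, pd.Series)):
        d = dict(theta)
        unknown = set(d) - set(names)
        if unknown:
            raise ValueError(f"theta has unknown statistic name(s): {sorted(unknown)}")
        th = np.array([float(d.get(name, 0.0)) for name in names])
    else:
        th = np.asarray(theta, dtype=float)
        if th.shape != (len(names),):
            raise ValueError(f"theta length {th.shape} != {len(names)} statistics")
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    return th


# ---------------------------------------------------------------------------
# exact enumeration (oracle-grade, n <= 15)
# ---------------------------------------------------------------------------

def exact_distribution(theta, network: DirectedNetwork, covariates=None,
                       config: StatisticConfig = StatisticConfig()):
    """Exact model distribution by enumerating all 2^n attribute vectors.

    Returns a dict with ``states`` ((2^n, n) binary matrix), ``probs``
    (normalized probabilities), ``stats`` ((2^n, k) statistic matrix) and
    ``moments`` (exact E[s] as a Series).  Guarded to n <= 15.
    """
    n = network.n
    if n > 15:
        raise ValueError(f"exact enumeration limited to n <= 15 (got {n})")
    ws = _Workspace(network, covariates, config)
    th = ws.theta_vector(theta)
    states = ((np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)
    Y = states.astype(float)
    cols = [Y.sum(axis=1)] + [Y @ vec for _, vec in ws.node_terms]
    for v in ws.config.contagion:
        if v == "transitive":
            t = ws.triangles
            cols.append((Y[:, t[:, 0]] * Y[:, t[:, 1]] * Y[:, t[:, 2]]).sum(axis=1)
                        if len(t) else np.zeros(2 ** n))
        else:
            cols.append(0.5 * np.einsum("bi,ij,bj->b", Y, ws.mats[v], Y))
    stats = np.column_stack(cols)
    energy = stats @ th
    energy -= energy.max()
    probs = np.exp(energy)
    probs /= probs.sum()
    moments = pd.Series(probs @ stats, index=ws.names)
    return {"states": states, "probs": probs, "stats": stats, "moments": moments,
            "names": ws.names}


# ---------------------------------------------------------------------------
# Gibbs simulation of y | theta
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_kernel(base, M, theta_m, theta_t, asym, y, sweeps, record_every, out, seed):
    """Systematic-scan Gibbs over the ALAAM full conditionals.

    base[i] is the theta-weighted change statistic of everything that does
    not involve other nodes' attributes (intercept, degrees, covariates);
    fields F[k, i] = sum_j M[k, i, j] y_j are maintained incrementally so
    a node update is O(1) unless the attribute flips.
    """
    np.random.seed(seed)
    n = base.shape[0]
    m = M.shape[0]
    F = np.zeros((m, n))
    for k in range(m):
        for j in range(n):
            if y[j] == 1:
                for i in range(n):
                    F[k, i] += M[k, i, j]
    rec = 0
    for sweep in range(sweeps):
        for i in range(n):
            logit = base[i]
            for k in range(m):
                logit += theta_m[k] * F[k, i]
            if theta_t != 0.0:
                cnt = 0
                for ja in range(n):
                    if y[ja] == 1 and ja != i and asym[i, ja] == 1:
                        for jb in range(ja + 1, n):
                            if (y[jb] == 1 and jb != i and asym[i, jb] == 1
                                    and asym[ja, jb] == 1):
                                cnt += 1
                logit += theta_t * cnt
            p = 1.0 / (1.0 + np.exp(-logit))
            new = 1 if np.random.random() < p else 0
            if new != y[i]:
                y[i] = new
                sgn = 1.0 if new == 1 else -1.0
                for k in range(m):
                    for j in range(n):
                        F[k, j] += sgn * M[k, i, j]
        if record_every > 0 and (sweep + 1) % record_every == 0:
            for j in range(n):
                out[rec, j] = y[j]
            rec += 1
    return y


def gibbs_sample(theta, network: DirectedNetwork, covariates=None,
                 config: StatisticConfig = StatisticConfig(), sweeps=1000,
                 seed=0, burn_in=0, thin=1, init=None):
    """Draw attribute vectors from the ALAAM by systematic-scan Gibbs.

    Runs ``burn_in`` discarded full sweeps, then ``sweeps`` further sweeps
    recording every ``thin``-th state.  Returns an (m, n) int8 array.
    """
    ws = _Workspace(network, covariates, config)
    return ws.gibbs(ws.theta_vector(theta), sweeps, seed, burn_in=burn_in,
                    thin=thin, init=init)


# ---------------------------------------------------------------------------
# exchange-algorithm posterior
# ---------------------------------------------------------------------------

class ALAAM(BaseEstimator):
    """Bayesian ALAAM fitted with the exchange algorithm.

    Parameters
    ----------
    config : StatisticConfig, optional
        Enabled contagion statistics (default: direct only).
    prior_sd : float
        SD of the independent Normal(0, prior_sd^2) priors on every
        coefficient (minimally informative default).
    iterations, burn_in : int
        Total exchange-MCMC steps and how many to discard.
    aux_sweeps : int
        Full Gibbs sweeps used to draw each auxiliary attribute vector at
        the proposed theta, initialized at the observed outcome.  The key
        approximation knob: the exchange ratio is exact only in the limit
        of a perfect auxiliary draw.
    proposal_scale : float
        Initial per-coordinate random-walk SD.
    adapt : bool
        Adapt the proposal scale toward ~25% acceptance during burn-in
        only (frozen afterwards, preserving detailed balance).
    random_state : int
        Seed for the whole fit.

    Attributes
    ----------
    draws_ : pandas.DataFrame
        Retained posterior draws (one column per coefficient).
    acceptance_rate_ : float
    summary_ : pandas.DataFrame
        Output of :func:`posterior_summary` on ``draws_``.
    param_names_ : list of str
    """

    def __init__(self, config=None, prior_sd=5.0, iterations=2000, burn_in=500,
                 aux_sweeps=50, proposal_scale=0.1, adapt=True, thin=1,
                 random_state=0):
        self.config = config
        self.prior_sd = prior_sd
        self.iterations = iterations
        self.burn_in = burn_in
        self.aux_sweeps = aux_sweeps
        self.proposal_scale = proposal_scale
        self.adapt = adapt
        self.thin = thin
        self.random_state = random_state

    def fit(self, y, network: DirectedNetwork, covariates=None):
        config = self.config or StatisticConfig()
        y = np.asarray(y, dtype=np.int8)
        if y.shape != (network.n,):
            raise ValueError("y does not match roster size")
        if y.min() == y.max():
            raise ValueError(f"outcome non-identified: y is constant (all {int(y[0])})")
        ws = _Workspace(network, covariates, config)
        for v, m in ws.mats.items():
            if not m.any():
                warnings.warn(
                    f"contagion statistic '{v}' is constant (no qualifying "
                    "pairs on this network); its coefficient is unidentified",
                    UserWarning, stacklevel=2)
        s_obs = ws.stats(y)
        k = len(ws.names)
        rng = np.random.default_rng(self.random_state)
        theta = np.zeros(k)
        p_obs = float(y.mean())
        theta[0] = np.log(p_obs / (1 - p_obs))  # start intercept at marginal logit
        scale = float(self.proposal_scale)

        def log_prior(th):
            return float(-0.5 * np.sum((th / self.prior_sd) ** 2))

        lp = log_prior(theta)
        draws = np.empty((self.iterations, k))
        accepted = 0
        acc_window = 0
        chol = np.eye(k)  # proposal shape; adapted from burn-in draws
        for it in range(self.iterations):
            prop = theta + scale * (chol @ rng.standard_normal(k))
            aux_seed = int(rng.integers(2 ** 31))
            y_aux = ws.gibbs(prop, sweeps=1, seed=aux_seed,
                             burn_in=self.aux_sweeps, init=y)[0]
            s_aux = ws.stats(y_aux)
            lp_prop = log_prior(prop)
            log_r = float((prop - theta) @ (s_obs - s_aux)) + lp_prop - lp
            if np.log(rng.random()) < log_r:
                theta, lp = prop, lp_prop
                accepted += 1
                acc_window += 1
            draws[it] = theta
            if self.adapt and it < self.burn_in and (it + 1) % 50 == 0:
                scale *= np.exp(0.5 * (acc_window / 50 - 0.25))
                acc_window = 0
                if it + 1 >= 200:  # shape from the burn-in sample covariance
                    cov = np.cov(draws[it // 2:it + 1].T) + 1e-6 * np.eye(k)
                    sd = np.sqrt(np.diag(cov).mean())
                    try:
                        chol = np.linalg.cholesky(cov) / max(sd, 1e-6)
                    except np.linalg.LinAlgError:
                        pass
        kept = draws[self.burn_in::self.thin]
        self.param_names_ = ws.names
        self.draws_ = pd.DataFrame(kept, columns=ws.names)
        self.acceptance_rate_ = accepted / self.iterations
        self.proposal_scale_ = scale
        self.summary_ = posterior_summary(self.draws_)
        self.config_ = config
        return self


def fit_alaam(y_obs, network, covariates=None, config=None, prior_sd=5.0,
              iterations=2000, burn_in=500, aux_sweeps=50, seed=0, **kwargs):
    """Functional wrapper around :class:`ALAAM`; returns the fitted model."""
    model = ALAAM(config=config, prior_sd=prior_sd, iterations=iterations,
                  burn_in=burn_in, aux_sweeps=aux_sweeps, random_state=seed,
                  **kwargs)
    return model.fit(y_obs, network, covariates)


def posterior_summary(draws) -> pd.DataFrame:
    """Median, central 95% interval and proportion of draws above zero,
    per parameter."""
    if isinstance(draws, ALAAM):
        draws = draws.draws_
    if not isinstance(draws, pd.DataFrame):
        draws = pd.DataFrame(np.asarray(draws))
    q = draws.quantile([0.5, 0.025, 0.975])
    return pd.DataFrame({
        "median": q.loc[0.5],
        "lower95": q.loc[0.025],
        "upper95": q.loc[0.975],
        "prop_above_zero": (draws > 0).mean(),
    })


def goodness_of_fit(draws, y_obs, network, covariates=None, config=None,
                    n_sim=100, seed=0, sim_sweeps=100) -> pd.DataFrame:
    """Posterior-predictive goodness of fit.

    For ``n_sim`` evenly spaced posterior draws, simulate an outcome
    vector by Gibbs sampling and compute *all* statistics (including
    contagion variants not in the fitted model).  Reports the simulated
    mean and SD of each statistic alongside the observed value and the
    t-ratio (obs - mean) / SD; a degenerate zero-variance statistic gets a
    NaN t-ratio rather than an error.
    """
    if isinstance(draws, ALAAM):
        draws = draws.draws_
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    config = config or StatisticConfig()
    full_config = StatisticConfig(contagion=CONTAGION_VARIANTS,
                                  tie_scope=config.tie_scope)
    ws_fit = _Workspace(network, covariates, config)
    ws_full = _Workspace(network, covariates, full_config)
    y_obs = np.asarray(y_obs, dtype=np.int8)
    obs = ws_full.stats_series(y_obs)
    idx = np.linspace(0, len(draws) - 1, n_sim).astype(int)
    rng = np.random.default_rng(seed)
    sims = []
    for i in idx:
        th = ws_fit.theta_vector(draws.iloc[int(i)][ws_fit.names])
        y_sim = ws_fit.gibbs(th, sweeps=1, burn_in=sim_sweeps,
                             seed=int(rng.integers(2 ** 31)), init=y_obs)[0]
        sims.append(ws_full.stats_series(y_sim))
    sim = pd.DataFrame(sims)
    mean, sd = sim.mean(), sim.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (obs - mean) / sd
    t[sd == 0] = np.nan
    return pd.DataFrame({"observed": obs, "sim_mean": mean, "sim_sd": sd,
                         "t_ratio": t})
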