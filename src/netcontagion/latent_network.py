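"""Latent-network estimation from double-sampled name-generator reports.

A double-sampled generator elicits the same directed relation from both
sides ("who would you go to" / "who would come to you"), so every ordered
pair (i, j) can carry up to two noisy reports of the latent tie
Y_ij in {0, 1}.  The generative model:

* dyad prior with a log-linear mutuality term,
  P(Y_ij, Y_ji) proportional to exp(alpha (Y_ij + Y_ji) + beta Y_ij Y_ji);
* each eligible reporter's statement about a pair is Bernoulli(lambda1)
  if the latent tie exists and Bernoulli(lambda0) otherwise (lambda1 =
  sensitivity, lambda0 = false-positive rate), with Beta priors on both.

Posterior tie probabilities rho_ij = P(Y_ij = 1 | reports) are computed
by Gibbs sampling over (Y, lambda1, lambda0, alpha, beta).  Pairs where
neither endpoint could report revert to the prior tie probability, and
pairs observable from one versus both sides are weighted automatically
through the likelihood.  The network is binarized at the mutuality-based
threshold

    t_rho = 0.33 * eta_est + 0.10

where eta_est = posterior mean of P(Y_ji = 1 | Y_ij = 1) = sigmoid(alpha
+ beta), a concrete mutuality summary guaranteed to lie in [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .core_data import DirectedNetwork, DoubleSampledReports

logger = logging.getLogger(__name__)

def _clip(p):
    # asymmetric guards so the noiseless limit keeps lambda1/lambda0 -> inf:
    # at lambda1 = 1, lambda0 = 0 a positive report stays decisive even on a
    # pair whose second eligible reporter stayed silent
    return float(min(max(p, 1e-18), 1.0 - 1e-9))


class LatentNetworkModel(BaseEstimator):
    """Bayesian latent-network model for double-sampled reports.

    Parameters
    ----------
    iterations, burn_in, thin : int
        Gibbs chain settings.
    scope : {"full", "reporters"}
        Fit over the full roster or only over the reporter subsample.
    lambda1, lambda0 : float or None
        Fix the reporting rates (e.g. for noiseless-limit checks); when
        None they are sampled with Beta priors.
    alpha, beta : float or None
        Fix the dyad-prior parameters; when None they get random-walk
        Metropolis updates with Normal priors.
    prior_lambda1, prior_lambda0 : (a, b)
        Beta prior hyperparameters for the reporting rates.
    prior_tie_probability : float
        Prior marginal tie probability; centres the Normal prior on alpha
        at its logit.
    prior_sd : float
        SD of the Normal priors on alpha and beta.

    Attributes
    ----------
    rho_ : (n, n) float array
        Posterior tie probabilities (diagonal 0).
    eta_est_ : float
        Mutuality estimate in [0, 1].
    t_rho_ : float
        Binarization threshold 0.33 * eta_est + 0.10.
    binarized_ : DirectedNetwork
        Ties where rho > t_rho.
    lambda1_mean_, lambda0_mean_ : float
        Posterior means of the reporting rates.
    draws_ : dict of arrays
        Retained draws of lambda1, lambda0, alpha, beta.
    roster_, reporter_set_ : fitted scope.
    """

    def __init__(self, iterations=1500, burn_in=500, thin=1, scope="full",
                 lambda1=None, lambda0=None, alpha=None, beta=None,
                 prior_lambda1=(9.0, 1.0), prior_lambda0=(1.0, 99.0),
                 prior_tie_probability=0.005, prior_sd=1.5, random_state=0):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.scope = scope
        self.lambda1 = lambda1
        self.lambda0 = lambda0
        self.alpha = alpha
        self.beta = beta
        self.prior_lambda1 = prior_lambda1
        self.prior_lambda0 = prior_lambda0
        self.prior_tie_probability = prior_tie_probability
        self.prior_sd = prior_sd
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _dyad_logprior(self, alpha, beta):
        """Log-weights of the four dyad states (00, 10, 01, 11)."""
        return np.array([0.0, alpha, alpha, 2 * alpha + beta])

    def fit(self, reports: DoubleSampledReports, roster):
        if len(reports.out_reports) + len(reports.in_reports) == 0:
            raise ValueError("empty report set")
        for side in (reports.out_reports, reports.in_reports):
            selfrep = side["ego"].astype(str) == side["alter"].astype(str)
            if selfrep.any():
                logger.warning("dropping %d self-report(s)", int(selfrep.sum()))
        roster = [str(r) for r in roster]
        if self.scope == "reporters":
            roster = [r for r in roster if r in reports.reporter_set]
        elif self.scope != "full":
            raise ValueError(f"unknown scope {self.scope!r}")
        n = len(roster)
        r_out, r_in, e_out, e_in = reports.to_matrices(roster)
        r_out &= e_out
        r_in &= e_in
        k_mat = r_out.astype(np.int8) + r_in.astype(np.int8)
        m_mat = e_out.astype(np.int8) + e_in.astype(np.int8)

        iu, ju = np.triu_indices(n, 1)
        k_a, m_a = k_mat[iu, ju].astype(float), m_mat[iu, ju].astype(float)
        k_b, m_b = k_mat[ju, iu].astype(float), m_mat[ju, iu].astype(float)
        n_dyads = len(iu)

        rng = np.random.default_rng(self.random_state)
        lam1 = _clip(self.lambda1 if self.lambda1 is not None
                     else self.prior_lambda1[0] / sum(self.prior_lambda1))
        lam0 = _clip(self.lambda0 if self.lambda0 is not None
                     else self.prior_lambda0[0] / sum(self.prior_lambda0))
        alpha0 = float(logit(self.prior_tie_probability))

        y_a = (k_a > 0).astype(np.float64)  # init at union of reports
        y_b = (k_b > 0).astype(np.float64)
        # moment-based starting values from the union network: density for
        # alpha, dyad-count log odds ratio for the mutuality beta
        n11 = float(y_a @ y_b)
        n10 = float(y_a.sum() + y_b.sum() - 2 * n11)
        n00 = float(n_dyads - n11 - n10)
        alpha = (self.alpha if self.alpha is not None else
                 float(np.clip(logit(max((y_a.mean() + y_b.mean()) / 2, 1e-4)),
                               -12.0, 0.0)))
        beta = (self.beta if self.beta is not None else
                float(np.clip(np.log(max(4 * n11 * n00, 0.25))
                              - 2 * np.log(max(n10, 0.5)), 0.0, 8.0)))

        rho_sum = np.zeros(n_dyads * 2)
        kept = 0
        draws = {"lambda1": [], "lambda0": [], "alpha": [], "beta": []}
        mh_scale = 0.15
        acc = 0

        def loglik_side(k, m, lam):
            return k * np.log(lam) + (m - k) * np.log1p(-lam)

        for it in range(self.iterations):
            # --- dyad states ------------------------------------------------
            l1_a = loglik_side(k_a, m_a, lam1)
            l0_a = loglik_side(k_a, m_a, lam0)
            l1_b = loglik_side(k_b, m_b, lam1)
            l0_b = loglik_side(k_b, m_b, lam0)
            pri = self._dyad_logprior(alpha, beta)
            logp = np.stack([
                pri[0] + l0_a + l0_b,
                pri[1] + l1_a + l0_b,
                pri[2] + l0_a + l1_b,
                pri[3] + l1_a + l1_b,
            ])
            gumbel = -np.log(-np.log(rng.random((4, n_dyads))))
            state = np.argmax(logp + gumbel, axis=0)
            y_a = ((state == 1) | (state == 3)).astype(np.float64)
            y_b = ((state == 2) | (state == 3)).astype(np.float64)

            # --- reporting rates (conjugate Beta) --------------------------
            if self.lambda1 is None:
                pos_k = float(k_a @ y_a + k_b @ y_b)
                pos_m = float(m_a @ y_a + m_b @ y_b)
                lam1 = _clip(rng.beta(self.prior_lambda1[0] + pos_k,
                                      self.prior_lambda1[1] + pos_m - pos_k))
            if self.lambda0 is None:
                neg_k = float(k_a @ (1 - y_a) + k_b @ (1 - y_b))
                neg_m = float(m_a @ (1 - y_a) + m_b @ (1 - y_b))
                lam0 = _clip(rng.beta(self.prior_lambda0[0] + neg_k,
                                      self.prior_lambda0[1] + neg_m - neg_k))

            # --- mutuality parameters (random-walk Metropolis) -------------
            if self.alpha is None or self.beta is None:
                s1 = float(y_a.sum() + y_b.sum())
                s2 = float(y_a @ y_b)

                def logpost(a, b):
                    z = np.logaddexp(np.logaddexp(0.0, np.log(2.0) + a),
                                     2 * a + b)
                    ll = a * s1 + b * s2 - n_dyads * z
                    lp = (-0.5 * ((a - alpha0) / self.prior_sd) ** 2
                          - 0.5 * (b / self.prior_sd) ** 2)
                    return ll + lp

                a_prop = (alpha + mh_scale * rng.standard_normal()
                          if self.alpha is None else alpha)
                b_prop = (beta + mh_scale * rng.standard_normal()
                          if self.beta is None else beta)
                if np.log(rng.random()) < logpost(a_prop, b_prop) - logpost(alpha, beta):
                    alpha, beta = a_prop, b_prop
                    acc += 1
                if it < self.burn_in and it % 50 == 49:
                    mh_scale *= np.exp(0.5 * (acc / 50 - 0.3))
                    acc = 0

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                rho_sum[:n_dyads] += y_a
                rho_sum[n_dyads:] += y_b
                draws["lambda1"].append(lam1)
                draws["lambda0"].append(lam0)
                draws["alpha"].append(alpha)
                draws["beta"].append(beta)
                kept += 1

        rho = np.zeros((n, n))
        rho[iu, ju] = rho_sum[:n_dyads] / kept
        rho[ju, iu] = rho_sum[n_dyads:] / kept
        self.draws_ = {k: np.asarray(v) for k, v in draws.items()}
        self.rho_ = rho
        self.eta_est_ = float(np.mean(expit(self.draws_["alpha"] + self.draws_["beta"])))
        self.t_rho_ = 0.33 * self.eta_est_ + 0.10
        self.lambda1_mean_ = float(np.mean(self.draws_["lambda1"]))
        self.lambda0_mean_ = float(np.mean(self.draws_["lambda0"]))
        self.roster_ = roster
        self.reporter_set_ = set(reports.reporter_set) & set(roster)
        self.binarized_ = DirectedNetwork(roster, adjacency=rho > self.t_rho_,
                                          layer="latent")
        return self


def fit_latent_network(reports: DoubleSampledReports, roster, seed=0,
                       **settings) -> LatentNetworkModel:
    """Fit :class:`LatentNetworkModel`; ``settings`` forwards to it."""
    return LatentNetworkModel(random_state=seed, **settings).fit(reports, roster)


def threshold_ties(estimate: LatentNetworkModel) -> DirectedNetwork:
    """Binarize a fitted estimate: tie iff rho_ij > t_rho, with t_rho
    recomputed from eta_est."""
    eta = estimate.eta_est_
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta_est must lie in [0, 1], got {eta}")
    t = 0.33 * eta + 0.10
    estimate.t_rho_ = t
    net = DirectedNetwork(estimate.roster_, adjacency=estimate.rho_ > t,
                          layer="latent")
    estimate.binarized_ = net
    return net


def baseline_union(reports: DoubleSampledReports, roster) -> DirectedNetwork:
    """Deterministic baseline: tie i -> j if either side reported it."""
    roster = [str(r) for r in roster]
    r_out, r_in, _, _ = reports.to_matrices(roster)
    return DirectedNetwork(roster, adjacency=r_out | r_in, layer="union")


def baseline_intersection(reports: DoubleSampledReports, roster) -> DirectedNetwork:
    """Deterministic baseline: tie i -> j only if both sides reported it.

    Only pairs where both endpoints could report can enter; use
    :func:`both_covered_mask` for the matching evaluation denominator.
    """
    roster = [str(r) for r in roster]
    r_out, r_in, e_out, e_in = reports.to_matrices(roster)
    return DirectedNetwork(roster, adjacency=r_out & r_in & e_out & e_in,
                           layer="intersection")


def covered_mask(reports: DoubleSampledReports, roster) -> np.ndarray:
    """Boolean (n, n) mask of ordered pairs observable by >= 1 reporter."""
    roster = [str(r) for r in roster]
    _, _, e_out, e_in = reports.to_matrices(roster)
    return e_out | e_in


def both_covered_mask(reports: DoubleSampledReports, roster) -> np.ndarray:
    """Boolean (n, n) mask of ordered pairs observable from both sides."""
    roster = [str(r) for r in roster]
    _, _, e_out, e_in = reports.to_matrices(roster)
    return e_out & e_in


def balanced_accuracy(predicted: DirectedNetwork, truth: DirectedNetwork,
                      mask=None) -> float:
    """(TPR + TNR) / 2 of a predicted tie set against the true network,
    over off-diagonal ordered pairs selected by ``mask``."""
    if predicted.roster != truth.roster:
        raise ValueError("rosters differ")
    n = truth.n
    off = ~np.eye(n, dtype=bool)
    mask = off if mask is None else (np.asarray(mask, dtype=bool) & off)
    p = predicted.adjacency[mask]
    t = truth.adjacency[mask]
    tpr = (p & t).sum() / max(t.sum(), 1)
    tnr = (~p & ~t).sum() / max((~t).sum(), 1)
    return float((tpr + tnr) / 2)
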