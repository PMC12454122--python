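"""Combined stochastic-block + social-relations model for dyadic ties.

Social selection (preference homophily) on a directed advice layer is
modelled at the level of ordered pairs within one zone:

    logit P(Y_ij = 1) = mu + Bpref[g_i, g_j] + Bgender[h_i, h_j]
                        + x_i . beta_focal + x_j . beta_target
                        + z_ij . beta_dyad + s_i + r_j + d_ij

with (s_i, r_i) bivariate normal (generalized other-orientation /
popularity, correlation rho_sr), and (d_ij, d_ji) bivariate normal with
the dyadic reciprocity correlation rho_d.  Each block-offset matrix is
constrained to sum to zero so it is separated from the global intercept.

When fitted to raw double-sampled reports, the latent tie Y_ij is a
parameter observed through the two sides' reports with shared
sensitivity/specificity (avoiding pre-estimation of the network); a
pre-binarized network may be supplied instead, in which case Y is taken
as observed.

Inference is Metropolis-within-Gibbs: latent ties and measurement rates
have exact conditional updates; fixed-effect blocks, random effects and
hyperparameters get adaptive random-walk proposals (adaptation frozen
after burn-in).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .core_data import DirectedNetwork, DoubleSampledReports

logger = logging.getLogger(__name__)

#: Preference-combination labels, as (focal, target), indexing Bpref[f, t].
COMBOS = ("pro-pro", "pro-anti", "anti-pro", "anti-anti")
_COMBO_IDX = {"pro-pro": (1, 1), "pro-anti": (1, 0),
              "anti-pro": (0, 1), "anti-anti": (0, 0)}


def hpdi(samples, mass=0.95):
    """Highest posterior density interval: the narrowest window holding
    ``mass`` of the draws."""
    x = np.sort(np.asarray(samples, dtype=float))
    m = len(x)
    k = max(int(np.floor(mass * m)), 1)
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: m - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def _sum_zero_expand(free):
    """Map 3 free parameters to a 2x2 block matrix summing to zero,
    cells ordered (0,0), (0,1), (1,0) with (1,1) = -(sum)."""
    b = np.empty((2, 2))
    b[0, 0], b[0, 1], b[1, 0] = free
    b[1, 1] = -free.sum()
    return b


class BlockSRM(BaseEstimator):
    """Bayesian block + social-relations model for one zone.

    Parameters
    ----------
    iterations, burn_in, thin : int
        MCMC settings.
    include_gender_blocks : bool
        Add a second sum-to-zero block matrix over gender.
    sensitivity, specificity : float or None
        Fix the measurement rates, or (None) sample them with Beta
        priors.  Ignored when fitted to a pre-binarized network.
    prior_sd : float
        SD of the Normal(0, prior_sd^2) priors on fixed effects and
        block offsets.
    re_sd_prior : float
        Scale of the half-Normal priors on random-effect SDs;
        correlations get a uniform prior over (-1, 1) via an atanh
        transform.
    min_members : int
        Smallest zone the model will accept.

    Attributes
    ----------
    draws_ : pandas.DataFrame of retained parameter draws.
    offsets_ : DataFrame with median/HPDI per preference combination.
    roster_ : fitted roster.
    acceptance_ : dict of per-block acceptance rates.
    """

    def __init__(self, iterations=3000, burn_in=1000, thin=1,
                 include_gender_blocks=True, sensitivity=None, specificity=None,
                 prior_sd=2.5, re_sd_prior=1.0,
                 prior_sensitivity=(9.0, 1.0), prior_specificity=(99.0, 1.0),
                 min_members=10, random_state=0):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.include_gender_blocks = include_gender_blocks
        self.sensitivity = sensitivity
        self.specificity = specificity
        self.prior_sd = prior_sd
        self.re_sd_prior = re_sd_prior
        self.prior_sensitivity = prior_sensitivity
        self.prior_specificity = prior_specificity
        self.min_members = min_members
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, reports_or_network, attributes, roster=None, covariates=None,
            dyad_covariates=None, gender=None):
        """Fit the model to raw double-sampled reports (measurement mode)
        or a pre-binarized :class:`DirectedNetwork` (observed-tie mode).

        ``attributes`` is the binary preference vector aligned to the
        roster; members with a missing attribute are excluded (logged).
        """
        if isinstance(reports_or_network, DirectedNetwork):
            roster = reports_or_network.roster
        elif roster is None:
            raise ValueError("roster is required when fitting raw reports")
        roster = [str(x) for x in roster]
        y_attr = np.asarray(attributes, dtype=float)
        if y_attr.shape != (len(roster),):
            raise ValueError("attributes do not match roster size")
        keep = np.isfinite(y_attr)
        if not keep.all():
            logger.warning("excluding %d member(s) with missing attributes",
                           int((~keep).sum()))
            roster = [r for r, k in zip(roster, keep) if k]
        n = len(roster)
        if n < self.min_members:
            raise ValueError(f"insufficient dyads: zone has {n} usable members "
                             f"(minimum {self.min_members})")
        g = y_attr[keep].astype(int)

        measurement = not isinstance(reports_or_network, DirectedNetwork)
        if measurement:
            r_out, r_in, e_out, e_in = reports_or_network.to_matrices(roster)
            obs_mask = e_out | e_in  # pairs with at least one possible report
        else:
            sub = [reports_or_network.index_of(r) for r in roster]
            Y_obs = reports_or_network.adjacency[np.ix_(sub, sub)].astype(np.int8)

        C = (covariates.loc[:, :].to_numpy(dtype=float)
             if isinstance(covariates, pd.DataFrame)
             else (np.zeros((n, 0)) if covariates is None
                   else np.asarray(covariates, dtype=float)))
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            C = C[keep]
        cov_names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                     else [f"cov{k}" for k in range(C.shape[1])])
        dyads = dict(dyad_covariates or {})
        Z = {k: np.asarray(v, dtype=float) for k, v in dyads.items()}
        for k, v in Z.items():
            if v.shape != (n, n):
                raise ValueError(f"dyad covariate {k!r} has shape {v.shape}")
        h = (np.asarray(gender, dtype=int)[keep]
             if gender is not None else np.zeros(n, dtype=int))
        use_gender = self.include_gender_blocks and gender is not None

        rng = np.random.default_rng(self.random_state)
        off = ~np.eye(n, dtype=bool)
        iu, ju = np.triu_indices(n, 1)

        # --- state ---------------------------------------------------------
        mu = -2.0
        bp = np.zeros(3)  # free params of the preference block matrix
        bg = np.zeros(3)
        beta_f = np.zeros(C.shape[1])
        beta_t = np.zeros(C.shape[1])
        beta_d = np.zeros(len(Z))
        s = np.zeros(n)
        r = np.zeros(n)
        d = np.zeros((len(iu), 2))
        log_sig = np.array([-1.0, -1.0, -1.0])  # log sd of s, r, d
        z_cor = np.array([0.0, 0.0])  # atanh of rho_sr, rho_d
        sens = self.sensitivity if self.sensitivity is not None else 0.85
        spec = self.specificity if self.specificity is not None else 0.99
        if measurement:
            Y = (r_out | r_in).astype(np.int8)  # init at union of reports
        else:
            Y = Y_obs

        zkeys = list(Z)
        znames = [f"dyad_{k}" for k in zkeys]

        def fixed_logits(mu_, bp_, bg_, bf_, bt_, bd_):
            Bp = _sum_zero_expand(bp_)
            L = mu_ + Bp[g][:, g]
            if use_gender:
                Bg = _sum_zero_expand(bg_)
                L = L + Bg[h][:, h]
            if C.shape[1]:
                L = L + (C @ bf_)[:, None] + (C @ bt_)[None, :]
            for w, k in zip(bd_, zkeys):
                L = L + w * Z[k]
            return L

        def dyad_mat():
            D = np.zeros((n, n))
            D[iu, ju] = d[:, 0]
            D[ju, iu] = d[:, 1]
            return D

        def loglik(L):
            # Bernoulli log-likelihood over off-diagonal ordered pairs
            return float((Y[off] * L[off] - np.logaddexp(0.0, L[off])).sum())

        Lfix = fixed_logits(mu, bp, bg, beta_f, beta_t, beta_d)

        def full_logits():
            return Lfix + s[:, None] + r[None, :] + dyad_mat()

        # --- adaptive block proposals --------------------------------------
        blocks = {
            "mu": np.array([0]), "bp": None, "bg": None,
            "beta_f": None, "beta_t": None, "beta_d": None,
        }
        scales = {k: 0.2 for k in
                  ("mu", "bp", "bg", "beta_f", "beta_t", "beta_d",
                   "s", "r", "d", "hyper")}
        acc = {k: 0 for k in scales}
        tries = {k: 0 for k in scales}
        del blocks

        def mh_fixed(name, vec, setter):
            nonlocal Lfix
            if len(vec) == 0:
                return vec
            prop = vec + scales[name] * rng.standard_normal(len(vec))
            Lp = setter(prop)
            cur_ll = loglik(full_logits())
            Lfix_old = Lfix
            Lfix = Lp
            new_ll = loglik(full_logits())
            lp = -0.5 * ((prop ** 2).sum() - (vec ** 2).sum()) / self.prior_sd ** 2
            tries[name] += 1
            if np.log(rng.random()) < new_ll - cur_ll + lp:
                acc[name] += 1
                return prop
            Lfix = Lfix_old
            return vec

        n_dy = len(iu)
        kept_rows = []
        names = (["intercept"]
                 + [f"block_pref[{c}]" for c in COMBOS]
                 + ([f"block_gender[{k}]" for k in range(4)] if use_gender else [])
                 + [f"focal_{c}" for c in cov_names]
                 + [f"target_{c}" for c in cov_names]
                 + znames
                 + ["sd_sender", "sd_receiver", "cor_sender_receiver",
                    "sd_dyad", "cor_dyad", "sensitivity", "specificity"])

        for it in range(self.iterations):
            adapt = it < self.burn_in
            # --- latent ties and measurement rates -------------------------
            if measurement:
                L = full_logits()
                p1 = (np.log(expit(L))
                      + r_out * np.log(sens) + (e_out & ~r_out) * np.log1p(-sens)
                      + r_in * np.log(sens) + (e_in & ~r_in) * np.log1p(-sens))
                p0 = (np.log1p(-expit(L))
                      + r_out * np.log(1 - spec) + (e_out & ~r_out) * np.log(spec)
                      + r_in * np.log(1 - spec) + (e_in & ~r_in) * np.log(spec))
                prob = expit(p1 - p0)
                Y = (rng.random((n, n)) < prob).astype(np.int8)
                np.fill_diagonal(Y, 0)
                if self.sensitivity is None:
                    pos = (Y == 1)
                    k1 = float((r_out & pos & e_out).sum() + (r_in & pos & e_in).sum())
                    m1 = float((pos & e_out).sum() + (pos & e_in).sum())
                    sens = float(np.clip(rng.beta(self.prior_sensitivity[0] + k1,
                                                  self.prior_sensitivity[1] + m1 - k1),
                                         1e-6, 1 - 1e-6))
                if self.specificity is None:
                    neg = (Y == 0) & off
                    k0 = float((r_out & neg & e_out).sum() + (r_in & neg & e_in).sum())
                    m0 = float((neg & e_out).sum() + (neg & e_in).sum())
                    spec = float(np.clip(rng.beta(self.prior_specificity[0] + m0 - k0,
                                                  self.prior_specificity[1] + k0),
                                         1e-6, 1 - 1e-6))

            # --- fixed effects ---------------------------------------------
            muv = mh_fixed("mu", np.array([mu]),
                           lambda v: fixed_logits(v[0], bp, bg, beta_f, beta_t, beta_d))
            mu = float(muv[0])
            bp = mh_fixed("bp", bp,
                          lambda v: fixed_logits(mu, v, bg, beta_f, beta_t, beta_d))
            if use_gender:
                bg = mh_fixed("bg", bg,
                              lambda v: fixed_logits(mu, bp, v, beta_f, beta_t, beta_d))
            beta_f = mh_fixed("beta_f", beta_f,
                              lambda v: fixed_logits(mu, bp, bg, v, beta_t, beta_d))
            beta_t = mh_fixed("beta_t", beta_t,
                              lambda v: fixed_logits(mu, bp, bg, beta_f, v, beta_d))
            beta_d = mh_fixed("beta_d", beta_d,
                              lambda v: fixed_logits(mu, bp, bg, beta_f, beta_t, v))

            # --- random effects (parallel per-unit MH) ----------------------
            sig_s, sig_r, sig_d = np.exp(log_sig)
            rho_sr, rho_d = np.tanh(z_cor)
            L = full_logits()

            def bvn_lp(a, b, sa, sb, rho):
                det = sa ** 2 * sb ** 2 * (1 - rho ** 2)
                q = (sb ** 2 * a ** 2 - 2 * rho * sa * sb * a * b
                     + sa ** 2 * b ** 2) / det
                return -0.5 * q

            # sender effects: row-wise independent given everything else
            prop_s = s + scales["s"] * rng.standard_normal(n)
            Lp = L + (prop_s - s)[:, None]
            mask = off
            d_ll = ((Y * Lp - np.logaddexp(0.0, Lp)) * mask).sum(axis=1) \
                 - ((Y * L - np.logaddexp(0.0, L)) * mask).sum(axis=1)
            d_lp = bvn_lp(prop_s, r, sig_s, sig_r, rho_sr) - bvn_lp(s, r, sig_s, sig_r, rho_sr)
            acc_mask = np.log(rng.random(n)) < d_ll + d_lp
            s = np.where(acc_mask, prop_s, s)
            tries["s"] += 1
            acc["s"] += float(acc_mask.mean())
            L = full_logits()

            # receiver effects: column-wise independent
            prop_r = r + scales["r"] * rng.standard_normal(n)
            Lp = L + (prop_r - r)[None, :]
            d_ll = ((Y * Lp - np.logaddexp(0.0, Lp)) * mask).sum(axis=0) \
                 - ((Y * L - np.logaddexp(0.0, L)) * mask).sum(axis=0)
            d_lp = bvn_lp(s, prop_r, sig_s, sig_r, rho_sr) - bvn_lp(s, r, sig_s, sig_r, rho_sr)
            acc_mask = np.log(rng.random(n)) < d_ll + d_lp
            r = np.where(acc_mask, prop_r, r)
            tries["r"] += 1
            acc["r"] += float(acc_mask.mean())
            L = full_logits()

            # dyad effects: per-dyad joint proposal on (d_ij, d_ji)
            prop_d = d + scales["d"] * rng.standard_normal((n_dy, 2))
            l_ab, l_ba = L[iu, ju], L[ju, iu]
            lp_ab = l_ab + (prop_d[:, 0] - d[:, 0])
            lp_ba = l_ba + (prop_d[:, 1] - d[:, 1])
            y_ab, y_ba = Y[iu, ju], Y[ju, iu]
            d_ll = (y_ab * lp_ab - np.logaddexp(0.0, lp_ab)
                    + y_ba * lp_ba - np.logaddexp(0.0, lp_ba)
                    - y_ab * l_ab + np.logaddexp(0.0, l_ab)
                    - y_ba * l_ba + np.logaddexp(0.0, l_ba))
            d_lp = (bvn_lp(prop_d[:, 0], prop_d[:, 1], sig_d, sig_d, rho_d)
                    - bvn_lp(d[:, 0], d[:, 1], sig_d, sig_d, rho_d))
            acc_mask = np.log(rng.random(n_dy)) < d_ll + d_lp
            d = np.where(acc_mask[:, None], prop_d, d)
            tries["d"] += 1
            acc["d"] += float(acc_mask.mean())

            # --- hyperparameters -------------------------------------------
            prop_ls = log_sig + scales["hyper"] * rng.standard_normal(3)
            prop_zc = z_cor + scales["hyper"] * rng.standard_normal(2)

            def hyper_lp(ls, zc):
                sa, sb, sd_ = np.exp(ls)
                ra, rd = np.tanh(zc)
                lp = (bvn_lp(s, r, sa, sb, ra).sum()
                      - n * (ls[0] + ls[1] + 0.5 * np.log(1 - ra ** 2))
                      + bvn_lp(d[:, 0], d[:, 1], sd_, sd_, rd).sum()
                      - n_dy * (2 * ls[2] + 0.5 * np.log(1 - rd ** 2)))
                # half-Normal prior on sds (+ Jacobian of the log transform),
                # uniform prior on correlations (+ Jacobian of atanh)
                lp += (-0.5 * ((np.exp(ls) / self.re_sd_prior) ** 2).sum()
                       + ls.sum())
                lp += np.log(1 - np.tanh(zc) ** 2).sum()
                return lp

            tries["hyper"] += 1
            if np.log(rng.random()) < hyper_lp(prop_ls, prop_zc) - hyper_lp(log_sig, z_cor):
                log_sig, z_cor = prop_ls, prop_zc
                acc["hyper"] += 1

            if adapt and (it + 1) % 50 == 0:
                for kname in scales:
                    rate = acc[kname] / max(tries[kname], 1)
                    target = 0.25 if kname in ("mu", "bp", "bg", "beta_f",
                                               "beta_t", "beta_d", "hyper") else 0.4
                    scales[kname] *= np.exp(0.6 * (rate - target))
                    acc[kname] = 0
                    tries[kname] = 0

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                Bp = _sum_zero_expand(bp)
                row = [mu] + [Bp[_COMBO_IDX[c]] for c in COMBOS]
                if use_gender:
                    Bg = _sum_zero_expand(bg)
                    row += list(Bg.ravel())
                row += list(beta_f) + list(beta_t) + list(beta_d)
                sig_s, sig_r, sig_d = np.exp(log_sig)
                rho_sr, rho_d = np.tanh(z_cor)
                row += [sig_s, sig_r, rho_sr, sig_d, rho_d, sens, spec]
                kept_rows.append(row)

        self.draws_ = pd.DataFrame(kept_rows, columns=names)
        self.roster_ = roster
        self.acceptance_ = {k: acc[k] / max(tries[k], 1) for k in acc}
        self.offsets_ = self._offset_table()
        return self

    def _offset_table(self) -> pd.DataFrame:
        rows = {}
        for c in COMBOS:
            x = self.draws_[f"block_pref[{c}]"]
            lo, hi = hpdi(x)
            rows[c] = {"median": float(x.median()), "hpdi_lower": lo,
                       "hpdi_upper": hi}
        return pd.DataFrame(rows).T


def fit_block_srm(reports_or_network, attributes, roster=None, covariates=None,
                  dyad_covariates=None, gender=None, seed=0, **settings) -> BlockSRM:
    """Fit :class:`BlockSRM` on one zone; returns the fitted model."""
    model = BlockSRM(random_state=seed, **settings)
    return model.fit(reports_or_network, attributes, roster=roster,
                     covariates=covariates, dyad_covariates=dyad_covariates,
                     gender=gender)


def block_contrasts(draws, reference: str = "pro-pro") -> pd.DataFrame:
    """Per-combination offsets and their contrasts against ``reference``.

    For each preference combination, reports the posterior median and 95%
    HPDI of the block offset and of the per-draw difference
    offset[combo] - offset[reference].  The reference's contrast with
    itself is exactly 0 with a zero-width interval.
    """
    if isinstance(draws, BlockSRM):
        draws = draws.draws_
    if reference not in COMBOS:
        raise ValueError(f"unknown reference combination {reference!r}")
    ref = draws[f"block_pref[{reference}]"].to_numpy()
    rows = {}
    for c in COMBOS:
        x = draws[f"block_pref[{c}]"].to_numpy()
        diff = x - ref
        olo, ohi = hpdi(x)
        clo, chi = hpdi(diff)
        rows[c] = {
            "offset_median": float(np.median(x)),
            "offset_hpdi_lower": olo, "offset_hpdi_upper": ohi,
            "contrast_median": float(np.median(diff)),
            "contrast_hpdi_lower": clo, "contrast_hpdi_upper": chi,
        }
    out = pd.DataFrame(rows).T
    out.loc[reference, ["contrast_median", "contrast_hpdi_lower",
                        "contrast_hpdi_upper"]] = 0.0
    out.attrs["reference"] = reference
    return out


def fit_all_zones(population: pd.DataFrame, reports: DoubleSampledReports,
                  covariate_cols=(), dyad_covariates_by_zone=None,
                  reference: str = "pro-pro", reporters_only: bool = True,
                  seed: int = 0, **settings) -> dict:
    """One independent :class:`BlockSRM` fit per zone.

    Zones failing preconditions (too small, or a constant preference
    vector) are reported in the result as skip records, not fatal; if all
    zones fail, raises.  Returns ``{zone: {"contrasts": DataFrame,
    "model": BlockSRM} | {"skipped": reason}}``.
    """
    from .core_data import preference_vector

    results = {}
    rng = np.random.default_rng(seed)
    n_ok = 0
    for zone, zdf in population.groupby("zone"):
        if reporters_only:
            zdf = zdf[zdf["is_reporter"]]
        roster = list(zdf["id"].astype(str))
        y = preference_vector(zdf, roster)
        zseed = int(rng.integers(2 ** 31))
        try:
            if len(roster) >= 2 and y.min() == y.max():
                raise ValueError("constant preference vector in zone")
            cov = zdf[list(covariate_cols)] if covariate_cols else None
            dyad = (dyad_covariates_by_zone or {}).get(zone)
            model = fit_block_srm(reports, y, roster=roster, covariates=cov,
                                  dyad_covariates=dyad, seed=zseed, **settings)
            results[int(zone)] = {"contrasts": block_contrasts(model, reference),
                                  "model": model}
            n_ok += 1
        except ValueError as e:
            logger.warning("zone %s skipped: %s", zone, e)
            results[int(zone)] = {"skipped": str(e)}
    if n_ok == 0:
        raise ValueError("all zones failed preconditions")
    return results
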