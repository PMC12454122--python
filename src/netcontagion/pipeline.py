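"""Config-driven end-to-end runs.

Stage order: simulate (or load CSV input) -> latent-network estimation
for the double-sampled layers -> descriptives -> ALAAMs per layer and
tie scope -> per-zone homophily fits.  Every stage writes its outputs
under the run directory and appends a record (outputs, seed, status) to
a JSON manifest; a failed stage is recorded and its dependents skipped,
leaving completed artifacts intact.

Stage seeds derive from the master seed by hashing ``"<master>:<stage>"``
(SHA-256, reduced mod 2^31), so every stochastic stage has an explicit,
reproducible seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alaam import StatisticConfig, fit_alaam, goodness_of_fit
from .core_data import build_layer, preference_vector, split_kin, write_tables
from .descriptives import (classify_norms, jaccard_overlap, network_summary,
                           prevalence_table)
from .homophily_srm import fit_all_zones
from .latent_network import fit_latent_network
from .synthetic_data import SimConfig, generate_dataset

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    ``config`` keys (all optional): ``sim`` (SimConfig field overrides or
    a SimConfig), ``alaam`` / ``latent`` / ``homophily`` (settings dicts
    forwarded to the fitters), ``layers`` (ALAAM layers to fit).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "master_seed": int(seed), "stages": []}
    state = {}

    def stage(name, deps, fn):
        rec = {"stage": name, "seed": derive_seed(seed, name)}
        failed = [d for d in deps if d not in state]
        if failed:
            rec["status"] = "skipped"
            rec["reason"] = f"dependency failed: {failed}"
        else:
            t0 = time.time()
            try:
                rec["outputs"] = fn(rec["seed"]) or []
                rec["status"] = "ok"
            except Exception as e:  # record, keep completed artifacts
                logger.exception("stage %s failed", name)
                rec["status"] = "failed"
                rec["reason"] = f"{type(e).__name__}: {e}"
            rec["elapsed_s"] = round(time.time() - t0, 2)
        manifest["stages"].append(rec)
        _write_manifest(out, manifest)
        return rec["status"] == "ok"

    def _simulate(s):
        sim = config.get("sim", {})
        sim_cfg = sim if isinstance(sim, SimConfig) else SimConfig(**sim)
        data = generate_dataset(sim_cfg, seed=s)
        write_tables(data["population"], data["nominations"],
                     out / "respondents.csv", out / "nominations.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump({"y": [int(v) for v in data["truth"]["y"]],
                       "theta_contagion": data["truth"]["theta_contagion"],
                       "zone_prevalence": data["truth"]["zone_prevalence"],
                       "regime": data["truth"]["regime"]}, fh)
        state["data"] = data
        return ["respondents.csv", "nominations.csv", "ground_truth.json"]

    if stage("simulate", [], _simulate):
        state["simulate"] = True

    def _latent(s):
        data = state["data"]
        outputs = []
        latent = {}
        settings = dict(config.get("latent", {}))
        roster = list(data["population"]["id"].astype(str))
        for layer, reports in data["reports"].items():
            est = fit_latent_network(reports, roster,
                                     seed=derive_seed(s, layer), **settings)
            latent[layer] = est
            ii, jj = np.nonzero(est.rho_ > 0)
            pd.DataFrame({"i": [est.roster_[a] for a in ii],
                          "j": [est.roster_[b] for b in jj],
                          "rho": est.rho_[ii, jj]}).to_csv(
                out / f"rho_{layer}.csv", index=False)
            with open(out / f"latent_{layer}.json", "w") as fh:
                json.dump({"eta_est": est.eta_est_, "t_rho": est.t_rho_,
                           "lambda1": est.lambda1_mean_,
                           "lambda0": est.lambda0_mean_}, fh)
            est.binarized_.write_graphml(out / f"latent_{layer}.graphml")
            outputs += [f"rho_{layer}.csv", f"latent_{layer}.json",
                        f"latent_{layer}.graphml"]
        state["latent"] = latent
        return outputs

    if "data" in state:
        stage("latent_networks", ["data"], _latent) and state.setdefault("latent_ok", True)

    def _describe(s):
        data = state["data"]
        pop, noms = data["population"], data["nominations"]
        roster = list(pop["id"].astype(str))
        outputs = []
        layers = {g: build_layer(noms, g, roster)
                  for g in ("chatting", "respect")}
        for name, est in state.get("latent", {}).items():
            layers[name] = est.binarized_
        summaries = pd.DataFrame({k: network_summary(v)
                                  for k, v in layers.items()}).T
        summaries.to_csv(out / "network_summaries.csv")
        gens = sorted(noms["generator"].unique())
        jac = pd.DataFrame(
            [[jaccard_overlap(noms, a, b)[0] for b in gens] for a in gens],
            index=gens, columns=gens)
        jac.to_csv(out / "jaccard.csv")
        prevalence_table(pop).to_csv(out / "prevalence.csv")
        _, aggregates = classify_norms(pop)
        aggregates["by_zone"].to_csv(out / "norms_by_zone.csv")
        aggregates["by_preference"].to_csv(out / "norms_by_preference.csv")
        outputs += ["network_summaries.csv", "jaccard.csv", "prevalence.csv",
                    "norms_by_zone.csv", "norms_by_preference.csv"]
        state["layers"] = layers
        return outputs

    if "data" in state:
        stage("descriptives", ["data"], _describe)

    def _alaam(s):
        data = state["data"]
        pop = data["population"]
        roster = list(pop["id"].astype(str))
        y = preference_vector(pop, roster)
        cov = _design_covariates(pop)
        settings = dict(config.get("alaam", {}))
        layer_names = config.get("layers", ["chatting"])
        scopes = config.get("tie_scopes", ["all"])
        outputs = []
        for lname in layer_names:
            base = state.get("layers", {}).get(lname) or \
                build_layer(data["nominations"], lname, roster)
            for scope in scopes:
                net = base
                if scope == "kin":
                    net = split_kin(base)[0]
                elif scope == "nonkin":
                    net = split_kin(base)[1]
                cfg = StatisticConfig(tie_scope=scope)
                model = fit_alaam(y, net, cov, config=cfg,
                                  seed=derive_seed(s, f"{lname}:{scope}"),
                                  **settings)
                tag = f"{lname}_{scope}"
                model.draws_.to_csv(out / f"alaam_draws_{tag}.csv", index=False)
                model.summary_.to_csv(out / f"alaam_summary_{tag}.csv")
                gof = goodness_of_fit(model, y, net, cov, cfg, n_sim=50,
                                      seed=derive_seed(s, f"gof:{tag}"))
                gof.to_csv(out / f"alaam_gof_{tag}.csv")
                outputs += [f"alaam_draws_{tag}.csv", f"alaam_summary_{tag}.csv",
                            f"alaam_gof_{tag}.csv"]
        return outputs

    if "data" in state:
        stage("alaam", ["data"], _alaam)

    def _homophily(s):
        data = state["data"]
        pop = data["population"]
        layer = config.get("homophily_layer", "advice")
        reports = data["reports"][layer]
        settings = dict(config.get("homophily", {}))
        results = fit_all_zones(pop, reports, seed=s, **settings)
        outputs = []
        rows = []
        for zone, res in results.items():
            if "skipped" in res:
                rows.append({"zone": zone, "skipped": res["skipped"]})
                continue
            ct = res["contrasts"]
            ct.to_csv(out / f"homophily_contrasts_zone{zone}.csv")
            outputs.append(f"homophily_contrasts_zone{zone}.csv")
            for combo, r in ct.iterrows():
                rows.append({"zone": zone, "combination": combo,
                             "median": r["offset_median"],
                             "lower": r["offset_hpdi_lower"],
                             "upper": r["offset_hpdi_upper"]})
        pd.DataFrame(rows).to_csv(out / "homophily_forest.csv", index=False)
        outputs.append("homophily_forest.csv")
        return outputs

    if "data" in state:
        stage("homophily", ["data"], _homophily)

    _write_manifest(out, manifest)
    return manifest


def _design_covariates(population: pd.DataFrame) -> pd.DataFrame:
    """Standard adjustment-set design matrix: standardized age, gender,
    education indicators, and zone indicators (largest zone reference)."""
    pop = population
    age = pd.to_numeric(pop["age"])
    cols = {"age_std": (age - age.mean()) / age.std()}
    cols["woman"] = (pop["gender"] == "woman").astype(float)
    for lev in ("some_primary", "completed_primary", "some_secondary_plus"):
        cols[f"edu_{lev}"] = (pop["education"] == lev).astype(float)
    sizes = pop["zone"].value_counts()
    ref = sizes.idxmax()
    for z in sorted(pop["zone"].unique()):
        if z != ref:
            cols[f"zone_{z}"] = (pop["zone"] == z).astype(float)
    return pd.DataFrame(cols, index=pop.index)


def _write_manifest(out: Path, manifest: dict):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
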