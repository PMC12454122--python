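# netcontagion

Statistical machinery for asking whether a binary practice preference —
the motivating case is pro-/anti-FGMC (female genital mutilation/cutting)
preference surveyed across the zones of a rural community — clusters on
socio-centric social networks through **social influence** ("contagion")
or **social selection** (preference homophily), starting from raw
name-generator survey tables.

The package covers the full analysis surface:

* **Latent-network reconstruction** from double-sampled name generators
  ("who would you go to" / "who would come to you"): a Bayesian model
  with latent directed ties Y_ij, a log-linear dyad mutuality term, and
  per-report sensitivity/false-positive rates (λ₁, λ₀), binarized at the
  mutuality-based threshold **t_ρ = 0.33·η_est + 0.10**, with union /
  intersection deterministic baselines.
* **Autologistic actor-attribute models (ALAAM)** for social influence:
  P(y|θ) ∝ exp(θ·s(y)) on a fixed network, with the direct-contagion
  statistic Σ_{i<j} Y_i Y_j X⁺_ij (plus reciprocal, indirect,
  closed-indirect and transitive variants), exact enumeration for small
  rosters, Gibbs simulation, and a doubly-intractable posterior sampled
  with the **exchange algorithm**.
* **Combined stochastic-block + social-relations models** for social
  selection: per-zone dyadic regressions with 2×2 preference (and
  gender) block offsets, focal/target/dyad covariates, correlated
  sender/receiver effects, dyadic reciprocity, and a report measurement
  layer; contrasts against a reference preference combination with 95%
  HPDIs.
* **Descriptives**: Jaccard overlap between name generators, per-layer
  ties/density/reciprocity/transitivity/isolates, centrality profiles by
  preference class, per-zone prevalence, and social-norm expectation
  classification (empirical expectations on a 0–100% decile scale,
  normative approval, and their joint criterion).
* **A synthetic-data generator** producing populations, multi-layer
  zone-clustered networks, capped noisy double-sampled reports and
  preference vectors under influence / selection / null regimes with
  known ground truth, so every stage is testable end to end.

## Worked example

```python
from netcontagion import SimConfig, generate_dataset, build_layer, \
    preference_vector, fit_alaam
from netcontagion.pipeline import _design_covariates

cfg = SimConfig(zone_sizes=(170, 170, 160), mean_degree=6.0,
                zone_prevalence=(0.12, 0.08, 0.05), regime="influence",
                theta_contagion=0.5)
data = generate_dataset(cfg, seed=1)
pop = data["population"]
net = data["networks"]["chatting"]            # true chatting layer
y = data["truth"]["y"]                        # 1 = pro-preference
model = fit_alaam(y, net, _design_covariates(pop),
                  iterations=3000, burn_in=1000, aux_sweeps=40, seed=2)
print(model.summary_.loc["contagion_direct"].round(3))
```

prints (seeds as above):

```
median             0.480
lower95            0.310
upper95            0.631
prop_above_zero    1.000
```

The direct-contagion coefficient used to generate the outcomes was 0.5:
the posterior median lands at 0.48, the 95% credible interval covers the
truth, and the proportion of the posterior above zero — the quantity
read as the strength of the influence signal — is 1.0.  Re-running with
`regime="null"` (contagion 0) gives intervals straddling zero and
proportions near 0.5.

The same objects drive the other models, e.g.

```python
from netcontagion import fit_latent_network, threshold_ties
est = fit_latent_network(data["reports"]["money"],
                         list(pop["id"]), seed=3)
money_net = threshold_ties(est)   # ties where rho > 0.33*eta_est + 0.10
```

A `netcontagion` command-line tool wraps the pipeline
(`simulate`, `estimate-network`, `describe`, `fit-alaam`,
`fit-homophily`, `run`); `netcontagion run --out dir/ --seed 1` executes
the whole chain and writes a JSON manifest of stage seeds and outputs.

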