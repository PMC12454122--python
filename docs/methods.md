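# Methods

This note documents the models the package implements, the parameters
that matter, the synthetic study conditions the validation suite uses,
and the numerical and design choices made where the design was open.

## The scientific setting

A socio-centric survey maps a bounded rural community (several
administrative zones of unequal size) with six name generators: chatting
and respect (single-sampled, "who do you…"), and money-borrowing and
marriage-advice, each elicited from **both** sides of the relation
("who would you go to" / "who would come to you") with up to ten
nominations per generator.  Roughly half of respondents are sampled as
network reporters.  The outcome is a binary practice preference (pro =
answering yes to wanting the practice for a hypothetical daughter *or*
daughter-in-law), held at low prevalence (~1–12% per zone).  The
analytic questions: does the preference cluster on these networks via
social influence (contagion) or social selection (homophily), and do
empirical/normative expectations support a social-norm account?

## Latent-network model (double-sampled generators)

Each ordered pair (i, j) carries a latent tie Y_ij ∈ {0, 1}.  The dyad
(Y_ij, Y_ji) has the log-linear prior
P ∝ exp(α(Y_ij + Y_ji) + β·Y_ij·Y_ji); each eligible reporter's
statement about the pair is Bernoulli(λ₁) if the tie exists and
Bernoulli(λ₀) otherwise.  Gibbs sampling alternates exact 4-state dyad
updates, conjugate Beta updates for (λ₁, λ₀) (priors Beta(9, 1) and
Beta(1, 99)), and random-walk Metropolis for (α, β) (Normal priors; α is
centred at logit of the prior tie probability, default 0.005).  Pairs
with no eligible reporter revert to the prior; one- versus two-sided
observability is weighted automatically through the likelihood.

* **Mutuality** is summarized as η_est = posterior mean of
  P(Y_ji = 1 | Y_ij = 1) = sigmoid(α + β), a concrete definition
  guaranteed to lie in [0, 1]; whether it coincides numerically with the
  mutuality parameter of other published estimators is unknown, and the
  binarization threshold **t_ρ = 0.33·η_est + 0.10** (strict inequality
  ρ > t_ρ; ties at the threshold are not ties) is applied to this
  definition.
* Rates are global across reporters by default (identifiable at our
  sample sizes); scope can be the full roster or reporters only.
* Numerical guard: λ's are clipped to [1e-18, 1 − 1e-9].  The asymmetric
  clip preserves λ₁/λ₀ → ∞ in the noiseless limit, so at λ₁ = 1, λ₀ = 0
  a positive report stays decisive and the binarized network equals the
  union of reports exactly.
* The nomination cap is **not** represented in the report likelihood; the
  model is accurate when reporters' degrees sit below the cap.
* Known limitation (verified analytically and by simulation): with a
  very small false-positive rate and homogeneous reporters, the Bayes
  decision at t_ρ coincides with the union rule for every singly-reported
  pair, and recovery of unreported ties through the mutuality channel
  requires the odds η/(1−η)·(1−λ₁) to exceed t_ρ/(1−t_ρ) — which the
  threshold formula tracks within ~0.02 across the whole η range.  Under
  the documented study conditions (λ₁ = 0.8, λ₀ = 0.002, reciprocity
  0.45) the thresholded latent network therefore ties with, rather than
  beats, the union baseline on balanced accuracy, while clearly beating
  the intersection baseline; the corresponding acceptance assertion is
  expected to fail and is retained as a documented negative result.

## ALAAM (social influence)

P(y | θ) ∝ exp(θ·s(y)) on a fixed, exogenous directed network.
Statistics: intercept Σy_i; activity Σy_i·outdeg_i; popularity
Σy_i·indeg_i; covariate main effects Σy_i·c_i (age, gender, education
indicators, zone indicators with the largest zone as reference);
contagion counts on the symmetrized adjacency x⁺_ij = max(x_ij, x_ji)
over unordered pairs — direct Σ_{i<j} y_i y_j x⁺_ij, reciprocal
(x_ij x_ji), indirect (no x⁺ tie but a shared x⁺ neighbour),
closed-indirect (x⁺ tie and a shared neighbour), transitive (all-pro
x⁺ triangles).  Direct contagion must be enabled whenever a higher-order
variant is (hierarchy), and out-/in-degree terms serve as the
lower-order controls.  Symmetrization is used for all contagion
statistics because the pair sum runs over i < j.

* **Exact enumeration** (n ≤ 15) provides oracle moments and an exact
  posterior on θ grids for tests.
* **Gibbs simulation** uses a systematic scan of the full conditionals
  logit P(y_i = 1 | y_−i) = θ·Δs_i with incrementally maintained fields
  (numba-compiled kernel).
* **Posterior sampling** uses the exchange algorithm: propose θ′ from an
  adaptive random walk (scalar scale and covariance shape adapted during
  burn-in only, then frozen), draw an auxiliary outcome vector from the
  model at θ′ by Gibbs (default 40–50 full sweeps, initialized at the
  observed outcome — the key approximation knob; the acceptance ratio is
  exact only in the limit of a perfect auxiliary draw), and accept with
  the exchange ratio.  Priors are Normal(0, 5²) on every coefficient.
* Summaries: median, central 95% interval, and the proportion of the
  posterior above zero.  Goodness of fit simulates outcomes at posterior
  draws and reports t-ratios (obs − sim mean)/sim SD for *all*
  statistics, including variants not in the fitted model; a
  zero-variance statistic yields NaN, not an error.
* Degenerate inputs: a constant outcome vector is an error ("outcome
  non-identified"); a contagion statistic with no qualifying pairs
  raises a warning flag.

## Block + social-relations model (social selection)

Within one zone, logit P(Y_ij = 1) = μ + Bpref[g_i, g_j] +
Bgender[h_i, h_j] + x_i·β_focal + x_j·β_target + z_ij·β_dyad + s_i +
r_j + d_ij, with (s_i, r_i) bivariate normal (correlation ρ_sr) and
(d_ij, d_ji) bivariate normal with the dyadic reciprocity correlation
ρ_d.  Each 2×2 block matrix is constrained to **sum to zero** (three
free parameters; the fourth is the negative sum), which separates the
offsets from the global intercept — adding a constant to all offsets
and subtracting it from μ leaves the likelihood invariant, so the
constraint is what pins the reported values.  Under this constraint a
single generating cell of +b appears as +3b/4 (the other cells −b/4).

When fitted to raw double-sampled reports, the latent Y_ij is observed
through the two sides' reports with shared sensitivity/specificity (Beta
priors Beta(9, 1) and Beta(99, 1)); a pre-binarized network can be
supplied instead.  Priors: Normal(0, 2.5²) on fixed effects and offsets,
half-Normal(1) on random-effect SDs, uniform over (−1, 1) on
correlations via an atanh transform.  Sampling is Metropolis-within-
Gibbs: exact conditional updates for latent ties and measurement rates;
adaptive random-walk blocks for fixed effects; parallel per-row /
per-column / per-dyad proposals for s, r, d (valid because each unit's
conditional is independent of the others' given the rest); adaptation
frozen after burn-in.  Zones are fitted independently; zones under 10
usable members, or with a constant preference vector, are skipped with a
recorded reason.  Contrasts are per-draw differences against a reference
combination (default pro→pro), summarized by medians and 95% HPDIs
(narrowest-window estimator).

A *homophily call* is defined as one preference combination whose 95%
HPDI fails to overlap the HPDIs of **all** other combinations — the
forest-plot pattern actually read as a selection signal; isolated
pairwise non-overlaps between two middle cells are not calls.

## Synthetic-data generator: what it emulates, and what not

Defaults encode the emulated design: nine zones of unequal size
(40–120 in the scaled-down default), reporter fraction 0.5, nomination
cap 10, kin fraction 0.45, within-zone mixing 0.95 (ties cluster in
zones), per-zone prevalence spread 1.4–12.1% produced by zone-specific
intercepts (demographics deliberately do not explain it), reporting
sensitivity λ₁ = 0.8 and within-zone false-positive rate λ₀ = 0.002
(fixture choices — no field value exists), and dyad-level reciprocity
0.45 for the network layers, matching the observed reciprocity of the
double-sampled layers (0.42–0.44; note those observed values are
themselves biased downward by partial reporting).  Ages are
gamma-skewed over 15–80 (median ≈ 30), education ≈ 24/46/12/18% over the
four levels, religion ≈ 94% majority, community roles ≈ 3.7%.

Regimes: *influence* draws the preference vector from the ALAAM joint
distribution by Gibbs; zone intercepts are lowered by θ·(mean x⁺
degree)·(target prevalence) so the configured prevalences remain
mean-field fixed points under contagion (without this, positive
contagion tips low-prevalence configurations to a high-prevalence
attractor).  *Selection* draws independent preferences, then the advice
layer from the dyadic model with a preference-block offset matrix.
*Null* is either with zero effect — the two nulls are distributionally
equivalent and downstream models must not find signal in either.

Not emulated: name-string matching error beyond an UNMATCHED fraction,
reporter heterogeneity in (λ₁, λ₀), elicitation order within the cap
(cap enforcement is uniform subsampling), household/GPS structure, and
longitudinal dynamics.  Passing tests therefore demonstrate correctness
of the estimators under the stated generative assumptions, not
robustness to the full messiness of field data.

## Validation study conditions (scripts/acceptance.py, tests)

Sizes are scaled to run on one CPU in minutes while keeping rates and
effect sizes at their documented values:

* **ALAAM recovery/calibration**: one community of n = 500 over three
  zones (prevalences 0.12/0.08/0.05), mean degree 6; 20 replicates per
  regime; θ_contagion = 0.5 (recovery) or 0 (null); exchange settings
  3000 iterations / 1000 burn-in / 40 auxiliary sweeps.
* **Exchange-vs-grid**: n = 8, two-parameter model (intercept + direct
  contagion, degree terms disabled), 12000 iterations against an 81×81
  grid over ±8; agreement is measured as marginal KL on 24 shared bins,
  documented tolerance 0.15 (observed ≈ 0.02–0.05).
* **Latent network**: n = 300 over two zones, mean degree 5, reciprocity
  0.45, λ₁ = 0.8, λ₀ = 0.002, cap 10, half reporters; balanced accuracy
  on reporter-covered ordered pairs (both-covered pairs for the
  intersection baseline, which is undefined elsewhere).
* **Block-SRM**: one zone of n = 80, pro share 0.35 (a 2×2 block model
  cannot be estimated at 1–12% prevalence on 80 people — the low-
  prevalence regime is served by the ALAAM studies), mean degree 3.0 so
  the nomination cap essentially never binds (the measurement model does
  not represent the cap; at higher densities cap truncation selectively
  removes ties into the boosted cell and attenuates the recovered
  offset), λ₁ = 0.9, λ₀ = 0.002; +1.5 pro→pro generating offset
  (sum-to-zero target +1.125); 2500 iterations / 1000 burn-in.
  A residual ≈ 6% downward bias of the recovered offset remains even
  when fitting the true network (prior shrinkage and random-effect
  absorption) and is visible in the reported medians.

## Other numerical choices

* All ids are opaque strings; roster row order defines every vector
  index.  Duplicate nominations collapse (tie sets); self-ties and
  off-roster alters are dropped with counts logged; UNMATCHED alters are
  excluded from networks but counted.
* In-direction generators are reversed at layer construction so both
  sides of a double-sampled pair describe the same directed relation.
* Kin flags are symmetric per dyad in the generator; a tie is kin if any
  nomination producing it was kin-labelled; a missing kin flag defaults
  to non-kin.
* Jaccard overlap is computed per respondent active under both
  generators, then averaged (a pooled-alter variant is available);
  transitivity is global clustering of the symmetrized graph; harmonic
  centrality sums inverse directed distances *to* a node with
  unreachable pairs contributing 0; isolates are counted against the
  full roster.
* Pipeline stage seeds derive from the master seed by SHA-256 of
  "master:stage" reduced mod 2³¹; every stochastic stage records its
  seed in the run manifest, and reruns are byte-identical.
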