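# Methods

## Model

The market is a bipartite graph between buyers and vendors. A tie is the
binary "has purchased from" relation — repeat purchases collapse — and
every vendor carries a cumulative sales rating ("reputation", in rating
units). Only buyers make choices; vendors are passive alters.

Network evolution is a continuous-time Markov chain. A buyer receiving a
change opportunity compares candidate states: toggling each possible tie
to a vendor (create if absent, dissolve if present) and "no change". The
candidate is drawn by multinomial logit over the linear objective
f(β, x) = Σₖ βₖ sₖ(x), computed with a max-shift so extreme coefficients
cannot overflow. The default effect statistics of the buyer's personal
network are:

* **outdegree** — number of ties; its coefficient is the per-tie cost
  (negative) or propensity to trade (positive);
* **alter_reputation** — summed rating of tied vendors (units:
  1/rating); reputation-driven attachment;
* **alter_popularity** — summed √degree of tied vendors, the
  conventional bounded-influence form of degree popularity. Evaluated on
  the candidate state, so creating a tie to v contributes √(deg(v)+1).

Effects are a registry (`EffectSet`); alternative functional forms can
be added without touching the engine. Reputations are frozen covariates
during a simulated period; attack-modified values persist. Chain length
between observations is M ~ Poisson(rate × n_buyers): nominal time is
arbitrary for this chain, only expected opportunities per buyer matter.

## Estimation

`robbins_monro_fit` solves the method-of-moments equations: choose β so
that chains simulated forward from wave 1 reproduce the observed wave-2
effect totals in expectation. Moment targets evaluate wave-2 ties with
wave-1 covariate values — the values the chains actually see; targets
computed on updated covariates would be unreachable by construction.

Simulation inside the estimator is *conditional on the observed amount
of change*: chains run until their tie Hamming distance from wave 1
reaches the observed wave1→wave2 distance (with a 50×n_buyers step
guard). This removes the rate from the moment system — in an
unconditional formulation the rate and the outdegree coefficient trade
off along a badly identified ridge and the coupled iteration is
unstable — and the rate is recovered afterwards as the mean number of
opportunities per buyer the conditional chains consumed. The closed form
at β = 0, rate = H/(n_buyers · V/(V+1)), is exposed as
`rate_moment_fit`.

The three phases follow the standard stochastic-approximation scheme:

1. **Sensitivity.** D = ∂E[S]/∂β by finite differences with common
   random numbers (n1 = 50 chains per perturbation; steps scale with the
   inverse per-buyer magnitude of each target, fd_scale = 1).
2. **Iteration.** β ← β − aₜ D⁺ (S_sim − S_obs) over n2 = 4 subphases of
   80 single-chain iterations, gains aₜ = 0.2/subphase; the estimate is
   the final subphase's average. D⁺ is a damped SVD inverse computed
   with moments in SD units and parameters on their natural scale:
   directions below 0.05·s_max are Tikhonov-damped and directions below
   0.005·s_max are cut, because along a near-null direction the exact
   Newton step is amplified simulation noise (and, when a moment is
   genuinely unreachable, even a damped step drifts forever). Steps are
   capped element-wise and iterates boxed (±20 parameter-scale units
   around the start) so noise cannot launch the chain into a saturated
   regime. D is re-estimated at the subphase midpoint.
3. **Diagnostics.** n3 = 250 chains at the estimate; t-ratios
   mean(S_sim − S_obs)/sd(S_sim), convergence when all |t| < 0.1 (the
   established convention); standard errors by the delta method
   D⁻¹ Cov(S) D⁻ᵀ with D re-estimated locally and inverted in full, so
   uncertainty along weakly identified directions is reported rather
   than hidden. A rejected fit re-enters phase 2 from the current
   estimate (one restart by default).

Weak identification is intrinsic here, not an implementation artifact:
outdegree, √degree popularity, and the rate all move total tie counts.
The honest consequence is large standard errors along the shared
direction. On reputation-reinforced synthetic data a second confound
appears: the cumulative rating is proportional to sales, so
reputation-attachment and degree-popularity are observationally
equivalent, and a three-effect fit can assign the mechanism to either
(including zeroing the reputation coefficient). The end-to-end pipeline
therefore fits the two-effect specification (outdegree + reputation,
`pipeline_effects()`), the mechanism the generator embodies; the
three-effect set remains the library default and is exactly identified
when reputations are independent of degree, which is the setting of the
parameter-recovery validation.

## Attacks and experiment

`targeted` deletes the ⌊n/100 × V⌋ highest-degree vendors (ties broken
by reputation, then id), `weak_link` the ⌊n/100 × B⌋ lowest-degree
buyers (ties by id), `signal` multiplies every reputation by 1 − n/100.
The floor rounding is a declared convention; deleted actors leave the
actor set, so post-attack isolate counts measure deterred participation
rather than the mechanical footprint of the deletion. All operators are
pure functions.

`run_experiment` runs control + 3×4 conditions, R replicates each, with
hierarchical seed derivation (master → condition → replicate), so any
condition can be re-run independently and the results table is
bit-reproducible. Default R = 30 keeps a desk run in seconds; R = 100
reproduces the full 1,300-network design. Summaries: per-replicate
proportion of the control mean; OLS of a metric on strategy indicators
plus linear level (conventional SEs, via statsmodels); Pearson
correlation of level with a metric per strategy.

## Metrics

* **Degree scaling.** Discrete power-law fit: γ maximizes the discrete
  likelihood (Hurwitz-zeta normalization) on the tail k ≥ xmin; xmin
  minimizes the KS distance between the tail empirical CDF and the
  fitted CDF, both right-continuous and compared at observed support
  points (the discrete convention — comparing at left limits, as in the
  continuous case, inflates KS by the point masses). Goodness of fit by
  semiparametric bootstrap: tail resampled from the fitted law
  (continuous inverse transform, rounded), body from the empirical data,
  full refit per resample; ks_p is the fraction of resamples with KS at
  least the observed. At least 10 positive degrees above a candidate
  cutoff are required; degenerate samples raise a typed error.
* **Assortativity.** Pearson correlation of (buyer degree, vendor
  degree) over ties. Undefined cases (constant side, < 2 ties) raise
  `UndefinedMetricError` — never silently 0, because isolate-heavy
  simulated networks would otherwise bias summaries; tabulation records
  them as missing.
* **Robustness curves.** Sequential deletion of one side in descending
  degree order, tracking residual tie fraction and buyer-isolate
  fraction; the dismantle fraction is the first removal fraction with
  zero ties. On a bipartite graph, deleting actors on one side never
  changes same-side degrees, so recomputed and initial orderings
  coincide; ids break ties for reproducibility.

## Synthetic data generator

The generator emulates the aggregate structure of a darknet drug market
whose transaction log is not public. Mechanism: n_transactions purchase
events in sequence; the buyer is drawn with log-normal activity weights
(dispersion 0.75 — enough heterogeneity to produce the observed mass of
single-purchase buyers without asserting an unprinted mechanism); the
vendor is drawn with probability ∝ base_attractiveness +
reputation_weight × current rating, then gains rating_per_sale. This is
a Pólya urn whose concentration is governed by one ratio,
base/(weight × rating_per_sale) = 1/25 at the defaults. The event log
splits at its midpoint into two cumulative waves (wave 2 ⊇ wave 1), the
minimal panel the estimator needs.

Calibration, checked over 20 seeds at the full scale of 7,126 buyers /
169 vendors / 16,847 transactions (medians): vendor degree-scaling
exponent ≈ 1.7 (band 1.2–1.9), assortativity ≈ −0.15 (band −0.25–0.05),
top-decile tie concentration ≈ 0.95 and top-decile transaction
concentration ≈ 0.69 (both ≥ 0.45). The single urn knob cannot hit all
three stylized facts at once, so the defaults sit inside all bands
rather than on any one published point. The desk scale (505 buyers, 50
vendors, 1,110 transactions) mirrors the market's early phase and is the
default for estimation and experimentation.

What the generator does **not** emulate — and what passing tests
therefore do not show about real markets:

* **No tie dissolution.** Waves are cumulative, so the wave1→wave2
  Hamming distance equals the tie growth and the fitted model is forced
  into a near-pure-growth regime (a strongly positive outdegree
  coefficient). Real market panels built from activity windows have
  buyers going inactive; a model fitted to such data has meaningful
  no-change and dissolution probabilities. Two documented consequences
  on synthetic markets: reputation (signal) attacks do not measurably
  deter tie formation (the creation logits dwarf the no-change
  candidate, so scaling reputations down changes *which* vendor is
  chosen, not *whether* one is), and the weak-link level correlates
  *positively* with assortativity (the mechanical removal of degree-1
  buyers — the (1, k) edge pairs — dominates any behavioral channel).
  Both directions are exercised as one-sided tests in the validation
  suite and fail under these study conditions; targeted-attack tie
  reduction and weak-link isolate reduction hold strongly.
* No prices, drug categories, shipping, vendor entry/exit, or
  buyer-side degree calibration (only the vendor side is calibrated).

## Numerical conventions and degenerate inputs

Deterministic tie-breaking everywhere (degree, then reputation, then
lexicographic id). All simulation seeds derive from
`numpy.random.SeedSequence` and stay below 2³¹. Logit computations are
max-shifted. Duplicate edge rows collapse with a warning on read;
negative reputations and bipartition violations are rejected at
construction. Identical panel waves give the minimal rate (10⁻³) with a
warning. Metrics undefined on a network are typed errors at the metric
level and missing values in tabulated output.

## Problem sizes

Validation runs use a 300 × 30 market for parameter recovery (20 fits),
desk scale (505 × 50) with R = 30 for the directional experiment, and 20
full-scale generator draws for calibration; the acceptance script runs
the full design at R = 100. These sizes make the whole validation cycle
reproducible on a single CPU in minutes.
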