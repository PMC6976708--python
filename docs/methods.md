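# Methods

## Generating model

Cohorts of n patients (default 1000) carry ten baseline covariates
X1..X10, i.i.d. standard normal (a Bernoulli(0.5) switch exists for binary
covariates). Treatment selection is logistic on X1..X7 and survival depends
on X4..X10, so X4..X7 confound while X1..X3 act only on selection and
X8..X10 only on outcome. Effects come from a five-step ladder of odds /
hazard ratios {1.25, 1.5, 2, 4, 8}; three fixed coefficient patterns define
the *low*, *medium* and *high* heterogeneity scenarios (weak to very strong
covariate effects on both selection and survival). Treatment is Bernoulli
on the true propensity expit(α₀ + Σ αᵥ xᵥ).

Overall survival is drawn by inverse-probability transform from a shape-2
Weibull proportional-hazards model,

    OS_z = ( −log u / (λ_w · exp(β z + Σ γᵥ xᵥ)) )^(1/2),   λ_w = 2·10⁻⁵,

with a *single* uniform u per subject evaluated at both z = 1 and z = 0
(common random numbers). The conditional hazard ratio exp(β) is 0.8 in all
scenarios, giving the exact per-subject ratio OS1/OS0 = 0.8^(−1/2) ≈ 1.118
and a strictly positive true survival gain SG = OS1 − OS0. The *true ATE*
is the mean of SG over treated subjects and the *true variance* V its
sample variance. Time is in months throughout; typical OS values are in the
hundreds of months because λ_w is calibrated to a slowly progressing
(chronic oncology-like) disease.

Censoring is an independent Bernoulli(p*) **status flag**: the recorded OS
value is left untouched and is interpreted downstream as a lower bound on
true survival. There is no censoring-time mechanism, no competing risk, and
no informative censoring.

The treatment-model intercept α₀ is calibrated to a target treated
proportion by bisection on [−30, 30] against one fixed Monte Carlo sample
of 100,000 covariate draws (reused across bisection steps), stopping when
the mean propensity is within 0.002 of the target. Calibration closure is
tested: re-simulating 100,000 subjects at the calibrated intercept recovers
the target within ±0.01.

## Propensity model

PS is estimated by plain maximum-likelihood logit (statsmodels, Newton,
100 iterations, tolerance 1e−8, no regularization) of Z on an intercept
plus X3..X10 — the covariates affecting survival, *not* those generating
treatment. This deliberate misspecification reflects the common practice of
choosing PS covariates by outcome relevance; since the confounders X4..X7
are included, the fitted score is still a valid balancing score for them.
Constant columns are absorbed into the intercept. Separation,
non-convergence and single-class treatment raise typed errors carrying the
optimizer diagnostics.

## Matching

Distance is the absolute PS difference |PS_i − PS_j| ∈ [0, 1]. Every
treated unit is matched independently, with replacement; ties in distance
break towards the smaller control identifier, making all schemes
deterministic given their seed. No caliper and no optimal matching are
offered — greedy NN is the design under study.

* **k-NN** — the k smallest distances, uniform weights 1/k; k = 1 is
  one-by-one matching.
* **Weighted k-NN** — same neighbours, weights ∝ exp(−α d); α = 5 pushes a
  maximal-distance match near zero weight while preserving contrast at
  small distances; α = 0 recovers uniform weights.
* **Complex bootstrap** — b resamples of the control group (size N^C, with
  replacement); within each, the PS model is refit on treated ∪ resampled
  controls and every treated unit is 1:1-matched to its nearest resampled
  control; the b matched original identities are pooled with weights 1/b.
  One model *form* is used for all resamples. A resample whose refit fails
  is redrawn (at most 10 times). With a single distinct control the match
  is forced, so no model is fit and distances are recorded as 0.

## Estimation and labelling

The survival-gain estimate is SG_i = OS_i^T − Σ w_ij OS_j^C. A patient is
labelled `response` when SG_i ≥ λ (threshold in months, default 3.0 — a
config parameter; ties at exactly λ count as response). Censoring makes
some labels undecidable; with censored values read as lower bounds:

* treated and all matched controls censored → `undetermined`;
* some (not all) controls censored → censored controls are dropped and the
  weights renormalized over the observed ones (without renormalization the
  control term would no longer be a weighted mean);
* all controls censored, treated observed → the computed SG is an upper
  bound, conclusive only when small: SG < λ is `non_response`, otherwise
  `undetermined`;
* treated censored → the computed SG is a lower bound, conclusive only when
  large: SG ≥ λ is `response`, otherwise `undetermined` (SG is reported as
  undefined in that case).

Zero-weight controls are transparent: dropping one changes neither the
label nor any estimate.

The STE variance in k-NN mode is Σ w² · s², with s² the unweighted sample
variance of the retained (observed, positive-weight) matched controls' OS;
it is undefined with fewer than two retained controls and whenever the
control contribution itself is unusable (the two all-censored undetermined
cases). The within-set s² is a *local* variance; the alternative — the
sample variance of the whole control group — is the `one_by_one_crude` mode
used for one-by-one matching, where a within-set variance does not exist.

One known asymmetry is inherited from the rule set: when the treated unit
is censored and SG ≥ λ, the label `response` is retained even though some
censored controls may have been dropped, which does not strictly preserve
the lower-bound direction. The condition lists are implemented as stated.

## Monte Carlo study

A scenario fixes heterogeneity, n, treated proportion, censoring rate,
method and k (or b; b defaults to k so that matched-set sizes are
comparable across schemes). Per iteration: simulate → fit PS → match →
estimate → reduce to scalar metrics:

* `mean_ste` — mean SG over treated units with a defined estimate;
* `mean_ste_var` — mean V_i over units where defined;
* `var_of_ste_var` — variance of V_i across treated units within the
  iteration (the across-iteration variance of the per-iteration mean is
  reported separately as `between_iter_var_of_mean_v`, since either reading
  of "variance of the STE variance" is defensible);
* `prop_labels_censored` — fraction of treated labels `undetermined`;
* `delta_var_rel` — (V − mean V_i)/V, the relative accuracy of the
  variance estimator against the true variance of that iteration's cohort.

Scenario summaries are means with Monte Carlo standard errors over
iterations, skipping (and counting) undefined values; an all-undefined
metric is reported missing, never zero. Seeds derive from
SeedSequence(base_seed, crc32(scenario key), iteration), so extending a
grid never changes existing cells; degenerate draws (single-class
treatment, too few controls, PS non-convergence) are redrawn from spawned
seeds and counted.

Three factor sweeps mirror the study design: treated proportion (no
censoring), censoring rate (20% treated), and k (20% treated, 20%
censored), each crossed with heterogeneity level and method, with the
non-swept factors held at 20% / 20% / k = 15. Default grids: proportion
treated {0.05, 0.1, 0.2, 0.3, 0.4, 0.5}, censoring {0, 0.1, ..., 0.5},
k {1, 2, 5, 10, 15, 25, 50}.

The default profile for tests and examples is 200 iterations of n = 1000
(about a tenth of a second per iteration for k-NN); the full study profile
is `n_iterations=1000`, a documented long mode run the same way.

## What the generator does and does not emulate

The synthetic cohorts have smooth, fully overlapping continuous covariates,
a correctly proportional hazards outcome, independent non-informative
censoring, and no missing data. Real registry cohorts add informative
censoring, discrete/missing covariates, non-proportional hazards and
unmeasured confounding — none of which are exercised here. Passing tests
therefore validate the estimators' internal consistency and their behaviour
under the stated generating model, not registry-grade robustness.

Two behaviours of the estimator under this model are worth knowing:

* **Label-censoring selection.** The rules can only rule *out* censored
  treated patients whose estimated gain is small, so with censoring the
  mean STE over labelable patients is selectively inflated (see the README
  example: 20.0 vs 31.9 months at 20% censoring).
* **Skewness and k.** OS is heavily right-skewed (log-normal-like across
  subjects), so the mean of m matched controls is median-biased low at
  small m; the probability that a censored treated patient's SG falls below
  λ — the dominant undetermined case for k ≥ 5 — *rises* slowly with k.
  The undetermined fraction therefore drops sharply from k = 1 to k = 5
  (≈ 0.20 → 0.13 at 20% censoring) and then creeps up by about a point at
  k = 15 for the k-NN schemes, rather than decreasing indefinitely. The
  bootstrap is flat in b because its pooled mean stays concentrated on the
  near-nearest controls.

## Numerical choices

* Uniform draws for the survival transform are redrawn if exactly 0 (open
  interval); u → 1 gives OS → 0.
* CSV round trips use `%.17g` formatting and round-trip float parsing, so
  tables are lossless to full double precision.
* Variances are sample variances (ddof = 1) throughout.
* Matching uses a stable argsort over controls pre-sorted by identifier,
  which implements the tie-break without a second key.
* The calibration tolerance (0.002), bisection bracket (±30) and redraw cap
  (10) are fixed constants; all scientific parameters (λ threshold, α, k,
  b, grids, censoring and treated proportions) are configuration.
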