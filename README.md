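# survgain

Subject-specific treatment effects from observational survival data, by
nearest-neighbour propensity-score matching — with a censoring-aware binary
response label and a Monte Carlo study comparing matching schemes.

## The problem

Cancer registries record overall survival (OS) but no longitudinal response
measurements, so patient-level response to a treatment has to be read off
survival itself. For each treated patient *i*, match one or more untreated
patients with a similar propensity score PS = Pr(Z=1 | X) and estimate the
*survival gain*

```
SG_i = OS_i^T − Σ_{j ∈ C(i)} w_ij OS_j^C ,
V_i  = Σ_{j ∈ C(i)} w_ij² · var(OS^C)_{C(i)} ,
```

where C(i) is the matched control set and the weights w sum to one. The
patient is labelled a *responder* when SG_i ≥ λ months (λ is a clinical
threshold, 3 months by default). Because survival times are right-censored —
a censored OS is only a lower bound — the label is sometimes undecidable:
e.g. a censored control with SG ≥ λ could still outlive the treated patient.
The package implements the full decision table (drop censored controls and
renormalize; flag undecidable combinations as `undetermined`).

Four matching schemes are provided, all with replacement:

| scheme | C(i) | weights |
|---|---|---|
| one-by-one | single nearest control | 1 |
| k-NN | k nearest controls | 1/k |
| weighted k-NN | k nearest controls | ∝ exp(−α·\|PS_i − PS_j\|), α = 5 |
| complex bootstrap | nearest control in each of b control-group resamples, PS refit per resample | 1/b |

A synthetic data-generating process (1000 patients, 10 standard-normal
covariates, logistic treatment selection at three heterogeneity levels,
Weibull survival via OS = (−log u / (λ_w e^LP))^½ with λ_w = 2·10⁻⁵ and a
conditional hazard ratio of 0.8) carries both potential outcomes per
subject, so the true per-patient survival gain, the true ATE and the true
variance are known and every estimator can be scored against them.

## Worked example

```python
import survgain as sg
from survgain.experiment import run_scenario

cfg = sg.ScenarioConfig(heterogeneity="low", prop_treated=0.2, p_censor=0.2,
                        method="knn", k_or_b=15, n_iterations=50, base_seed=7)
summary, _ = run_scenario(cfg)
```

Each iteration simulates a fresh cohort, fits the PS model (logit of Z on
X3–X10), matches, estimates, and reduces to scalar metrics; `summary`
averages them. With no censoring versus 20% censoring (low heterogeneity):

```
p_censor=0.0: true ATE 19.8 | mean STE 20.0 +/- 1.4 | delta_var/V -2.26 | undetermined 0.0%
p_censor=0.2: true ATE 20.1 | mean STE 31.9 +/- 1.4 | delta_var/V -3.56 | undetermined 10.5%
```

Without censoring, k-NN matching recovers the true mean survival gain of
the treated (20.0 vs 19.8 months). With 20% censoring, 10.5% of labels are
undecidable, and — because the rules can only exclude censored treated
patients whose estimated gain is *small* — the mean over the remaining
labelable patients is selectively inflated (31.9 months). `delta_var/V` is
the relative difference between the true variance of the survival gain and
the mean estimated STE variance; negative values mean the within-matched-set
estimator overstates the between-patient variance. Quantifying these effects
across schemes, censoring rates, treated proportions and k is exactly what
the Monte Carlo study is for.

The same pipeline is scriptable from the shell:

```
survgain simulate --heterogeneity low --n 1000 --prop-treated 0.2 --p-censor 0.2 --seed 7 --out cohort.csv
survgain estimate cohort.csv --method knn --k 15 --threshold 3 --out estimates.csv
survgain experiment --config config.yaml --out-dir results/
survgain report --results results/results.csv --out-dir results/
```

`estimate` also accepts any real cohort CSV with columns
`id, z, os_months, censored, x1..x10` (censoring flag: 1 = censored).

## Layout

```
src/survgain/dgp.py         synthetic cohorts with known truth
src/survgain/propensity.py  ML logistic PS estimation
src/survgain/matching.py    k-NN / weighted / bootstrap matched sets
src/survgain/estimation.py  SG, variance, censoring-aware labels
src/survgain/experiment.py  Monte Carlo driver and factor sweeps
src/survgain/cli.py         command-line interface
docs/methods.md             model, assumptions, design choices
```
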