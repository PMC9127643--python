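# Methods

This note documents the measurement model, the scoring rules and their edge
cases, the synthetic-cohort generator, and the numerical conventions the
package commits to where more than one defensible choice existed.

## Instruments and scoring rules

**Switching task (SGST).** A session holds 49 scorable trials: 10
normal-baseline ("go on green"-type single rule), 10 reverse-baseline
(inverted rule), and a 29-trial mixed block split into 23 nonswitch and 6
switch trials (the rule changed on the previous trial). Each condition is
scored as the **median response time in seconds**; medians are used instead
of means to damp stray slow responses, so no additional latency trimming is
applied. Accuracy is the fraction correct over all 49 trials. Sessions
below **70% accuracy are not scored**: the items are easy enough that low
accuracy signals careless responding, which also makes the latencies
invalid. The gate is inclusive (≥ 0.70, so 35/49 passes and 34/49 fails).
Medians are computed **over correct trials only** by default — an incorrect
response's latency does not measure the intended process, and the 70% gate
bounds the trial loss at 30% — but `include_incorrect_trials=True`
reproduces the literal "all trials of a type" reading. A condition with no
correct trials in an otherwise scored session has no defined median and is
reported as missing. The sample median of an even count is the mean of the
two central order statistics.

**Figure identification.** All 60 items are administered untimed; speed
pressure is reintroduced at scoring time:

1. *Outlier removal.* Trials slower than 30 s are removed outright and count
   toward nothing — neither elapsed time, nor credit, nor the accuracy
   denominator. The comparison is strict and done in milliseconds
   (> 30 000 ms), so exactly 30.000 s is retained.
2. *Posterior time limit.* Within each 30-item set — defined by administered
   position 1–30 / 31–60, fixed **before** outlier removal, since the
   administered blocks are randomized per respondent — retained latencies
   are accumulated in order, and a figure scores iff it is correct and its
   cumulative time through its own response is ≤ 90.000 s (inclusive:
   "within 90 seconds"). The primary score is the sum over both sets (0–60).
3. *Secondary measures* deliberately ignore the time limit so that speed and
   accuracy can be examined separately: percent incorrect and the median RT
   of accurate figures use **all** non-outlier figures.
4. The 70% validity gate uses accuracy over non-outlier figures (42/60
   passes, 41/60 fails). A session whose figures are all outliers is
   unscorable and flagged.

A 120-second set limit is available as a parameter (scores under a longer
limit are never smaller — the package asserts this as an invariant) but is
not a supported primary output, because electronic responding is fast enough
that the longer limit produces ceiling effects.

**Block balancing.** Items are assigned to 6 administration blocks from
pilot item statistics (median and IQR of item RTs as difficulty and
discrimination proxies): items are ranked by median, each consecutive
rank-group of 6 is randomly permuted across blocks (one item per stratum per
block), the randomization is repeated 500 times, and the most balanced
assignment is kept. "Most balanced" is operationalized as the sum of two
unit-free terms: the across-block variance of the block median of item
medians, scaled by the across-item variance of medians, plus the
across-block variance of the block IQR of item medians, scaled by the
across-item variance of the pilot IQRs (raw variance if that scale is
zero). Ties go to the earliest iteration, which also makes the degenerate
all-items-identical case return iteration 1 with objective 0. The precise
objective is a package convention; any dispersion-of-block-summaries
objective would serve the same purpose.

## Comparison statistics

* **Cohen d** from summary statistics with the (n−1)-weighted pooled SD and
  a normal-approximation CI, SE² = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)). The
  keyboard group is the reference, so d > 0 means larger values on touch
  screens.
* **Cohen q** = atanh(r₁) − atanh(r₂) with r₁ the keyboard-group age
  correlation. The sign convention matters and is fixed package-wide.
* **OLS** distraction regressions (each score on the eight binary
  environment fields plus age) use statsmodels with conventional SEs,
  complete cases, and t-based two-sided p-values. Binary distractors with no
  variation in the sample (e.g. nobody reported playing a game) are dropped
  before fitting rather than crashing on a singular design; truly collinear
  predictors raise an error naming the column. No multiplicity adjustment is
  applied (α = .05, unadjusted, matching standard practice for these
  descriptive tables).
* **Partial correlations** are correlations of OLS residuals after
  projecting out the controls (with intercept).
* **Weighted norms**: x̄_w = Σwx/Σw per age group (18-34, 35-44, 45-54,
  55-64, 65-74, ≥75), CI = x̄_w ± 1.96·SE with the linearization form
  SE² = Σw²(x−x̄_w)²/(Σw)². With unit weights this reduces exactly to the
  unweighted mean and the large-sample CI with the ML (ddof=0) variance;
  that identity is tested to 1e−12. Groups of size 1 report a mean with no
  CI. The CI method is a package convention — survey software offers several
  variants and the choice is documented rather than asserted as canonical.
* **Within-person comparison** (both-device owners): mean difference
  (touch − keyboard), paired d = mean/SD of differences (undefined and
  flagged when the SD is 0), and the cross-device Pearson correlation.
  Primary analyses use each respondent's first session only; the paired
  analysis is an optional flag because the both-device subsample is smaller
  and self-selected.

## Synthetic cohort generator

The generator emulates the study conditions the analysis machinery assumes;
its defaults are the package's fixed reference conditions, not tuning knobs.

Latency model: log RT = baseline + β_age·(age−50) + δ_device·1[touch] +
δ_interrupt·1[interrupted] + u_person + ε, u ~ N(0, σ_p²), ε ~ N(0, σ_t²).
Lognormal latencies give the right skew and make age/device effects
multiplicative, which is the natural scale for RT data; age is centered at
50 years (≈ the panel mean) so baselines are interpretable mid-panel.

| parameter | default | rationale |
|---|---|---|
| β_age | 0.006 /yr | ≈0.6%/yr slowing; yields age correlations ≈0.3–0.5 |
| δ_device | 0.05 | ≈5% slower on touch; d ≈ 0.1–0.2 on median scores |
| δ_interrupt | 0.08 | ≈8% slowing per interrupted session |
| condition baselines | log(1.0/1.1/0.95/1.5) s | switching-cost ordering; medians ≈ published magnitudes |
| item baselines | log-linear, 3→7 s | figure-item latencies ≈3.5–6.5 s; count scores ≈30–48 by age |
| σ_person / σ_trial | 0.25 / 0.20 | cross-device score correlations land in the published 0.37–0.83 range |
| p_correct attentive / careless | 0.97 / 0.55 | careless fail the 70% gate with analytic probability 0.9861 (49 trials) / 0.9873 (60) |
| careless fraction | 0.05 | small contaminating subpopulation; latencies also shrunk to 0.6× (rushing) |
| p_outlier | 0.002 | rare >30 s walk-aways on the figure test (drawn Uniform(30, 60) s) |
| interruption / at-home / TV / music / talking / texting / internet / gaming | .125 / .896 / .15 / .085 / .07 / .007 / .007 / .0015 | survey-like distraction prevalences |

Interruption is drawn per session and applied to all its trials; the
instruments measure distraction per session, so per-trial distraction is out
of scope. Weights are two-way inverse-inclusion weights (age band ×
education: the cohort over-samples older and college-educated strata
relative to nominal population shares), normalized to mean 1 — the simplest
structure under which weighted and unweighted norms genuinely differ.

Reproducibility: one global seed feeds a named substream per respondent
(`SeedSequence(seed, spawn_key=(i,))`), so growing a cohort never changes
earlier respondents, and identical configs reproduce byte-identical files.

What the generator does **not** emulate — so what passing tests do not show
about real data: device ownership is drawn independently of demographics
(real touch-only respondents are younger and less educated, confounding
device with age); items affect only mean log-latency (no
person-by-item interaction, no learning or fatigue across trials);
environment fields are mutually independent and independent of age;
correctness is exchangeable across trials rather than clustered late in the
session; and latencies are exactly lognormal with homogeneous within-person
variance. Parameter-recovery results here demonstrate that the estimators
are consistent under the stated model, not that the model captures every
feature of panel data.

## Problem sizes and numerical conventions

Simulation-based tests use cohorts of 1 000–5 000 respondents and
brute-force oracles of ≥10⁶ trials (device-effect recovery) or ≥10⁴ random
sessions (exact scoring-oracle equivalence); these sizes make Monte-Carlo
standard errors small relative to the 3·SE acceptance bands while keeping a
full test run in a few minutes. Latencies are stored in integer-or-real
milliseconds and converted to seconds exactly once, inside scoring; the
outlier cut compares milliseconds to avoid float-second rounding ambiguity.
Stochastic assertions use 3-standard-error bands throughout (binomial SEs
for rates, Fisher-z SEs for correlations, the d SE above for effect sizes).

Known limitations: the published nonswitch device d (0.13) cannot be
recovered from the published rounded means and SDs (they imply 0.15); the
package reproduces the other effect-size rows to two decimals and documents
this one as input-rounding loss. Published norm tables require the original
panel microdata and are not reproduction targets; the package reproduces
their *direction* (latencies rise, figure counts fall across age groups) on
synthetic cohorts.
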