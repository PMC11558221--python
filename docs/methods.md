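# Methods

## The measurement

A smartphone keyboard replacement records keypress metadata only: a UTC
timestamp, the device's IANA timezone, and a coarse key category
(alphanumeric, backspace, autocorrection, punctuation, autosuggestion,
special). A typing session starts at the first keypress and ends when the
keyboard is dismissed or after 6 seconds of inactivity; a gap of exactly
6 s therefore stays within a session (`segment_sessions` splits strictly
on gap > 6 s). The daily backspace rate for subject *i* on local calendar
day *j* is

    y_ij = (# backspace keypresses that day) / (# keypresses that day),

with backspaces counted in the denominator and day boundaries at local
midnight in the recorded timezone (typing is diurnal, so UTC bucketing
would split evenings for western-hemisphere users). Days below a
configurable minimum keypress count (default 1) are omitted rather than
emitted as 0/0. Whether autocorrection and autosuggestion events should
count as "keypresses" is not observable from the data definition; the
default denominator includes all six categories and
`aggregate_daily(include_categories=...)` restricts it.

## The mixture model

Subject *i* contributes n_i daily rates y_ij ∈ (0, 1). A latent phenotype
z_i ∈ {1..K} lives at the **subject** level; given z_i = k the days are
iid

    y_ij | z_i = k  ~  N(mu_k, sigma^2) truncated to (0, 1),

with one shared sigma across components (the study design this package
reproduces reports a single SD) and weights pi on the simplex. Mixing at
the subject level is the substantively right unit — individuals, not
days, are classified — and ~2,900 daily observations nested in 128
subjects would otherwise be treated as independent. A
`subject_level=False` switch turns on observation-level mixing for
sensitivity analysis.

Priors are noninformative conjugate: mu_k ~ N(0.5, 10) restricted to
(0, 1), sigma^2 ~ InvGamma(0.001, 0.001), pi ~ Dirichlet(1). Inference is
Gibbs sampling with, by default, 5,000 burn-in iterations and 2 chains of
10,000 kept iterations:

* z_i | rest: categorical with log-probabilities log pi_k +
  sum_j log f(y_ij | mu_k, sigma), computed from per-subject sufficient
  statistics (n_i, sum y, sum y^2) so each sweep is O(subjects x K)
  regardless of the number of days;
* mu_k | rest and sigma^2 | rest: the truncation normalizer
  Z(mu, sigma) = Phi((1-mu)/sigma) - Phi(-mu/sigma) breaks conjugacy, so
  both updates are Metropolis-within-Gibbs with the *untruncated*
  conjugate full conditional (normal resp. inverse-gamma) as an
  independence proposal; the acceptance ratio reduces to a ratio of
  truncation normalizers raised to the class observation counts.
  mu proposals outside (0, 1) are rejected (that is the truncated prior).
  With `truncation_correction=False` the updates are pure Gibbs;
* pi | rest: Dirichlet(1 + subject counts per class).

**Initialization matters for the truncated sampler.** An independence
proposal cannot escape a state whose importance weight Z(current)^-n is
astronomically larger than the proposal region's, so sigma^2 must start
near the data scale. It is initialized from the pooled *within-subject*
variance, which estimates the component variance consistently for any K;
component means start at the (k+0.5)/K quantiles of the subject means
with a small per-chain jitter. Rates exactly on {0, 1} are clamped to
(1e-6, 1 - 1e-6) with a warning.

Label switching is resolved after sampling by sorting components by mean
within every draw (weights permuted alongside, z remapped). Convergence
is monitored by split-R-hat on the relabeled means, weights and sigma;
fits above 1.05 warn. Model fit uses the deviance information criterion
on the observed-data (z-marginalized) likelihood,

    DIC = Dbar + pD,  pD = Dbar − D(theta_bar),  D(theta) = −2 log L(y|theta),

where theta_bar is the posterior mean of the relabeled draws. DIC is
negative here: densities of rates on (0, 1) exceed 1. Draws with a
non-finite deviance are excluded with a warning.

## Choosing K

`select_model` combines internal fit with external validity: a candidate
K is excluded if any *modal* class holds fewer than 5 subjects (too small
to interpret) or if the Pearson chi-square between modal class and
mood-disorder diagnosis (HC / unipolar / bipolar) is not significant at
alpha = 0.05. Among survivors the lowest DIC wins; DIC differences within
2 are treated as ties and the smaller K is chosen (parsimony). Hard modal
assignments build the contingency table because the selection logic
reasons about integer subjects per class; all-zero rows or columns (an
empty class) are dropped with a warning, no continuity correction is
applied.

## Phenotype scores

For a single observed rate, the score of class k is by default the plain
normal density f(rate | mu_k, sigma) — no mixture weight, no truncation
normalizer — and normalized scores divide by the sum. This is the
practitioner-facing rule: with the fitted parameters (means
0.112/0.180/0.268, SD 0.048) a rate of 0.14 scores (7.01, 5.87, 0.24),
normalized (0.53, 0.45, 0.02), label Low. `use_weights=True` multiplies
by pi (after which normalization is exactly the Bayes posterior over
classes for one observation) and `use_truncation=True` divides by the
(0,1) normalizer; both default off so the default reproduces the rule
above. Cohort subjects with multi-day data are instead assigned by MCMC
posterior class probabilities (modal label, ties to the lower class);
for K = 3 the classes ordered by mean are named Low / Medium / High.

## Association models

* **Group test**: rate ~ group with a subject random intercept
  (statsmodels MixedLM), fitted by ML (`reml=True` optional), Wald test
  on the group term; a degenerate random-intercept fit falls back to OLS
  with cluster-robust SEs and is flagged.
* **Depression severity**: OLS of HAM-D totals on phenotype (Low
  reference), optionally adjusting for medication (yes = 1) and
  diagnosis; collinear columns are dropped with a warning.
* **Mania severity**: the YMRS total is zero-inflated, so a two-part
  hurdle model is used: logistic regression for P(total > 0) and a gamma
  GLM with log link on the positive totals. A gamma density has no atom
  at zero, so the "zero-inflated" and hurdle likelihoods coincide and
  the total log likelihood decomposes exactly into the two parts
  (`hurdle_log_likelihood` verifies this). If the logistic MLE fails to
  converge because a small group is perfectly predicted
  (quasi-separation), the Wald estimates are reported with a
  non-convergence note — the inflated SE carries the information
  honestly. YMRS totals are treated as continuous in the gamma part.
* **Symptom items**: proportional-odds (cumulative-logit) regression per
  item, parameterized so positive coefficients mean higher odds of
  higher ratings; reported as OR with exp(b ± 1.96 SE) CIs. Structural
  zeros — a phenotype group whose members all share one category of an
  item — make that group's contrast inestimable: the model is marked
  non-convergent, the group dropped, the model refitted on the remaining
  groups, and a note recorded. An item constant in everyone yields a
  descriptive note only.

Inference is Wald throughout (z statistics, 1.96 intervals), matching
the reporting style of the tables this mirrors. No multiple-testing
correction is applied across items by default; `symptom_item_models`
offers Benjamini-Hochberg adjusted p-values as an opt-in column.

## The synthetic cohort generator

`generate_cohort` emulates the study conditions: 128 subjects (27 HC, 87
unipolar, 14 bipolar), ~23 observation days each (Poisson, so ~2,948
subject-days), medication prevalence 22.2% (HC) / 59.4% (MD), daily
rates from the truncated-normal mixture at the fitted parameters, and
clinical outcomes from configurable effect truths. Latent classes are by
default allocated *exactly* according to the observed class-by-diagnosis
composition (HC 13/14/0, bipolar 7/4/3, unipolar 27/54/6 across
Low/Medium/High), shuffled within diagnosis: the realized contingency
table — the quantity the external-validity test consumes — is then the
study's own, rather than a multinomial draw around it that adds ~4
percentage points of noise to the Medium weight.
`class_assignment="sampled"` gives the probabilistic variant.

Outcome truths and their defaults:

| truth | default | why |
|---|---|---|
| depression intercept / residual SD | 5.5 / 4.0 HAM-D points | overall mean ~6.2, matching the cohort's descriptives |
| b_Medium / b_High (depression) | 2.32 / 1.0 | reported effect; High reported non-significant |
| hurdle logit intercept, b_Medium, b_High | −1.1, 0.5, 1.91 | ~25% nonzero YMRS in Low; Medium reported n.s.; High reported effect |
| gamma log intercept, b_Medium, b_High, shape | log 1.8, 0.79, 1.46, 1.5 | positive-part means ~1.8/4.0/7.8 |
| item truths | log of each reported OR | per-item cumulative-logit shifts |

Item thresholds give mild-symptom marginals in the Low group (~75-85%
zeros), and the items that failed to converge in the source analysis are
generated as structural zeros (e.g. guilt, suicide and weight loss are
identically 0 in High; hypochondriasis in Low; three YMRS items in
everyone), so the drop-and-refit protocol is exercised end to end.

Daily rates are realized as integer backspace/keypress counts
(keypresses log-normal around ~400/day, clipped to [60, 3000]; backspace
count = rate x keypresses rounded and clipped into [1, n−1]), so
`aggregate_daily(generate_keystroke_events(daily))` reproduces the daily
table exactly; the rounding perturbs rates by < 1/60 of a keypress.
Generated event streams use integer-second gaps of 1–2 s within sessions
and 30–300 s between sessions, starting 08:00 local, so they stay inside
one local calendar day.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: circadian and weekday usage structure,
missing-not-at-random adherence, within-subject autocorrelation of daily
rates, diagnosis-conditional severity (outcomes depend on phenotype
only), and additive consistency between generated severity *totals* and
generated *items* — totals come from the linear/hurdle truths and items
from the proportional-odds truths, two marginal models that do not sum.
`read_clinical` always recomputes totals from items, so analyses of
external files are internally consistent; analyses of generated cohorts
use the totals the truths produced. The within-class SD (0.048) together
with the class means implies an overall daily SD of ~0.066, slightly
above the reported overall 0.062; the generator follows the class
parameters.

Severity totals are floored at 0 and rounded to integers (HAM-D). The
floor censors ~8% of Low-group draws and attenuates the recovered
Medium-vs-Low coefficient by ~0.1 points — well inside the 2-SE band
(per-cohort SE ~0.73) the recovery checks use.

## Problem sizes and numerical choices

The default MCMC budget (5,000 burn-in, 2 x 10,000 kept) is used for the
single headline K = 3 fit; the per-subject sufficient-statistics sweep
makes this a ~6 s computation at cohort scale. Replicated studies use
deliberately smaller budgets chosen so posterior summaries are already
stable: model-selection replicates run 1 chain with 600 burn-in / 1,500
kept iterations per K, and the LMM null-calibration study uses 40
subjects x 6 days x 50 replicates. Truncated-normal variates come from
scipy's truncnorm; truncation normalizers are floored at 1e-300 before
logs; mixture likelihoods use log-sum-exp; categorical draws use the
Gumbel-max trick so a fixed seed gives bit-identical chains; DIC
deviances are evaluated in draw chunks of 2,000 to bound memory. Exact
score ties classify to the lower (smaller-mean) class everywhere.
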