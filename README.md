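# keyphen

Digital phenotyping of smartphone keyboard **backspace rates** for mood
disorder research. Passive keystroke metadata (timestamps and key
categories, never content) yields one number per person per day — the
fraction of keypresses that were backspaces, y_ij ∈ (0, 1) — and this
package turns those daily rates into discrete behavioral phenotypes and
links them to clinical symptoms.

The core model is a K-component, equal-variance Gaussian mixture bounded
to the unit interval, with the latent class at the subject level:

    y_ij | z_i = k  ~  N(μ_k, σ²) truncated to (0, 1),    z_i ~ Categorical(π)

fitted by Gibbs sampling (noninformative conjugate priors; 5,000 burn-in
iterations, then 2 chains × 10,000; Metropolis-within-Gibbs corrections
for the truncation). K is chosen by combining the deviance information
criterion (DIC = D̄ + p_D) and a minimum-class-size rule with an
external-validity χ² test of modal class against diagnosis
(HC / unipolar / bipolar). For K = 3 the classes ordered by mean are the
Low / Medium / High backspace-rate phenotypes; a single observed rate is
scored against each class by its normal density f(rate | μ_k, σ).
Downstream models relate phenotypes to clinical outcomes: a
random-intercept linear mixed model for the group contrast on daily
rates, OLS for depression severity (HAM-D), a hurdle gamma model
(logistic × log-link gamma) for zero-inflated mania totals (YMRS), and
proportional-odds regressions per symptom item with a drop-and-refit
protocol for structural zeros.

Because raw keystroke exports cannot be redistributed, the package ships
a synthetic-cohort generator that emulates the study conditions (128
subjects, ~23 days each, the fitted mixture parameters, the
class-by-diagnosis composition, and the reported effect sizes as
generating truths), so the entire pipeline is testable end to end.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
import keyphen as kp

# a synthetic cohort at the study conditions
daily, clinical, truth = kp.generate_cohort(seed=7)   # 2957 subject-days

# fit the 3-class bounded mixture
fit = kp.fit_mixture(daily, 3, config=kp.MCMCConfig(n_burn=1000, n_iter=3000,
                                                    n_chains=2, seed=7))
print("means  :", np.round(fit.params.means, 3))    # [0.112 0.18  0.276]
print("sigma  :", round(fit.params.sigma, 3))       # 0.049
print("weights:", np.round(fit.params.weights, 3))  # [0.367 0.557 0.076]
print("DIC    :", round(fit.dic, 1))                # -9312.4
```

The posterior means recover the generating parameters (μ =
0.112/0.180/0.268, σ = 0.048): about 37% of subjects type with low
backspace rates, 56% medium, 8% high. Model selection against diagnosis
picks K = 3:

```python
diag = truth["subjects"].set_index("subject_id")["diagnosis"]
fits = [kp.fit_mixture(daily, k, config=kp.MCMCConfig(n_burn=600, n_iter=1500,
                                                      n_chains=1, seed=7))
        for k in (2, 3, 4)]
kp.select_model(fits, diag).chosen_k                # 3
```

A practitioner can score a single observed rate against the fitted
classes — e.g. someone typing with a 14% backspace rate:

```python
a = kp.class_density_scores(0.14, fit.params)
a.unnormalized.round(2)   # [6.87 5.83 0.18]  (7.01 5.87 0.24 at the exact params)
a.normalized.round(2)     # [0.53 0.45 0.01]
a.label                   # 'Low'
```

i.e. the rate is about as likely under the Low as under the Medium class
and essentially impossible under High — a graded classification rather
than a hard cutoff. Finally, phenotypes predict symptoms; the Medium
group scores about 2 HAM-D points above Low (generating truth 2.32):

```python
res = kp.severity_regression(clinical, truth["subjects"]["label"])
print(res.table.round(3).to_string(index=False))
# part   term  estimate    se      z     p
#       const     5.553 0.525 10.577 0.000
#      Medium     1.822 0.675  2.699 0.007
#        High     1.558 1.310  1.190 0.234
```

A thin CLI mirrors the library: `keyphen simulate`, `keyphen aggregate`
(events → daily rates), `keyphen fit-mixture`, `keyphen select`,
`keyphen classify`, and `keyphen associate`.

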