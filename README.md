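# relapse-frailty

Bayesian analysis of **recurrent relapse gap times** with an
**event-dependent Weibull gamma-frailty model**, built around the setting of
chronic schizophrenia: patients are repeatedly re-hospitalized, the at-risk
interval ("gap time", in weeks) runs from each discharge to the next
admission, and the last interval may be right-censored at the end of
follow-up.  The package is aimed at biostatisticians who want a tested,
reproducible implementation of this model — likelihoods, sampler,
synthetic-cohort generator, and simulation-based parameter-recovery tooling
— rather than a one-off WinBUGS script.

## The model

Subject *i* carries fixed covariates *x<sub>i</sub>* (age at disease onset in
years plus five indicators: male gender, single marital status, gradual mode
of onset, head injury, family history) and a latent frailty
ν<sub>i</sub> ~ Gamma(1/θ, 1/θ) (mean 1, variance θ).  The conditional
hazard of the *k*-th gap is

```
h_ik(t) = ν_i · α^(k−1) · exp(β₀ + x_i′β) · γ · t^(γ−1)
```

* **γ** — Weibull shape; γ < 1 means the relapse hazard declines within each
  gap.
* **α** — event dependence; each prior relapse multiplies the hazard by α.
* **β** — covariate log-hazard ratios (proportional hazards).
* **θ** — frailty variance; quantifies heterogeneity between patients and
  induces Kendall's τ = θ/(θ+2) between gap times of the same patient.

The gamma frailty integrates out in closed form, giving the marginal
per-subject likelihood used both as an oracle and inside the sampler.
Estimation is Metropolis-within-Gibbs: a jointly-adapted random-walk block
for (β₀, β, log γ, log α) against the frailty-marginalized likelihood,
conjugate gamma Gibbs draws for the frailties, and a Metropolis step for
log θ.  Priors are vague and proper: β ~ N(0, 1000), log γ, log α ~ N(0,
100), θ ~ Inverse-Gamma(0.01, 0.01).

Because no patient-level data are deposited for this setting, the package
ships a **synthetic-cohort generator** whose defaults emulate the study
cohort (159 subjects; 84.28% male; onset age 21.52 ± 6.84 truncated to
10–43; 19.59% married; 53.46% sudden onset; 47.8% head injury; 6.29% family
history) and whose default generating parameters are the analysis' reported
posterior means, so the whole pipeline is exercised by parameter recovery.

## Worked example

```python
import relapse_frailty as rf

ds = rf.simulate_cohort(seed=1)          # 159 subjects, default truth
print(ds.n_subjects, len(ds))            # 159 795
draws = rf.run_mcmc(ds, config=rf.MCMCConfig(seed=2))
print(rf.summarize(draws))
```

```
                     mean    sd  ci_2.5%  ci_97.5%  null  significant
parameter
beta.age_onset      0.088 0.009    0.069     0.107 0.000         True
beta.gender         0.465 0.190    0.085     0.834 0.000         True
beta.marital        0.677 0.138    0.414     0.961 0.000         True
beta.mode_onset     0.228 0.110    0.012     0.445 0.000         True
beta.head_injury    0.303 0.103    0.112     0.513 0.000         True
beta.family_history 0.623 0.280    0.092     1.176 0.000         True
gamma               0.862 0.028    0.809     0.921 1.000         True
alpha               2.812 0.120    2.593     3.059 1.000         True
theta               0.192 0.046    0.110     0.291 0.000         True
```

The cohort was generated with γ = 0.860, α = 2.785, θ = 0.206 and
β = (0.072, 0.418, 0.710, 0.199, 0.285, 0.327); every posterior mean above
lands within its 95% credible interval of the generating value.  A
parameter is flagged *significant* when its equal-tailed 95% interval
excludes the null (0 for β and θ, 1 for γ and α); intervals are unadjusted
across covariates.  `rf.diagnostics(draws)` reports split-R̂ and effective
sample sizes.

The same pipeline is available from the shell:

```bash
relapse-frailty simulate --seed 1 --out out/
relapse-frailty fit --data out/dataset.csv --seed 2 --out out/
relapse-frailty describe --data out/dataset.csv --out out/
relapse-frailty recover --seed 1 --n-seeds 5 --out out/
```

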