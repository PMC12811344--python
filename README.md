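# intervalcure

Mixture cure models for **mixed-case interval-censored** time-to-event
data, with an SVM-based incidence component.

In longitudinal follow-up studies the event time is often known only to
lie between two examination visits, the number of visits varies by
subject, and a fraction of the population will never experience the event
at all ("cured"). The population survival function is then the improper
mixture

    S_p(t | x, z) = 1 − π(z) + π(z) · S(t | x),

where `π(z)` is the uncured probability given incidence covariates `z` and
`S(t | x) = S0(t)^{exp(x'β)}` is a proportional-hazards latency for the
uncured over a nonparametric (Turnbull) baseline `S0`. Classical practice
models `π(z)` with logistic regression, which presumes a linear boundary
between cured and uncured subjects — an assumption that cannot be checked,
because cured status is unobserved for every right-censored subject. This
package instead classifies cured vs uncured with a soft-margin RBF-kernel
SVM and converts decision values to probabilities by Platt scaling
(`π(z) = 1/(1 + exp(A g(z) + B))`), so nonlinear cure boundaries are
captured. Estimation is by an EM-type algorithm: the E-step computes each
right-censored subject's posterior uncured probability, the incidence
M-step multiply-imputes the missing cured statuses (M = 5 draws, one
SVM + Platt fit per draw, averaged), and the latency M-step maximizes the
weighted interval-censored log-likelihood by Nelder-Mead over the frozen
Turnbull baseline. A logistic-incidence comparator shares all other
machinery, and bootstrap resampling supplies standard errors.

The package is aimed at biostatisticians analyzing panel-examination data
with a cured subgroup (e.g. time to onset of grade-IV venous gas emboli in
NASA's hypobaric decompression sickness study, which motivates the
real-data workflow here) and at methodologists who want a tested
simulation bench for cure models under mixed-case interval censoring.

## Worked example

```python
import numpy as np
import intervalcure as ic

rng = np.random.default_rng(42)
spec = ic.scenario_spec(2)                   # nonlinear cure boundary
data, truth = ic.generate_dataset(spec, 300, rng)

fit = ic.fit_mcm_svm(data, ic.EMConfig(max_iter=10, seed=42),
                     np.random.default_rng(42))

err = fit.pi_hat - truth.pi_true
print("beta_hat:", np.round(fit.beta_hat, 3))
print("pi bias:", round(err.mean(), 4), " mse:", round((err**2).mean(), 4))
print("AUC vs true cure labels:", round(ic.roc_auc(fit.pi_hat, truth.J_true), 4))

roc = ic.simulated_label_roc(fit, data, n_draws=500,
                             rng=np.random.default_rng(1))
print("simulated-label AUC:", round(roc["auc"], 4))
```

Output:

```
beta_hat: [-2.695  2.396]
pi bias: -0.0465  mse: 0.0478
AUC vs true cure labels: 0.7477
simulated-label AUC: 0.8734
```

`fit.pi_hat` holds the per-subject uncured probabilities averaged over the
five imputations; the bias/MSE lines compare them with the generating
truth (the SVM incidence tracks the interaction surface that a logistic
model cannot — swap in `ic.fit_mcm_logit` to see its AUC collapse to ~0.5
on this scenario). The first AUC scores `pi_hat` against the true cure
labels kept by the generator; the second is the 500-draw simulation-based
AUC that remains computable when, as in real data, cure labels are
unknown. `fit.beta_hat` is the latency coefficient vector over the frozen
Turnbull baseline; see `docs/methods.md` for why these are attenuated
relative to the generating values under this baseline convention, and
`fit.trace` / `fit.converged` for the EM diagnostics.

A command-line interface wraps the same functions:

```bash
intervalcure simulate --scenario 2 --n 300 --seed 7 --out d.csv --truth t.csv
intervalcure fit --model svm --data d.csv --seed 7 --out fit.json
intervalcure evaluate --data d.csv --truth t.csv --fit fit.json --out metrics.csv
intervalcure reproduce --scenario 2 --n 300 --reps 50 --seed 7 --out study/
intervalcure hdsd-workflow --seed 7 --out workflow.json
```

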