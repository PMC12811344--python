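# Methods

## Model

`intervalcure` fits a two-component mixture cure model to mixed-case
interval-censored time-to-event data. Each subject is observed only through
a censoring interval `(U_L, U_R]` produced by a random number of
examination visits, with `U_L = 0` (left censoring) and `U_R = ∞` (right
censoring) as special cases; the indicators are `δ1 = I(U_L = 0)` and
`δ2 = I(U_L > 0, U_R < ∞)`. The population survival function is improper:

    S_p(t | x, z) = 1 − π(z) + π(z) · S(t | x),

where `π(z)` is the probability of being uncured (susceptible) given
incidence covariates `z`, and `S(t | x) = S0(t)^{exp(x'β)}` is a Cox
proportional-hazards latency for the uncured given covariates `x`, over a
nonparametric baseline `S0`. A subject's cured status `J` (1 = uncured) is
observed for left- and interval-censored subjects and missing for
right-censored ones; this missingness is what the EM algorithm integrates
out.

## Incidence: SVM with Platt scaling

Instead of a parametric link, `π(z)` is obtained from a soft-margin SVM
with radial-basis kernel `K(z_i, z_j) = exp(−γ‖z_i − z_j‖²)`, trained on
cured/uncured labels `V ∈ {−1, +1}` by solving the dual program

    max_c  −½ Σ_ij c_i c_j V_i V_j K(z_i, z_j) + Σ_i c_i
    s.t.   Σ_i c_i V_i = 0,  0 ≤ c_i ≤ Q,

giving the decision value `g(z) = Σ_i c_i V_i K(z_i, z) − b`. The dual is
solved by scikit-learn's libsvm backend (an SMO decomposition); the fitted
rule exposes the dual coefficients, support labels and intercept, and its
optimum is verified in the test suite against a dense SLSQP solve of the
same program. The intercept is the solver's margin-support-vector average
of the KKT relation `b = Σ c_i V_i K(z_i, z_j) − V_j`.

Margins become probabilities through Platt scaling:
`π(z) = 1 / (1 + exp(A g(z) + B))`, with `(A, B)` maximizing the smoothed
Bernoulli likelihood whose targets shrink the labels to
`(n1+1)/(n1+2)` (uncured) and `1/(n0+2)` (cured). The two-parameter
objective is concave; it is maximized by damped Newton iteration from
Platt's recommended start `A = −1`, `B = log((n0+1)/(n1+1))`, to gradient
norm 1e−8 (at most 100 iterations, step halving on any decrease). The
sigmoid is fitted on in-sample decision values within each EM imputation:
the shrunken targets are the overfitting guard, and holding out data inside
every imputation would starve the fit.

Hyperparameters `(γ, Q)` are chosen once, at initialization, by grid search
over `γ ∈ {2⁻⁶, 2⁻⁵, 2⁻⁴}` and `Q ∈ {2⁴, 2⁵, 2⁶}` (defaults), minimizing
the stratified 10-fold cross-validated misclassification rate on the
δ-based labels; ties break toward smaller `Q`, then smaller `γ`. A
data-driven alternative grid `{γ0 · 2^k, k = −3..3}` with
`γ0 = 1 / median‖z_i − z_j‖²` is available (`gamma_grid=None`). Re-tuning
at every EM iteration is exposed as a switch (`retune_every_iter`, default
off) but is computationally wasteful: one tuning per fit matches how the
hyperparameters are used. When the minority class is smaller than the fold
count, folds shrink to the minority size (two minimum) so stratified folds
always contain both classes.

## Baseline: Turnbull NPMLE, frozen

`S0` is the Turnbull nonparametric MLE computed once from all subjects'
intervals and held fixed across EM iterations. Equivalence classes are the
classic maximal intersections — `(a, b]` with `a` an observed left
endpoint, `b` an observed finite right endpoint, and no observed endpoint
interior to `(a, b)` — plus a tail class `(max endpoint, ∞)` carrying the
residual mass whenever right-censored subjects exist. Masses are fitted by
the self-consistency (EM) iteration to tolerance 1e−6 (max 10000
iterations; the baseline is computed once, so this is cheap), and the fit
is cross-checked in the tests against both a direct simplex maximization of
the Turnbull likelihood and lifelines' NPMLE routine. Within-class
placement is undefined by the NPMLE; evaluation puts each class's mass at
its right endpoint, giving a right-continuous non-increasing step function
with `S0(0) = 1`. Inside likelihoods, `S0` values are clipped to
`[1e−12, 1]` before logs and powers.

Freezing an *unadjusted* all-subject Turnbull curve as `S0` is a
deliberate, documented contract, and it has a visible consequence: the
curve estimates the population survival (plateau ≈ the cure fraction), not
the uncured baseline, so latency coefficients are attenuated relative to
the generating values and their bootstrap spread is wide (the latency
likelihood flattens when the baseline plateaus). The package reproduces
survival-probability behavior (small overall-survival bias, a positive
susceptible-survival bias of roughly +0.08 on the linear scenario) exactly
as expected under this convention. A cure- or covariate-adjusted baseline
(re-estimated inside EM) would remove the attenuation but is out of scope
here.

## Estimation: EM with multiple imputation

* **E-step.** For right-censored subjects,
  `w_i = π(z_i) S0(U_Li)^{exp(x_i'β)} / (1 − π(z_i) + π(z_i)
  S0(U_Li)^{exp(x_i'β)})`; left/interval-censored subjects have `w_i = 1`.
* **Incidence M-step.** `M = 5` imputations (default): cured statuses of
  right-censored subjects are drawn from Bernoulli(`w_i`), an SVM + Platt
  model is fitted per draw, and the `M` probability vectors are averaged.
  A draw yielding a single class is redrawn (bounded) and finally repaired
  by flipping the right-censored subject with weight nearest ½; if there
  are no right-censored subjects at all, the constant shrunken-target
  probability `(n+1)/(n+2)` is used.
* **Latency M-step.** `β` maximizes the weighted complete-data latency
  log-likelihood (left/interval terms plus `w_i e^{x'β} log S0(U_Li)` for
  right-censored subjects) by Nelder-Mead from the current iterate, with
  one restart and an ascent guarantee; non-positive interval masses return
  a large negative sentinel rather than raising, so the simplex can back
  away. A flat objective (unidentified `β`, e.g. all intervals in one
  Turnbull class) returns the starting point with a warning.
* **Initialization.** `π⁰` from one SVM + Platt fit on the δ-based labels
  (right-censored ⇒ cured); `β⁰` from the no-cure latency fit (all weights
  one) started at the origin.
* **Stopping.** Squared L2 distance between successive concatenated
  parameter vectors (per-subject π plus β) below `ε = 1e−3` (default), or
  `max_iter`. The criterion is applied unnormalized, as defined; because π
  has length n, a normalized variant is exposed (`normalize_criterion`).
  The convergence check uses the imputation-averaged π. Because the
  incidence M-step is stochastic (fresh imputations each iteration), the
  criterion need not reach ε on every dataset; results report
  `converged` honestly and the trace records the observed log-likelihood
  and criterion per iteration. For the SVM variant the M-step is not a
  likelihood maximizer, so observed-likelihood monotonicity is *not*
  asserted; the logistic comparator (exact Newton incidence M-step) is
  monotone to 1e−8 and the tests enforce that.

Standard errors for `β` come from a nonparametric bootstrap (B = 100
default): resample subjects with replacement, refit, take the sample SD
across successful refits; more than 20% failures is an error.

## Logistic comparator

`fit_mcm_logit` swaps the incidence M-step for an exact damped-Newton
maximization of the weighted Bernoulli likelihood with a logistic
`π(z) = expit(b0 + z'b)` (at most 50 Newton steps, gradient tolerance
1e−10, ridge 1e−6 fallback on separation). Everything else — baseline,
E-step, latency M-step, stopping — is shared, which makes the two models
directly comparable.

## Synthetic data

The generator follows a four-step recipe: draw a uniform cure threshold
(cured with probability `1 − π(z)`); draw uncured event times from a
Weibull with shape `α` and scale `exp(x'β)^{−1/α}` (so
`S(t|x) = exp(−e^{x'β} t^α)`), via inverse-CDF sampling; accumulate
examination gaps `ξ ~ Uniform(0.1, 0.25)` until the schedule passes
`min(t, 2.5)`; classify as left- (`t ≤ 0.1`), interval-, or right-censored
(`t > 2.5`). An event inside the very first gap leaves `U_{j−1} = 0`; such
subjects are recorded as left-censored, by the definition `δ1 = I(U_L=0)`.
Four scenarios define the true incidence surface: (1) a steep logistic in
two standard-normal covariates (linear boundary, truth `α=1, β=(−5,5)`);
(2) the same logistic with a `5z₁z₂ − 3z₁z₂` interaction, implemented
literally (net `2z₁z₂`); (3–4) an identical complementary-log-log-style
surface in ten covariates (truth `α=0.2`,
`β=(−0.8,1.5,0.5,1.3,−0.6,−1.4,−0.5,−0.8,0.5,1.8)`), with scenario 3 using
correlated `N₁₀(0, Σ)`, `Σ_ij = 0.7^{|i−j|}`, and scenario 4 mixing
Bernoulli(0.5, 0.3, 0.5, 0.7) and standard-normal covariates. In scenario
4 all ten covariates enter the latency but the models see only
`(z₁,…,z₅)` as incidence covariates, while the *true* π is evaluated on
all ten as the formula is written. Consequences worth knowing: the
long-run class proportions implied by these formulas are (cured,
right-censored) ≈ (0.480, 0.662), (0.446, 0.665), (0.429, 0.685), (0.604,
0.716) for scenarios 1–4 (quadrature / large-sample Monte Carlo), and in
scenario 4 most of the incidence signal lives in covariates the models
cannot see, so every model's cure-prediction AUC sits near chance there.

The HDSD-like fixture is a synthetic stand-in for NASA's hypobaric
decompression sickness study (238 subjects; Age, Sex, TR360, NOADYN): the
printed summary moments are used as parameters of truncated-normal /
Bernoulli samplers, the incidence is a nonlinear age-by-sex interaction
logistic calibrated once to ≈71% right censoring, and the latency is a
unit-shape Weibull on standardized covariates. It reproduces data *shape*
(moments, censoring share, imbalance) for workflow tests, not any real
result. Truncation shifts the sampled Age/TR360 means slightly away from
the nominal parameters; tests allow for this.

What the generator does not emulate: covariate-dependent examination
schedules, measurement error, informative censoring, or ties in
examination times — so passing tests demonstrate correctness of the
estimation machinery under the stated design, not robustness to those
real-data features.

## Evaluation

Bias and MSE are per-replication subject means, averaged across
replications. AUC uses the rank statistic (ties count ½) and is checked
exhaustively against the pairwise definition. When true cure labels are
unknown, the simulation-based ROC draws cured statuses of right-censored
subjects from their posterior weights, repeats (500 draws by default),
averages AUC, and vertically averages ROC curves on a 101-point
false-positive-rate grid. Survival-probability errors compare fitted
overall (`S_p`) and susceptible (`S`) curves against the generating truth
at each subject's last finite examination endpoint (`U_L` for
right-censored, `U_R` otherwise) — the only times the data identify; a
fixed grid can be supplied instead. Minority-class oversampling duplicates
minority subjects (by the δ-based class) with replacement until classes
balance, preserving all originals.

## Study sizes and numerical defaults

Monte-Carlo studies run at n = 300 with 50 replications for scenarios 1–2
and 30 for the heavier ten-covariate scenarios, EM capped at 10 iterations
in the experiments module (well past where the criterion trace flattens),
two-thirds/one-third stratified train/test splits, M = 5, B = 100. These
are the package's reproduction sizes; the library defaults
(`EMConfig.max_iter = 50`, ε = 1e−3) are set for single-dataset analyses.
All randomness flows from one seed per run through named child streams, so
identical inputs give bit-identical results.

## Known limitations

* The frozen population-level Turnbull baseline attenuates latency
  coefficients and inflates their bootstrap spread (see Baseline above);
  incidence estimates and survival-probability summaries are unaffected.
* Scenario 4's hidden-covariate design caps achievable AUC near chance.
* The criterion's dependence on the stochastic π update means `converged`
  may stay false at tight ε; the trace should be inspected.
* No truncation, exact event times, time-varying covariates, competing
  risks, or baselines other than the frozen Turnbull step function.
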