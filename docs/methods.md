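# Methods

`thetagrow` analyses replicated clonal population-growth experiments of the
kind used in resurrection ecology: many small populations, each founded by a
single *Daphnia* neonate, censused repeatedly as they grow toward carrying
capacity, with clones sourced from two contrasting periods (before and after
a predator invasion). This note records the models, the generative
assumptions of the synthetic-data module, the numerical choices, and the
places where the design was genuinely open.

## Models

### Growth rates

For a census interval of length `d` days the daily growth rate is
`G = ln(N_{t+1}/N_t)/d`, computed for counts ("numerical") or total dry
biomass (mg). The observed intrinsic growth rate of a population is
`r = ln(N_2/N_0)/d` using only the founding abundance and the second
census; because every population starts from one individual, this window
is spent at low density and pins `r` down directly. Fixing `r` per
population this way avoids the well-known likelihood ridge of the
theta-logistic model, in which flat combinations of `r` and `theta` fit
equally well. `d` is always taken from the actual census dates, so
irregular schedules (the design supports one delayed census) are handled
without assumptions.

Intervals that touch a zero abundance are dropped — the log ratio is
undefined, and extinction is treated as a descriptive outcome, not part of
the growth model. Populations extinct before the second census have no
observed `r` and are excluded from both analyses.

### Linear mixed model for r

`r_ij = mu + beta * pre_i + a_i + e_ij`, with clone random intercept
`a_i ~ N(0, sigma_clone^2)` and residual `e_ij ~ N(0, sigma_resid^2)`;
the null candidate drops `beta`. Estimation is delegated to
`statsmodels.MixedLM`. The ML log-likelihood feeds AICc; REML estimates are
reported. Parameter counts: 4 (full) and 3 (null).

### Theta-logistic nonlinear mixed-effects model

For intervals after the first two censuses,

    G_cpj = r_cp (1 - (N_cpj / K_cp)^theta_g) + e_cpj,
    log K_cp = log K_g + b_c + b_cp,

with `r_cp` the *observed* intrinsic rate of that population entering as a
known offset, `b_c ~ N(0, sigma_clone^2)` and `b_cp ~ N(0, sigma_pop^2)`
nested random effects on log K, and Gaussian residuals on G. `K_g` and/or
`theta_g` may depend on invasion history, giving four candidates with
k = 7, 6, 6, 5 estimated parameters.

The marginal likelihood integrates the random effects out by a Laplace
approximation. Random effects are independent across clones, so the
integral factors into per-clone blocks of dimension 1 + (number of
populations). Within a block the joint negative log-density is minimized
by damped Newton with analytic gradient and Hessian (the Hessian has an
arrow structure but is small enough to treat densely); the approximation
adds half the log-determinant of that Hessian at the mode. Zero variance
components drop their dimension exactly, so with both SDs at zero the
marginal likelihood reduces to plain Gaussian nonlinear regression — this
limit, and agreement with brute-force quadrature on one- and
two-random-effect instances (within 1e-4), are enforced by tests.

Fixed effects and variance components are estimated by quasi-Newton
(L-BFGS-B) on the Laplace marginal likelihood, with `K`, `theta` and all
SDs on the log scale. Initial values are data-driven: `K` at the 90th
percentile of observed densities, `theta = 1`, `sigma_resid` at the SD of
G, and the random-effect SDs at fractions of it. `fit_nlme` defaults to 5
multi-starts (jittered inits, ties broken by best log-likelihood then
smallest parameter norm); the candidate-set sweep instead warm-starts each
richer model from the solutions of the models nested in it, which both
speeds the sweep up and guarantees that fitted log-likelihoods respect
nesting up to optimizer tolerance.

Standard errors come from the inverse numerical Hessian of the negative
marginal log-likelihood, delta-method-transformed to the natural scale
(intercept = reference "post" group; the other group reported as a
difference). p-values are Wald with a normal reference — the appropriate
degrees-of-freedom correction for a nonlinear mixed model is not
well-defined, and at ~1,000 observations the normal reference is adequate.

REML-style estimates (reported for the best candidate, as variance
components are biased low under ML) maximize the Laplace likelihood with
fixed effects profiled out, penalized by half the log-determinant of the
fixed-effect information. ML is always used for AICc: models differing in
fixed effects are not comparable under a restricted likelihood.

### Model selection

`AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)` with `n` the number of
likelihood contributions (growth observations for the NLME, populations
for the LMM) and `k` counting fixed effects plus variance components.
Akaike weights are `exp(-Delta_i/2)` normalized over the candidate set;
exact ties break toward fewer parameters. The percentage contrast between
groups is `100 (post/(post + diff) - 1)` on the natural scale.

## Synthetic data

The generator inverts the fitted model: between censuses,
`N_{t+1} = N_t exp(d [r_pop (1 - (N_t/K_pop)^theta) + eps])` with one
`eps ~ N(0, sigma_resid)` per interval, clone effects on `r` and on
`log K`, and population effects on `log K` (the log scale keeps K positive;
additive effects on K itself could not). With demographic stochasticity on,
each census draws `Poisson(expected N)` and zero is absorbing. Biomass is
count times a lognormally fluctuating mean individual mass (default CV 0.3,
a typical spread for *Daphnia* dry mass across changing stage structure).

Defaults state the emulated experiment: 8 pre- and 11 post-invasion clones,
10 populations per clone (190 total), founded with 1 individual, censused
10 times every 8 days from day 11; group parameters r = 0.16/0.13 per day,
K = 50.88/39.99 individuals, theta = 0.38; SDs 0.0033 (clone on log K),
0.0011 (population on log K), 0.04 (clone on r), 0.0763 (residual G).
The default mean individual mass, 2.76/50.88 ≈ 0.054 mg, makes the biomass
carrying capacity consistent with the numerical one.

What the generator does *not* emulate: replacement of neonates dying in
the first week (the emulated experiment replaced them before the analysed
series began), video-based abundance estimation error, food or medium
dynamics, and any within-interval dynamics (growth noise is drawn once per
interval, exactly as the fitted model assumes).

Two realism switches matter for interpretation:

* **Demographic stochasticity** (default on) produces integer counts,
  early extinctions at realistic rates, and — because the same noisy count
  enters the growth rate and the density covariate — a mild
  errors-in-variables attenuation of fitted K (a few percent at the
  default design). The real experiment shares this mechanism.
* **Observed-r offsets.** With `theta < 1` density dependence already
  bites at a handful of individuals, so `r` observed over the first two
  censuses underestimates the latent intrinsic rate by roughly a third at
  the default parameters, and NLME estimates conditioned on observed r
  inherit part of that attenuation. This is a property of the *design*
  (shared with the emulated experiment), not of the estimators. The
  parameter-recovery tests therefore run the generator in its model-exact
  configuration — continuous abundances, latent per-population r supplied
  as the offset — which isolates the estimators from the design effects; a
  green recovery test establishes that the estimators recover the
  likelihood they fit, not that the two-stage design is free of
  attenuation.

## Numerical choices

* Inner Newton: convergence when the predicted quadratic decrease falls
  below `1e-11 (1 + |objective|)`; Levenberg ridge on factorization
  failure; Armijo backtracking. Modes are cached and warm-started across
  outer iterations.
* Outer L-BFGS-B: finite-difference step 1e-6 (the inner solves are
  accurate enough for forward differences at this step), `ftol` 1e-10,
  log-SD bounds [-9, 3]; estimates at the lower bound are flagged as
  boundary fits rather than errors (noise-free data legitimately collapse
  all variance components).
* Exponents of the power (N/K)^theta are clipped at |60| in log space to
  avoid overflow during optimization excursions.
* A candidate that fails to converge is excluded from the comparison with
  a warning instead of aborting the sweep.
* AICc ties closer than 1e-9 resolve toward the smaller k.

## Known limitations

* The Laplace approximation is evaluated, not exact; its error is
  negligible at the default design (variance components are small and the
  per-block curvature is dominated by dozens of observations) and is
  checked against quadrature only on small instances.
* The REML-type criterion for the nonlinear model is one of several
  reasonable definitions; different software disagrees here, which is why
  all model comparison uses ML.
* Wald p-values near variance boundaries are approximate.
* The generator's biomass layer scales the count trajectory; it does not
  model size-structure dynamics, so biomass analyses of synthetic data
  share the numerical K/theta up to the mass factor.
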