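import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from thetagrow import (
    NLMESpec,
    StudyDesign,
    ThetaLogisticParams,
    fit_candidate_set,
    fit_nlme,
    growth_table,
    nlme_marginal_loglik,
    simulate_study,
)
from thetagrow.design import SimulationParams


def _tiny_instance(rng, *, n_pops=2, n_obs=3, K=50.0, theta=0.5, sd_e=0.05,
                   b_clone=0.06):
    """One clone, a few populations, observations on the growth curve with
    a known clone-level log-K shift."""
    rows, r_rows = [], []
    for pi in range(n_pops):
        r_pop = 0.15 + 0.02 * pi
        for N in np.linspace(10.0, 45.0, n_obs):
            mu = r_pop * (1.0 - (N / (K * np.exp(b_clone))) ** theta)
            rows.append({"clone_id": "c1", "group": "post",
                         "population_id": f"p{pi}", "day_start": 1.0, "d": 8.0,
                         "N_start": N, "G": mu + rng.normal(0.0, sd_e),
                         "measure": "numerical"})
        r_rows.append({"clone_id": "c1", "group": "post",
                       "population_id": f"p{pi}", "r": r_pop})
    return pd.DataFrame(rows), pd.DataFrame(r_rows)


def test_k_accounting():
    ks = [s.k for s in (NLMESpec(k_by_group=True, theta_by_group=True),
                        NLMESpec(k_by_group=True, theta_by_group=False),
                        NLMESpec(k_by_group=False, theta_by_group=True),
                        NLMESpec(k_by_group=False, theta_by_group=False))]
    assert ks == [7, 6, 6, 5]


def test_no_random_effects_is_plain_regression(rng):
    """sigma_clone = sigma_pop = 0 reduces the marginal likelihood to the
    Gaussian nonlinear-regression log-likelihood."""
    g, rt = _tiny_instance(rng)
    K, theta, sd_e = 50.0, 0.5, 0.05
    ll = nlme_marginal_loglik(
        NLMESpec(k_by_group=False, theta_by_group=False), g, rt,
        dict(K=K, theta=theta, sigma_clone=0.0, sigma_pop=0.0, sigma_resid=sd_e))
    r = rt.set_index("population_id").loc[g["population_id"], "r"].to_numpy()
    mu = r * (1.0 - (g["N_start"].to_numpy() / K) ** theta)
    direct = norm.logpdf(g["G"].to_numpy(), mu, sd_e).sum()
    assert ll == pytest.approx(direct, abs=1e-10)


def test_laplace_matches_quadrature_single_effect(rng):
    """1 clone, 2 populations, sigma_pop = 0: Laplace vs adaptive
    quadrature over the single clone effect, to 1e-4."""
    g, rt = _tiny_instance(rng)
    K, theta, sd_e, sd_c = 50.0, 0.5, 0.05, 0.08
    ll = nlme_marginal_loglik(
        NLMESpec(k_by_group=False, theta_by_group=False), g, rt,
        dict(K=K, theta=theta, sigma_clone=sd_c, sigma_pop=0.0, sigma_resid=sd_e))
    y = g["G"].to_numpy()
    N = g["N_start"].to_numpy()
    r = rt.set_index("population_id").loc[g["population_id"], "r"].to_numpy()

    def dens(b):
        mu = r * (1.0 - (N / (K * np.exp(b))) ** theta)
        return np.exp(norm.logpdf(y, mu, sd_e).sum()) * norm.pdf(b, 0.0, sd_c)

    val, _ = quad(dens, -10 * sd_c, 10 * sd_c, limit=200)
    assert ll == pytest.approx(np.log(val), abs=1e-4)


def test_laplace_matches_quadrature_two_effects(rng):
    """1 clone, 1 population, both SDs positive: the clone and population
    effects enter only through their sum, so the 2-D integral reduces
    exactly to a 1-D integral over N(0, sd_c^2 + sd_p^2) — an independent
    oracle for the 2-random-effect Laplace value."""
    g, rt = _tiny_instance(rng, n_pops=1, n_obs=5)
    K, theta, sd_e, sd_c, sd_p = 50.0, 0.5, 0.05, 0.08, 0.05
    ll = nlme_marginal_loglik(
        NLMESpec(k_by_group=False, theta_by_group=False), g, rt,
        dict(K=K, theta=theta, sigma_clone=sd_c, sigma_pop=sd_p, sigma_resid=sd_e))
    y = g["G"].to_numpy()
    N = g["N_start"].to_numpy()
    r = float(rt["r"].iloc[0])
    sd_s = float(np.hypot(sd_c, sd_p))

    def dens(s):
        mu = r * (1.0 - (N / (K * np.exp(s))) ** theta)
        return np.exp(norm.logpdf(y, mu, sd_e).sum()) * norm.pdf(s, 0.0, sd_s)

    val, _ = quad(dens, -10 * sd_s, 10 * sd_s, limit=200)
    assert ll == pytest.approx(np.log(val), abs=1e-4)


def test_loglik_stationary_at_fitted_optimum(small_study):
    """Perturbing sigma_resid away from its MLE lowers the marginal
    log-likelihood."""
    census, truth = small_study
    g = growth_table(census, skip_through_census=2)
    spec = NLMESpec(k_by_group=True, theta_by_group=False)
    fit = fit_nlme(spec, g, truth, n_starts=1, reml=False)
    groups = {"post", "pre"}
    params = dict(
        K={gr: fit.effect("K post-invasion (intercept)").estimate for gr in groups},
        theta=fit.effect("theta").estimate,
        sigma_clone=fit.random_sd["clone"],
        sigma_pop=fit.random_sd["population_in_clone"],
        sigma_resid=fit.random_sd["residual"],
    )
    params["K"]["pre"] = (fit.effect("K post-invasion (intercept)").estimate
                          + fit.effect("K pre-invasion (difference)").estimate)
    ll_hat = nlme_marginal_loglik(spec, g, truth, params)
    assert ll_hat == pytest.approx(fit.loglik_ml, abs=1e-4)
    for factor in (0.8, 1.25):
        perturbed = dict(params, sigma_resid=params["sigma_resid"] * factor)
        assert nlme_marginal_loglik(spec, g, truth, perturbed) < ll_hat


def test_noise_free_fit_matches_grid_oracle():
    """Noise-free data lie exactly on the generating curve; the fitted
    (K, theta) must coincide with the zero of the residual sum of squares,
    confirmed by an independent grid search."""
    design = StudyDesign(groups=("g",), clones_per_group={"g": 3},
                         populations_per_clone=2,
                         census_days=tuple(11 + 8 * i for i in range(6)))
    K_true, theta_true = 30.0, 0.8
    params = SimulationParams(
        group_params={"g": ThetaLogisticParams(r=0.2, K=K_true, theta=theta_true)},
        demographic_stochasticity=False,
    )
    census, truth = simulate_study(design, params, seed=1, return_truth=True)
    g = growth_table(census, skip_through_census=0)
    fit = fit_nlme(NLMESpec(k_by_group=False, theta_by_group=False), g, truth,
                   n_starts=1, reml=False)
    K_hat = fit.effect("K g-invasion (intercept)").estimate
    theta_hat = fit.effect("theta").estimate

    N = g["N_start"].to_numpy()
    y = g["G"].to_numpy()
    r = truth.set_index(["clone_id", "population_id"]).loc[
        list(zip(g["clone_id"], g["population_id"])), "r"].to_numpy()
    Ks = np.linspace(0.5 * K_true, 1.5 * K_true, 121)
    thetas = np.linspace(0.2, 2.0, 121)
    ssr = np.array([
        [np.sum((y - r * (1 - (N / K) ** th)) ** 2) for th in thetas] for K in Ks
    ])
    iK, ith = np.unravel_index(ssr.argmin(), ssr.shape)
    assert Ks[iK] == pytest.approx(K_true, abs=Ks[1] - Ks[0])
    assert thetas[ith] == pytest.approx(theta_true, abs=thetas[1] - thetas[0])
    assert K_hat == pytest.approx(K_true, rel=1e-3)
    assert theta_hat == pytest.approx(theta_true, rel=1e-3)
    assert fit.boundary  # all variance components collapse on noise-free data


def test_common_spec_invariant_to_group_labels(small_study):
    """With no group effects the fit must not depend on which populations
    carry which label."""
    census, truth = small_study
    g = growth_table(census, skip_through_census=2)
    swap = {"pre": "post", "post": "pre"}
    g2 = g.assign(group=g["group"].map(swap))
    truth2 = truth.assign(group=truth["group"].map(swap))
    spec = NLMESpec(k_by_group=False, theta_by_group=False)
    f1 = fit_nlme(spec, g, truth, n_starts=1, reml=False)
    f2 = fit_nlme(spec, g2, truth2, n_starts=1, reml=False)
    assert f1.loglik_ml == pytest.approx(f2.loglik_ml, abs=1e-6)


def test_nesting_monotonicity(small_study):
    """Richer candidates never score a lower ML log-likelihood than models
    nested within them."""
    census, truth = small_study
    g = growth_table(census, skip_through_census=2)
    fits = {f.label: f.loglik_ml for f in fit_candidate_set(g, truth, n_starts=1)}
    full = fits["K and theta ~ invasion history"]
    k_only = fits["K ~ invasion history, theta ~ 1"]
    t_only = fits["K ~ 1, theta ~ invasion history"]
    null = fits["K and theta ~ 1"]
    tol = 1e-4
    assert full >= k_only - tol and full >= t_only - tol
    assert k_only >= null - tol and t_only >= null - tol


def test_scale_equivariance(small_study):
    """Multiplying all densities by c multiplies K by c and leaves theta
    and sigma_resid unchanged."""
    census, truth = small_study
    g = growth_table(census, skip_through_census=2)
    c = 3.7
    g2 = g.assign(N_start=g["N_start"] * c)
    spec = NLMESpec(k_by_group=True, theta_by_group=False)
    f1 = fit_nlme(spec, g, truth, n_starts=1, reml=False)
    f2 = fit_nlme(spec, g2, truth, n_starts=1, reml=False)
    K1 = f1.effect("K post-invasion (intercept)").estimate
    K2 = f2.effect("K post-invasion (intercept)").estimate
    assert K2 == pytest.approx(c * K1, rel=1e-3)
    assert f2.effect("theta").estimate == pytest.approx(
        f1.effect("theta").estimate, rel=1e-3)
    assert f2.random_sd["residual"] == pytest.approx(
        f1.random_sd["residual"], rel=1e-3)


def test_populations_without_r_are_excluded(small_study):
    census, truth = small_study
    g = growth_table(census, skip_through_census=2)
    truth_missing = truth.iloc[1:]  # drop one population's offset
    spec = NLMESpec(k_by_group=False, theta_by_group=False)
    full = fit_nlme(spec, g, truth, n_starts=1, reml=False)
    red = fit_nlme(spec, g, truth_missing, n_starts=1, reml=False)
    assert red.extra["n_excluded_pops"] == 1
    assert red.n < full.n


def test_group_effect_requires_both_groups(rng):
    g, rt = _tiny_instance(rng)
    with pytest.raises(ValueError):
        fit_nlme(NLMESpec(k_by_group=True, theta_by_group=False), g, rt)
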