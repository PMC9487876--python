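"""Stochastic census-table generator.

The generator is the exact inverse of the model the estimators fit: between
consecutive censuses a population's abundance follows

    N_{t+1} = N_t * exp(d * [ r_pop * (1 - (N_t / K_pop)**theta) + eps ])

with ``eps ~ Normal(0, sigma_resid)`` drawn once per interval, ``r_pop``
the group r plus a clone effect, and ``K_pop`` the group K scaled by
``exp(clone effect + population effect)`` so the two nested random effects
act additively on log K. With demographic stochasticity on, the realized
count at each census is Poisson(expected N) and zero is absorbing —
extinct populations stay extinct. Biomass is count times a lognormally
fluctuating mean individual mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SimulationParams, StudyDesign
from .growth import CENSUS_COLUMNS, CensusSeries
from .theta import ThetaLogisticParams, theta_logistic_growth

__all__ = ["simulate_population", "simulate_study"]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _biomass_factors(rng, cv: float, mean_mass: float, n: int) -> np.ndarray:
    """Per-census lognormal individual mass with mean ``mean_mass``, CV ``cv``."""
    if cv == 0:
        return np.full(n, mean_mass)
    s2 = np.log1p(cv**2)
    return mean_mass * rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)


def simulate_population(
    params: ThetaLogisticParams,
    design: StudyDesign,
    seed,
    *,
    sigma_resid: float = 0.0,
    demographic_stochasticity: bool = True,
    biomass_cv: float = 0.0,
    clone_id: str = "c00",
    group: str = "post",
    population_id: str = "p00",
) -> CensusSeries:
    """Simulate one population's census series under theta-logistic
    expected dynamics.

    ``params`` are the population-level (r, K, theta) — any clone or
    population random effects are already folded in by the caller.
    ``seed`` is an int or a ``numpy.random.Generator``.
    """
    rng = _as_rng(seed)
    days = np.concatenate([[0.0], np.asarray(design.census_days, dtype=float)])
    n_steps = len(days) - 1
    counts = np.empty(len(days))
    counts[0] = float(design.initial_abundance)
    n = counts[0]
    eps = rng.normal(0.0, sigma_resid, size=n_steps) if sigma_resid > 0 else np.zeros(n_steps)
    for i in range(n_steps):
        if n <= 0:
            counts[i + 1] = 0.0  # extinction is absorbing
            continue
        d = days[i + 1] - days[i]
        g = theta_logistic_growth(params, n) + eps[i]
        expected = n * np.exp(d * g)
        n = float(rng.poisson(expected)) if demographic_stochasticity else expected
        counts[i + 1] = n
    mass = _biomass_factors(rng, biomass_cv, design.mean_individual_mass, len(days))
    return CensusSeries(
        clone_id=clone_id,
        group=group,
        population_id=population_id,
        days=tuple(days),
        counts=tuple(counts),
        biomass=tuple(counts * mass),
    )


def simulate_study(design: StudyDesign, params: SimulationParams, seed,
                   return_truth: bool = False):
    """Simulate a full study: one census series per population.

    Clone random effects (on log K and on r) are shared by all of a clone's
    populations; each population adds its own log-K effect. Deterministic
    given ``seed``. Returns a census table (one row per population x census,
    day 0 included) with columns ``clone_id, group, population_id, day,
    count, biomass_mg``; with ``return_truth`` also a frame of the latent
    per-population parameters (``r``, ``K``, ``theta``) actually used —
    handy for parameter-recovery studies.
    """
    if set(params.group_params) != set(design.groups):
        raise ValueError("params.group_params must cover exactly the design groups")
    rng = _as_rng(seed)
    frames = []
    truth_rows = []
    for group in design.groups:
        gp = params.group_params[group]
        for ci in range(design.clones_per_group[group]):
            clone_id = f"{group}-c{ci + 1:02d}"
            b_k_clone = rng.normal(0.0, params.sigma_clone) if params.sigma_clone else 0.0
            b_r_clone = rng.normal(0.0, params.sigma_r_clone) if params.sigma_r_clone else 0.0
            for pi in range(design.populations_per_clone):
                b_k_pop = rng.normal(0.0, params.sigma_pop) if params.sigma_pop else 0.0
                pop_params = ThetaLogisticParams(
                    r=gp.r + b_r_clone,
                    K=gp.K * np.exp(b_k_clone + b_k_pop),
                    theta=gp.theta,
                )
                series = simulate_population(
                    pop_params,
                    design,
                    rng,
                    sigma_resid=params.sigma_resid,
                    demographic_stochasticity=params.demographic_stochasticity,
                    biomass_cv=params.biomass_cv,
                    clone_id=clone_id,
                    group=group,
                    population_id=f"p{pi + 1:02d}",
                )
                frames.append(series.to_frame())
                truth_rows.append(
                    {
                        "clone_id": clone_id,
                        "group": group,
                        "population_id": f"p{pi + 1:02d}",
                        "r": pop_params.r,
                        "K": pop_params.K,
                        "theta": pop_params.theta,
                    }
                )
    census = pd.concat(frames, ignore_index=True)[CENSUS_COLUMNS]
    if return_truth:
        return census, pd.DataFrame(truth_rows)
    return census
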