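"""Linear mixed model for per-population observed intrinsic growth rates.

The model is ``r_ij = mu + beta * 1[group_i = pre] + a_i + e_ij`` with a
clone random intercept ``a_i ~ N(0, sigma_clone^2)`` and residual
``e_ij ~ N(0, sigma_resid^2)``; the null candidate drops the group fixed
effect. Estimation is delegated to ``statsmodels`` MixedLM; the marginal ML
log-likelihood feeds AICc comparison, while REML estimates are used for
parameter reporting.

Parameter counts: full model k = 4 (intercept, group difference, two
variance components), null model k = 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .results import FixedEffect, ModelFit

__all__ = ["LMMSpec", "fit_lmm_r"]

_DEGENERATE_VAR = 1e-14


@dataclass(frozen=True)
class LMMSpec:
    """Candidate structure for the r analysis.

    ``by_group`` toggles the invasion-history fixed effect;
    ``reference`` names the group coded as the intercept (the other group
    enters as a difference).
    """

    measure: str = "numerical"
    by_group: bool = True
    reference: str = "post"

    @property
    def label(self) -> str:
        return "r ~ invasion history" if self.by_group else "r ~ 1"

    @property
    def k(self) -> int:
        return (2 if self.by_group else 1) + 2


def _as_frame(estimates) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        df = estimates.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "clone_id": e.clone_id,
                    "group": e.group,
                    "population_id": e.population_id,
                    "r": np.nan if e.r is None else e.r,
                }
                for e in estimates
            ]
        )
    df = df.dropna(subset=["r"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable r estimates")
    return df


def _degenerate_fit(df: pd.DataFrame, spec: LMMSpec, names: list[str],
                    exog: np.ndarray) -> ModelFit:
    # all residual variation is zero: fixed effects are the exact group
    # means, both variance components collapse to the boundary
    beta, *_ = np.linalg.lstsq(exog, df["r"].to_numpy(), rcond=None)
    fes = [FixedEffect(name=nm, estimate=float(b), se=0.0,
                       p=None if i == 0 else 0.0)
           for i, (nm, b) in enumerate(zip(names, beta))]
    return ModelFit(
        label=spec.label, spec=spec, loglik_ml=np.inf, loglik_reml=np.inf,
        k=spec.k, n=len(df), fixed_effects=fes,
        random_sd={"clone": 0.0, "residual": 0.0},
        converged=True, boundary=True,
        message="zero residual variance; degenerate fit at the boundary",
    )


def fit_lmm_r(estimates, spec: LMMSpec = LMMSpec()) -> ModelFit:
    """Fit one LMM candidate to per-population observed r values.

    ``estimates`` is a frame with columns ``clone_id, group, population_id,
    r`` (NaN r rows are dropped) or a list of IntrinsicRateEstimate.
    Returns a :class:`ModelFit` carrying both the ML log-likelihood (for
    AICc) and the REML log-likelihood, REML fixed-effect estimates with
    Wald SEs/p-values, and the clone/residual SDs (REML).
    """
    df = _as_frame(estimates)
    groups_present = sorted(df["group"].unique())
    if spec.by_group:
        others = [g for g in groups_present if g != spec.reference]
        if spec.reference not in groups_present or len(others) != 1:
            raise ValueError(
                f"group effect needs exactly 2 groups incl. {spec.reference!r}, "
                f"found {groups_present}"
            )
        pre = (df["group"] == others[0]).to_numpy(float)
        exog = np.column_stack([np.ones(len(df)), pre])
        names = [f"r {spec.reference}-invasion (intercept)",
                 f"r {others[0]}-invasion (difference)"]
    else:
        exog = np.ones((len(df), 1))
        names = ["r (intercept)"]

    resid = df["r"].to_numpy() - exog @ np.linalg.lstsq(exog, df["r"].to_numpy(),
                                                        rcond=None)[0]
    if np.var(resid) < _DEGENERATE_VAR:
        return _degenerate_fit(df, spec, names, exog)

    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for reml in (False, True):
            model = MixedLM(df["r"].to_numpy(), exog, groups=df["clone_id"].to_numpy())
            try:
                fits[reml] = model.fit(reml=reml)
            except np.linalg.LinAlgError:
                # boundary (zero clone variance) can make the default
                # optimizer's Hessian singular; retry derivative-free
                fits[reml] = model.fit(reml=reml, method="powell")
    ml, rm = fits[False], fits[True]

    sigma_clone = float(np.sqrt(max(np.asarray(rm.cov_re)[0, 0], 0.0)))
    sigma_resid = float(np.sqrt(rm.scale))
    fes = []
    for i, nm in enumerate(names):
        fes.append(
            FixedEffect(
                name=nm,
                estimate=float(rm.fe_params[i]),
                se=float(rm.bse_fe[i]),
                p=None if i == 0 else float(rm.pvalues[i]),
            )
        )
    boundary = sigma_clone**2 < 1e-8 * rm.scale
    return ModelFit(
        label=spec.label,
        spec=spec,
        loglik_ml=float(ml.llf),
        loglik_reml=float(rm.llf),
        k=spec.k,
        n=len(df),
        fixed_effects=fes,
        random_sd={"clone": sigma_clone, "residual": sigma_resid},
        converged=bool(ml.converged and rm.converged),
        boundary=bool(boundary),
        message="" if (ml.converged and rm.converged) else "optimizer did not converge",
    )
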