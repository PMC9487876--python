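"""Nonlinear mixed-effects theta-logistic model.

For census interval ``j`` of population ``p`` in clone ``c`` the observed
daily growth rate is modeled as

    G_cpj = r_cp * (1 - (N_cpj / K_cp) ** theta_g) + e_cpj

where ``r_cp`` is that population's *observed* intrinsic growth rate
(a known offset, not an estimated parameter), ``N_cpj`` the density at the
interval start and ``e ~ N(0, sigma_resid^2)``. The carrying capacity
carries two nested random effects on the log scale,

    log K_cp = log K_g + b_c + b_cp,
    b_c ~ N(0, sigma_clone^2),  b_cp ~ N(0, sigma_pop^2),

with ``K_g`` (and optionally ``theta_g``) depending on the invasion-history
group. The marginal likelihood integrates the random effects out with a
Laplace approximation: per clone block, the joint negative log-density is
minimized over (b_c, b_c1..b_cP) by damped Newton with analytic gradient
and Hessian, and the Gaussian curvature correction (log-determinant of the
Hessian at the mode) completes the approximation. Fixed effects and
variance components are estimated by maximizing this marginal likelihood
(K, theta and the SDs on the log scale) with multi-start quasi-Newton.

The four candidate structures let K and/or theta depend on the group:
k = 7 (both), 6 (one), 5 (neither), counting 3 variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess1

from .results import FixedEffect, ModelFit

__all__ = ["NLMESpec", "LaplaceError", "nlme_marginal_loglik", "fit_nlme"]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_LOGSD_LO, _LOGSD_HI = -9.0, 3.0
_EXP_CLIP = 60.0


class LaplaceError(RuntimeError):
    """Inner mode-finding failed for one clone block."""


@dataclass(frozen=True)
class NLMESpec:
    """Candidate structure for the theta-logistic NLME.

    ``k_by_group`` / ``theta_by_group`` toggle invasion-history effects on
    K and theta; ``reference`` is the group reported as the intercept.
    """

    measure: str = "numerical"
    k_by_group: bool = True
    theta_by_group: bool = False
    reference: str = "post"

    @property
    def label(self) -> str:
        if self.k_by_group and self.theta_by_group:
            return "K and theta ~ invasion history"
        if self.k_by_group:
            return "K ~ invasion history, theta ~ 1"
        if self.theta_by_group:
            return "K ~ 1, theta ~ invasion history"
        return "K and theta ~ 1"

    @property
    def k(self) -> int:
        return (2 if self.k_by_group else 1) + (2 if self.theta_by_group else 1) + 3


def candidate_specs(measure: str = "numerical", reference: str = "post"):
    """The four-candidate set: K and/or theta by invasion history."""
    return [
        NLMESpec(measure, True, True, reference),
        NLMESpec(measure, True, False, reference),
        NLMESpec(measure, False, True, reference),
        NLMESpec(measure, False, False, reference),
    ]


# ---------------------------------------------------------------------------
# data preparation

class _CloneBlock:
    """Per-clone observation arrays and random-effect design."""

    __slots__ = ("clone_id", "group_idx", "y", "lnN", "r", "pop_idx", "n_pops",
                 "n_obs", "_Z_cache")

    def __init__(self, clone_id, group_idx, y, lnN, r, pop_idx):
        self.clone_id = clone_id
        self.group_idx = group_idx
        self.y = y
        self.lnN = lnN
        self.r = r
        self.pop_idx = pop_idx
        self.n_pops = int(pop_idx.max()) + 1 if len(pop_idx) else 0
        self.n_obs = len(y)
        self._Z_cache: dict = {}

    def design(self, use_c: bool, use_p: bool) -> np.ndarray:
        """Random-effect design matrix s = Z u (cached)."""
        Z = self._Z_cache.get((use_c, use_p))
        if Z is None:
            q = (1 if use_c else 0) + (self.n_pops if use_p else 0)
            Z = np.zeros((self.n_obs, q))
            col = 0
            if use_c:
                Z[:, 0] = 1.0
                col = 1
            if use_p:
                Z[np.arange(self.n_obs), col + self.pop_idx] = 1.0
            self._Z_cache[(use_c, use_p)] = Z
        return Z


class _Problem:
    """Prepared data + parameter packing for one candidate spec."""

    def __init__(self, spec: NLMESpec, growth_obs: pd.DataFrame,
                 r_offsets: pd.DataFrame):
        self.spec = spec
        df = growth_obs.merge(
            r_offsets[["clone_id", "group", "population_id", "r"]],
            on=["clone_id", "group", "population_id"],
            how="left",
            validate="many_to_one",
        )
        n_missing = df["r"].isna().sum()
        if n_missing:
            pops = df.loc[df["r"].isna(), ["clone_id", "population_id"]]
            self.n_excluded_pops = pops.drop_duplicates().shape[0]
            logger.info(
                "excluding %d populations lacking an observed r (%d observations)",
                self.n_excluded_pops, n_missing,
            )
            df = df.dropna(subset=["r"])
        else:
            self.n_excluded_pops = 0
        if df.empty:
            raise ValueError("no growth observations with an r offset")
        if not np.isfinite(df[["N_start", "G", "r"]].to_numpy()).all():
            raise ValueError("growth observations must be finite")
        if (df["N_start"] <= 0).any():
            raise ValueError("N_start must be > 0")

        groups = sorted(df["group"].unique())
        if spec.k_by_group or spec.theta_by_group:
            if spec.reference not in groups or len(groups) != 2:
                raise ValueError(
                    f"group effects need both groups incl. {spec.reference!r}, "
                    f"found {groups}"
                )
        # reference group first so index 0 is the reported intercept
        self.groups = sorted(groups, key=lambda g: g != spec.reference)
        gmap = {g: i for i, g in enumerate(self.groups)}

        self.blocks: list[_CloneBlock] = []
        for clone_id, sub in df.groupby("clone_id", sort=True):
            gidx = {gmap[g] for g in sub["group"].unique()}
            if len(gidx) != 1:
                raise ValueError(f"clone {clone_id!r} spans multiple groups")
            pops = {p: i for i, p in enumerate(sorted(sub["population_id"].unique()))}
            self.blocks.append(
                _CloneBlock(
                    clone_id=str(clone_id),
                    group_idx=gidx.pop(),
                    y=sub["G"].to_numpy(float),
                    lnN=np.log(sub["N_start"].to_numpy(float)),
                    r=sub["r"].to_numpy(float),
                    pop_idx=sub["population_id"].map(pops).to_numpy(int),
                )
            )
        self.n_obs = sum(b.n_obs for b in self.blocks)
        self.n_k = 2 if spec.k_by_group else 1
        self.n_t = 2 if spec.theta_by_group else 1
        self.n_fixed = self.n_k + self.n_t
        self.n_params = self.n_fixed + 3
        self._mode_cache: dict[str, np.ndarray] = {}

    # -- parameter packing: x = [lnK(1|2), lnTheta(1|2), log sd_c, sd_p, sd_e]
    def unpack(self, x):
        x = np.asarray(x, float)
        nG = len(self.groups)
        lnK = x[: self.n_k]
        lnT = x[self.n_k: self.n_fixed]
        sd_c, sd_p, sd_e = np.exp(x[self.n_fixed:])
        lnK_g = lnK if self.n_k == nG else np.full(nG, lnK[0])
        lnT_g = lnT if self.n_t == nG else np.full(nG, lnT[0])
        return lnK_g, lnT_g, sd_c, sd_p, sd_e

    def loglik(self, x) -> float:
        lnK_g, lnT_g, sd_c, sd_p, sd_e = self.unpack(x)
        total = 0.0
        for block in self.blocks:
            total += _laplace_block(
                block, lnK_g[block.group_idx], np.exp(lnT_g[block.group_idx]),
                sd_c, sd_p, sd_e, self._mode_cache,
            )
        return total

    def neg_loglik(self, x) -> float:
        try:
            ll = self.loglik(x)
        except (LaplaceError, FloatingPointError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10


# ---------------------------------------------------------------------------
# Laplace approximation for one clone block

def _laplace_block(block: _CloneBlock, lnK: float, theta: float,
                   sd_c: float, sd_p: float, sd_e: float,
                   cache: dict | None = None) -> float:
    """Marginal log-likelihood contribution of one clone.

    Integrates the clone effect and its populations' effects (whichever
    have positive SD) out of the Gaussian joint by Laplace approximation.
    Zero-SD effects are pinned at 0 exactly, so the no-random-effect limit
    reduces to the plain nonlinear-regression log-likelihood.
    """
    if sd_e <= 0:
        raise ValueError("sigma_resid must be > 0")
    use_c, use_p = sd_c > 0, sd_p > 0
    n, P = block.n_obs, block.n_pops
    # a_j = (N_j / K_g)^theta before random effects
    ln_a = np.clip(theta * (block.lnN - lnK), -_EXP_CLIP, _EXP_CLIP)
    a = np.exp(ln_a)
    var_e = sd_e**2
    const = -0.5 * n * (_LOG2PI + np.log(var_e))

    q = (1 if use_c else 0) + (P if use_p else 0)
    if q == 0:
        resid = block.y - block.r * (1.0 - a)
        return const - 0.5 * np.dot(resid, resid) / var_e

    # random-effect design: s_j = Z_j u
    Z = block.design(use_c, use_p)
    prior_var = np.empty(q)
    if use_c:
        prior_var[0] = sd_c**2
        prior_var[1:] = sd_p**2
    else:
        prior_var[:] = sd_p**2

    def joint_neg(u):
        s = Z @ u
        t = np.exp(np.clip(ln_a - theta * s, -_EXP_CLIP, _EXP_CLIP))
        resid = block.y - block.r * (1.0 - t)
        return (0.5 * np.dot(resid, resid) / var_e
                + 0.5 * np.sum(u * u / prior_var)), t, resid

    key = (block.clone_id, use_c, use_p)
    u = None
    if cache is not None:
        u = cache.get(key)
        if u is not None and len(u) != q:
            u = None
    if u is None:
        u = np.zeros(q)

    g_val, t, resid = joint_neg(u)
    converged = False
    for _ in range(100):
        m1 = block.r * theta * t                 # d mu / d s
        h = (m1 * m1 + resid * block.r * theta**2 * t) / var_e
        grad = Z.T @ (-resid * m1 / var_e) + u / prior_var
        H = (Z * h[:, None]).T @ Z
        H[np.diag_indices_from(H)] += 1.0 / prior_var
        ridge = 0.0
        for _try in range(10):
            try:
                cf = cho_factor(H + ridge * np.eye(q), lower=True)
                break
            except np.linalg.LinAlgError:
                ridge = max(4.0 * ridge, 1e-6 * (1.0 + abs(np.trace(H)) / q))
        else:
            raise LaplaceError(f"Hessian factorization failed for clone {block.clone_id}")
        step = cho_solve(cf, grad)
        decr = 0.5 * np.dot(grad, step)          # predicted quadratic decrease
        if decr < 1e-11 * (1.0 + abs(g_val)):
            converged = True
            break
        lam = 1.0
        while lam > 1e-10:
            g_new, t_new, resid_new = joint_neg(u - lam * step)
            if g_new <= g_val - 1e-4 * lam * decr:
                u = u - lam * step
                g_val, t, resid = g_new, t_new, resid_new
                break
            lam *= 0.5
        else:
            # line search stalled at float precision; accept if near-critical
            converged = decr < 1e-6 * (1.0 + abs(g_val))
            break
    else:
        converged = decr < 1e-6 * (1.0 + abs(g_val))
    if not converged:
        raise LaplaceError(f"inner optimization failed for clone {block.clone_id}")
    if cache is not None:
        cache[key] = u.copy()

    # curvature at the mode
    m1 = block.r * theta * t
    h = (m1 * m1 + resid * block.r * theta**2 * t) / var_e
    H = (Z * h[:, None]).T @ Z
    H[np.diag_indices_from(H)] += 1.0 / prior_var
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        # indefinite curvature at the mode: dominate with the prior precision
        raise LaplaceError(f"non-PD curvature at mode for clone {block.clone_id}")
    return (const
            - g_val
            - 0.5 * np.sum(np.log(2.0 * np.pi * prior_var))
            + 0.5 * q * _LOG2PI
            - 0.5 * logdet)


# ---------------------------------------------------------------------------
# public API

def nlme_marginal_loglik(spec: NLMESpec, growth_obs: pd.DataFrame,
                         r_offsets: pd.DataFrame, params: dict) -> float:
    """Laplace marginal log-likelihood at given parameter values.

    ``params`` maps ``"K"`` and ``"theta"`` to either a scalar (common) or
    a ``{group: value}`` dict, plus scalars ``"sigma_clone"``,
    ``"sigma_pop"`` and ``"sigma_resid"``. Zero SDs drop the corresponding
    random effect exactly, so with both zero this is the plain Gaussian
    nonlinear-regression log-likelihood.
    """
    prob = _Problem(spec, growth_obs, r_offsets)
    x = _pack_params(prob, params)
    # bypass exp packing for exact zero SDs
    lnK_g, lnT_g, _, _, _ = prob.unpack(x)
    sd_c = float(params["sigma_clone"])
    sd_p = float(params["sigma_pop"])
    sd_e = float(params["sigma_resid"])
    if sd_c < 0 or sd_p < 0 or sd_e <= 0:
        raise ValueError("SDs must be >= 0 and sigma_resid > 0")
    total = 0.0
    for block in prob.blocks:
        total += _laplace_block(
            block, lnK_g[block.group_idx], float(np.exp(lnT_g[block.group_idx])),
            sd_c, sd_p, sd_e, None,
        )
    return float(total)


def _pack_params(prob: _Problem, params: dict) -> np.ndarray:
    def expand(val, n, what):
        if np.isscalar(val):
            if n == 2:
                raise ValueError(f"{what} must be per-group for this spec")
            return [float(val)]
        vals = [float(val[g]) for g in prob.groups]
        if n == 2:
            return vals
        if len(set(vals)) != 1:
            raise ValueError(f"{what} is common in this spec; got differing values")
        return vals[:1]

    lnK = np.log(expand(params["K"], prob.n_k, "K"))
    lnT = np.log(expand(params["theta"], prob.n_t, "theta"))
    sds = np.array([max(float(params["sigma_clone"]), 1e-300),
                    max(float(params["sigma_pop"]), 1e-300),
                    float(params["sigma_resid"])])
    return np.concatenate([lnK, lnT, np.log(sds)])


def _initial_point(prob: _Problem) -> np.ndarray:
    allN = np.concatenate([np.exp(b.lnN) for b in prob.blocks])
    allG = np.concatenate([b.y for b in prob.blocks])
    lnK0 = float(np.log(np.percentile(allN, 90)))
    sdG = float(np.std(allG)) or 0.05
    x = np.concatenate([
        np.full(prob.n_k, lnK0),
        np.zeros(prob.n_t),                      # theta = 1
        np.log([0.5 * sdG, 0.25 * sdG, sdG]),
    ])
    return x


def _bounds(prob: _Problem, x0: np.ndarray):
    b = []
    for i in range(prob.n_fixed):
        b.append((x0[i] - 8.0, x0[i] + 8.0))
    b.extend([(_LOGSD_LO, _LOGSD_HI)] * 3)
    return b


def fit_nlme(spec: NLMESpec, growth_obs: pd.DataFrame, r_offsets: pd.DataFrame,
             *, n_starts: int = 5, seed: int = 0, reml: bool = True,
             extra_starts=()) -> ModelFit:
    """Maximize the Laplace marginal likelihood for one candidate spec.

    Multi-start quasi-Newton from data-driven initial values (K at the 90th
    percentile of observed densities, theta at 1, sigma_resid at the SD of
    G); ties between starts break toward the larger log-likelihood, then
    the smaller parameter norm. Fixed-effect SEs come from the inverse
    numerical Hessian with delta-method transformation to the natural
    scale; p-values are Wald with a normal reference.

    With ``reml=True`` the variance components are re-estimated under a
    REML-type criterion (the marginal likelihood, fixed effects profiled
    out, penalized by half the log-determinant of the fixed-effect
    information) and reported in ``random_sd``/``fixed_effects``;
    ``loglik_ml`` is always the ML value used for AICc.
    """
    prob = _Problem(spec, growth_obs, r_offsets)
    rng = np.random.default_rng(seed)
    x0 = _initial_point(prob)
    bounds = _bounds(prob, x0)

    starts = [x0] + [np.asarray(x, float) for x in extra_starts]
    starts += [x0 + rng.normal(0.0, 0.3, size=len(x0))
               for _ in range(max(n_starts, 1) - 1)]

    best = None
    n_failed = 0
    for xs in starts:
        xs = np.clip(xs, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        try:
            res = minimize(prob.neg_loglik, xs, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7,
                                    "eps": 1e-6})
        except LaplaceError:
            n_failed += 1
            continue
        cand = (-res.fun, -float(np.linalg.norm(res.x)), res)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise LaplaceError(f"all {n_starts} starts failed for {spec.label!r}")
    ll_ml, _, res = best
    x_ml = res.x
    converged = bool(res.success) and np.isfinite(ll_ml)

    x_rep, ll_reml = x_ml, None
    if reml:
        try:
            x_rep, ll_reml = _reml_refit(prob, x_ml)
        except Exception as exc:  # REML refit is reporting-only; fall back to ML
            logger.warning("REML refit failed (%s); reporting ML estimates", exc)

    fes, boundary = _report_effects(prob, x_rep)
    lnK_g, lnT_g, sd_c, sd_p, sd_e = prob.unpack(x_rep)
    boundary = boundary or any(
        abs(v - _LOGSD_LO) < 1e-6 for v in x_rep[prob.n_fixed:]
    )
    return ModelFit(
        label=spec.label,
        spec=spec,
        loglik_ml=float(ll_ml),
        loglik_reml=None if ll_reml is None else float(ll_reml),
        k=spec.k,
        n=prob.n_obs,
        fixed_effects=fes,
        random_sd={"clone": float(sd_c), "population_in_clone": float(sd_p),
                   "residual": float(sd_e)},
        converged=converged,
        boundary=bool(boundary),
        message="" if converged else str(res.message),
        extra={"n_excluded_pops": prob.n_excluded_pops, "n_failed_starts": n_failed,
               "x_internal": x_rep.tolist()},
    )


def _embed_x(x: np.ndarray, src: NLMESpec, dst: NLMESpec) -> np.ndarray:
    """Map an internal parameter vector of a reduced spec into a richer
    spec's coordinates (duplicate the common K and/or theta entry)."""
    n_k_src = 2 if src.k_by_group else 1
    lnK, lnT, logsd = x[:n_k_src], x[n_k_src:-3], x[-3:]
    if dst.k_by_group and not src.k_by_group:
        lnK = np.repeat(lnK, 2)
    if dst.theta_by_group and not src.theta_by_group:
        lnT = np.repeat(lnT, 2)
    return np.concatenate([lnK, lnT, logsd])


def fit_candidate_set(growth_obs: pd.DataFrame, r_offsets: pd.DataFrame,
                      measure: str = "numerical", reference: str = "post",
                      *, n_starts: int = 2, seed: int = 0) -> list[ModelFit]:
    """Fit all four candidates, warm-starting richer models from the
    solutions of the models nested within them.

    The embedding starts make the fitted log-likelihoods respect nesting
    (a richer model never scores below a model it contains, up to optimizer
    tolerance) and speed the sweep up considerably. Candidates that fail
    are skipped with a warning; at least one must succeed.
    """
    null = NLMESpec(measure, False, False, reference)
    k_only = NLMESpec(measure, True, False, reference)
    t_only = NLMESpec(measure, False, True, reference)
    full = NLMESpec(measure, True, True, reference)
    fits: list[ModelFit] = []
    sols: dict[str, np.ndarray] = {}

    def _fit(spec, parents):
        extra = [_embed_x(sols[p.label], p, spec) for p in parents
                 if p.label in sols]
        try:
            fit = fit_nlme(spec, growth_obs, r_offsets, n_starts=n_starts,
                           seed=seed, reml=False, extra_starts=extra)
        except Exception as exc:
            logger.warning("candidate %r failed: %s", spec.label, exc)
            return
        sols[spec.label] = np.asarray(fit.extra["x_internal"], float)
        fits.append(fit)

    _fit(null, [])
    _fit(k_only, [null])
    _fit(t_only, [null])
    _fit(full, [k_only, t_only])
    if not fits:
        raise LaplaceError("no NLME candidate converged")
    return fits


def _reml_criterion(prob: _Problem, logsd: np.ndarray, beta0: np.ndarray):
    """Profile the fixed effects, add the REML information penalty."""
    def neg_beta(beta):
        return prob.neg_loglik(np.concatenate([beta, logsd]))

    res = minimize(neg_beta, beta0, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-10, "eps": 1e-6})
    beta = res.x
    F = approx_hess1(beta, neg_beta)
    sign, logdet = np.linalg.slogdet(F)
    if sign <= 0:
        logdet = 0.0
    crit = -res.fun + 0.5 * len(beta) * _LOG2PI - 0.5 * logdet
    return crit, beta


def _reml_refit(prob: _Problem, x_ml: np.ndarray):
    """Re-estimate variance components under the REML-type criterion."""
    beta_ml = x_ml[: prob.n_fixed].copy()
    state = {"beta": beta_ml}

    def neg_crit(logsd):
        logsd = np.clip(logsd, _LOGSD_LO, _LOGSD_HI)
        crit, beta = _reml_criterion(prob, logsd, state["beta"])
        state["beta"] = beta
        return -crit

    res = minimize(neg_crit, x_ml[prob.n_fixed:], method="Nelder-Mead",
                   options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-6})
    logsd = np.clip(res.x, _LOGSD_LO, _LOGSD_HI)
    crit, beta = _reml_criterion(prob, logsd, state["beta"])
    return np.concatenate([beta, logsd]), crit


def _report_effects(prob: _Problem, x: np.ndarray):
    """Natural-scale fixed effects (intercept + difference) with delta-method
    SEs from the inverse numerical Hessian of the negative log-likelihood."""
    spec = prob.spec
    try:
        H = approx_hess1(x, prob.neg_loglik)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag[: prob.n_fixed] < 0):
            raise np.linalg.LinAlgError("negative variance")
        ok = True
    except np.linalg.LinAlgError:
        cov = np.full((len(x), len(x)), np.nan)
        ok = False

    fes: list[FixedEffect] = []
    ref = prob.groups[0]
    other = next((g for g in prob.groups if g != ref), None)

    def natural(idx_int, idx_diff, name, unit_name):
        v_int = float(np.exp(x[idx_int]))
        se_int = float(v_int * np.sqrt(cov[idx_int, idx_int])) if ok else None
        fes.append(FixedEffect(f"{unit_name} {ref}-invasion (intercept)", v_int,
                               se_int, None))
        if idx_diff is not None:
            v_o = float(np.exp(x[idx_diff]))
            grad = np.zeros(len(x))
            grad[idx_int], grad[idx_diff] = -v_int, v_o
            var = float(grad @ cov @ grad) if ok else np.nan
            se = float(np.sqrt(var)) if ok and var >= 0 else None
            diff = v_o - v_int
            p = 2.0 * float(norm.sf(abs(diff) / se)) if se and se > 0 else None
            fes.append(FixedEffect(f"{unit_name} {other}-invasion (difference)",
                                   diff, se, p))

    natural(0, 1 if spec.k_by_group else None, "K", "K")
    t0 = prob.n_k
    if spec.theta_by_group:
        natural(t0, t0 + 1, "theta", "theta")
    else:
        v = float(np.exp(x[t0]))
        se = float(v * np.sqrt(cov[t0, t0])) if ok else None
        fes.append(FixedEffect("theta", v, se, None))
    return fes, not ok
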