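"""End-to-end analysis pipeline.

Given a census table (simulated or read from CSV), for each measure
(numerical counts, biomass):

1. observed intrinsic growth rates r per population (founding abundance to
   the second census);
2. LMM candidate pair for r, ML-fitted, AICc-compared; REML estimates of
   the candidates reported;
3. per-interval growth rates after the first two censuses, theta-logistic
   NLME four-candidate set, ML-fitted, AICc-compared; best candidate
   re-estimated REML-style for the parameter table;
4. percentage contrasts (post vs. pre invasion) from the best candidates
   containing the relevant group effect.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .design import SimulationParams, StudyDesign, build_default_design, build_default_params
from .growth import growth_table, intrinsic_rate_table
from .lmm import LMMSpec, fit_lmm_r
from .nlme import NLMESpec, candidate_specs, fit_candidate_set, fit_nlme
from .results import ModelFit
from .selection import ModelComparison, compare, relative_difference
from .simulate import simulate_study

__all__ = [
    "AnalysisConfig",
    "run_r_analysis",
    "run_theta_analysis",
    "run_study",
]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run.

    ``census_csv`` switches the input from simulation to a file; otherwise
    ``design``/``params``/``seed`` drive the generator.
    """

    census_csv: str | None = None
    design: StudyDesign = field(default_factory=build_default_design)
    params: SimulationParams = field(default_factory=build_default_params)
    seed: int = 0
    measures: tuple[str, ...] = ("numerical", "biomass")
    r_window: int = 2
    skip_through_census: int = 2
    reference: str = "post"
    n_starts: int = 2
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.measures:
            raise ValueError("at least one measure is required")
        if self.census_csv is not None and not Path(self.census_csv).exists():
            raise FileNotFoundError(self.census_csv)


def load_census(config: AnalysisConfig) -> pd.DataFrame:
    if config.census_csv is not None:
        return io.read_census_csv(config.census_csv)
    return simulate_study(config.design, config.params, config.seed)


def run_r_analysis(census: pd.DataFrame, measure: str, *,
                   r_window: int = 2, reference: str = "post"):
    """LMM candidate pair for observed r on one measure.

    Returns ``(comparison, fits, r_table)`` where ``fits`` maps candidate
    label -> ModelFit and ``r_table`` is the per-population r frame reused
    by the theta-logistic stage.
    """
    r_table = intrinsic_rate_table(census, measure=measure, window=r_window)
    n_missing = int(r_table["r"].isna().sum())
    if n_missing:
        logger.info("%s: %d populations have no observable r", measure, n_missing)
    specs = [LMMSpec(measure, True, reference), LMMSpec(measure, False, reference)]
    fits: dict[str, ModelFit] = {}
    for spec in specs:
        try:
            fit = fit_lmm_r(r_table, spec)
        except Exception as exc:
            logger.warning("LMM candidate %r failed: %s", spec.label, exc)
            continue
        fits[fit.label] = fit
    if not fits:
        raise RuntimeError("no LMM candidate converged")
    comparison = compare(list(fits.values()))
    return comparison, fits, r_table


def run_theta_analysis(census: pd.DataFrame, r_table: pd.DataFrame, measure: str, *,
                       skip_through_census: int = 2, reference: str = "post",
                       n_starts: int = 5, seed: int = 0, reml_best: bool = True):
    """Theta-logistic NLME four-candidate set on one measure.

    ML fits feed the AICc comparison; the best candidate is re-estimated
    REML-style when ``reml_best``. Returns ``(comparison, fits, best_fit)``.
    """
    growth = growth_table(census, measure=measure,
                          skip_through_census=skip_through_census)
    fit_list = fit_candidate_set(growth, r_table, measure, reference,
                                 n_starts=n_starts, seed=seed)
    fits: dict[str, ModelFit] = {f.label: f for f in fit_list}
    comparison = compare(list(fits.values()))
    best_fit = fits[comparison.best]
    if reml_best:
        best_fit = fit_nlme(best_fit.spec, growth, r_table, n_starts=n_starts,
                            seed=seed, reml=True)
        fits[comparison.best] = best_fit
    return comparison, fits, best_fit


def _effect_contrast(fits: dict[str, ModelFit], comparison: ModelComparison,
                     needs, effect_prefix: str):
    """Percent contrast from the highest-weight candidate containing the
    group effect (None when no such candidate converged)."""
    ordered = comparison.table["label"].tolist()
    for label in ordered:
        fit = fits.get(label)
        if fit is None or not needs(fit.spec):
            continue
        inter = next(fe for fe in fit.fixed_effects
                     if fe.name.startswith(effect_prefix) and "intercept" in fe.name)
        diff = next(fe for fe in fit.fixed_effects
                    if fe.name.startswith(effect_prefix) and "difference" in fe.name)
        return {
            "model": label,
            "weight": comparison.weight(label),
            "intercept_post": inter.estimate,
            "difference_pre": diff.estimate,
            "percent_increase": relative_difference(inter.estimate, diff.estimate),
        }
    return None


def run_study(config: AnalysisConfig) -> dict:
    """Run the full pipeline; optionally write the report files.

    Returns a dict keyed by measure with the comparisons, fits and
    contrasts; writes ``table1_<measure>.csv``, ``table2_<measure>.json``,
    ``table3_<measure>.json`` and ``contrasts.json`` under
    ``config.out_dir`` when set.
    """
    census = load_census(config)
    out = {"census_rows": len(census)}
    contrasts = {}
    for measure in config.measures:
        logger.info("=== %s analysis ===", measure)
        r_cmp, r_fits, r_table = run_r_analysis(
            census, measure, r_window=config.r_window, reference=config.reference
        )
        t_cmp, t_fits, t_best = run_theta_analysis(
            census, r_table, measure,
            skip_through_census=config.skip_through_census,
            reference=config.reference, n_starts=config.n_starts, seed=config.seed,
        )
        contrasts[measure] = {
            "r": _effect_contrast(r_fits, r_cmp, lambda s: s.by_group, "r "),
            "K": _effect_contrast(t_fits, t_cmp, lambda s: s.k_by_group, "K "),
            "theta": _effect_contrast(t_fits, t_cmp, lambda s: s.theta_by_group,
                                      "theta "),
        }
        out[measure] = {
            "r_comparison": r_cmp,
            "r_fits": r_fits,
            "theta_comparison": t_cmp,
            "theta_fits": t_fits,
            "theta_best": t_best,
            "r_table": r_table,
        }
        if config.out_dir:
            outdir = Path(config.out_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            table1 = pd.concat(
                [
                    r_cmp.table.assign(block="r"),
                    t_cmp.table.assign(block="K_theta"),
                ],
                ignore_index=True,
            )
            table1.to_csv(outdir / f"table1_{measure}.csv", index=False)
            best_r = r_fits[r_cmp.best]
            io.dump_json(best_r.to_dict(), outdir / f"table2_{measure}.json")
            io.dump_json(t_best.to_dict(), outdir / f"table3_{measure}.json")
    out["contrasts"] = contrasts
    if config.out_dir:
        io.dump_json(contrasts, Path(config.out_dir) / "contrasts.json")
    return out
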