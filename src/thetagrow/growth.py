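"""Per-interval growth rates and per-population intrinsic growth rates.

Census tables record abundance (counts) and biomass (mg) at dated censuses.
Two derived quantities drive the downstream models:

* the daily growth rate over a census interval,
  ``G = ln(N_{t+1} / N_t) / d`` with ``d`` the interval length in days; and
* the observed intrinsic growth rate of a population,
  ``r = ln(N_second / N_0) / d``, computed from the founding abundance and
  the *second* census only — early enough that density dependence is
  negligible, which pins down r directly and avoids the r-theta likelihood
  ridge of the theta-logistic fit.

Both are computed for either measure (``"numerical"`` counts or
``"biomass"`` mg). Intervals touching a zero abundance are dropped: the log
ratio is undefined and extinction is handled descriptively, outside the
growth model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CensusSeries",
    "GrowthObservation",
    "IntrinsicRateEstimate",
    "UndefinedRateError",
    "interval_growth_rate",
    "intrinsic_rate",
    "intrinsic_rate_table",
    "growth_table",
]

logger = logging.getLogger(__name__)

MEASURES = ("numerical", "biomass")

#: Census-table columns, one row per population x census (day 0 holds the
#: founding abundance).
CENSUS_COLUMNS = ["clone_id", "group", "population_id", "day", "count", "biomass_mg"]

#: Growth-observation columns.
GROWTH_COLUMNS = [
    "clone_id",
    "group",
    "population_id",
    "day_start",
    "d",
    "N_start",
    "G",
    "measure",
]


class UndefinedRateError(ValueError):
    """Raised when a growth rate is requested for a zero/negative abundance
    or a non-positive interval length."""


@dataclass(frozen=True)
class CensusSeries:
    """One population's census time series.

    ``days`` are strictly increasing days since the population was founded;
    day 0 (the founding census, ``initial_abundance`` individuals) is
    included as the first entry. ``counts`` are individuals, ``biomass`` mg
    dry mass, both aligned with ``days``.
    """

    clone_id: str
    group: str
    population_id: str
    days: tuple[float, ...]
    counts: tuple[float, ...]
    biomass: tuple[float, ...]

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        if days.size and (np.any(np.diff(days) <= 0) or np.any(days < 0)):
            raise ValueError("days must be non-negative and strictly increasing")
        if not (len(self.days) == len(self.counts) == len(self.biomass)):
            raise ValueError("days, counts and biomass must have equal length")
        if any(c < 0 for c in self.counts) or any(b < 0 for b in self.biomass):
            raise ValueError("counts and biomass must be >= 0")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.clone_id, self.group, self.population_id)

    def values(self, measure: str) -> np.ndarray:
        _check_measure(measure)
        return np.asarray(self.counts if measure == "numerical" else self.biomass,
                          dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_id,
                "group": self.group,
                "population_id": self.population_id,
                "day": list(self.days),
                "count": list(self.counts),
                "biomass_mg": list(self.biomass),
            }
        )[CENSUS_COLUMNS]


@dataclass(frozen=True)
class GrowthObservation:
    """A daily growth rate over one census interval, with the density at the
    interval start (the covariate of the theta-logistic model)."""

    clone_id: str
    group: str
    population_id: str
    day_start: float
    d: float
    N_start: float
    G: float
    measure: str

    def __post_init__(self) -> None:
        if not (self.d > 0):
            raise ValueError("interval length d must be > 0")
        if not math.isfinite(self.G):
            raise ValueError("G must be finite")


@dataclass(frozen=True)
class IntrinsicRateEstimate:
    """Observed intrinsic growth rate of one population (or a missing-r
    marker when the population died before the second census)."""

    clone_id: str
    group: str
    population_id: str
    r: float | None
    d: float | None
    measure: str


def _check_measure(measure: str) -> None:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")


def interval_growth_rate(n_start: float, n_end: float, d: float) -> float:
    """Daily growth rate ``G = ln(n_end / n_start) / d`` over ``d`` days.

    Raises
    ------
    UndefinedRateError
        If either abundance is <= 0 or ``d`` <= 0; the caller decides
        whether to drop the interval.
    """
    if not (d > 0):
        raise UndefinedRateError(f"interval length must be > 0, got {d}")
    if not (n_start > 0 and n_end > 0):
        raise UndefinedRateError(
            f"abundances must be > 0 for a log growth rate, got {n_start}, {n_end}"
        )
    return math.log(n_end / n_start) / d


def intrinsic_rate(series: CensusSeries, measure: str = "numerical",
                   window: int = 2) -> IntrinsicRateEstimate:
    """Observed intrinsic growth rate from the founding abundance and the
    ``window``-th census: ``r = ln(N_window / N_0) / d``.

    ``d`` is the actual elapsed time between the founding day and that
    census (robust to irregular schedules). A population extinct (or with
    zero biomass) by then gets a missing-r marker and is excluded from the
    r analysis and from the theta-logistic fit.
    """
    _check_measure(measure)
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = series.values(measure)
    days = np.asarray(series.days, dtype=float)
    if days.size == 0 or days[0] != 0:
        raise ValueError("series must include the founding census at day 0")
    if len(vals) <= window or vals[0] <= 0 or vals[window] <= 0:
        return IntrinsicRateEstimate(*series.key, r=None, d=None, measure=measure)
    d = float(days[window] - days[0])
    r = interval_growth_rate(float(vals[0]), float(vals[window]), d)
    return IntrinsicRateEstimate(*series.key, r=r, d=d, measure=measure)


def iter_series(census: pd.DataFrame):
    """Yield a :class:`CensusSeries` per population of a census table."""
    for (clone, group, pop), sub in census.groupby(
        ["clone_id", "group", "population_id"], sort=True
    ):
        sub = sub.sort_values("day")
        yield CensusSeries(
            clone_id=str(clone),
            group=str(group),
            population_id=str(pop),
            days=tuple(sub["day"].astype(float)),
            counts=tuple(sub["count"].astype(float)),
            biomass=tuple(sub["biomass_mg"].astype(float)),
        )


def intrinsic_rate_table(census: pd.DataFrame, measure: str = "numerical",
                         window: int = 2) -> pd.DataFrame:
    """Per-population observed r for a whole census table.

    Returns a frame with columns ``clone_id, group, population_id, r, d,
    measure``; populations whose r is undefined carry NaN.
    """
    rows = []
    for series in iter_series(census):
        est = intrinsic_rate(series, measure=measure, window=window)
        rows.append(
            {
                "clone_id": est.clone_id,
                "group": est.group,
                "population_id": est.population_id,
                "r": np.nan if est.r is None else est.r,
                "d": np.nan if est.d is None else est.d,
                "measure": measure,
            }
        )
    return pd.DataFrame(rows)


def growth_table(census: pd.DataFrame, measure: str = "numerical",
                 skip_through_census: int = 2) -> pd.DataFrame:
    """Per-interval daily growth rates for the density-dependence fit.

    The first ``skip_through_census`` post-founding censuses are discarded
    (they are the window used to observe r), then one observation is formed
    per remaining pair of consecutive censuses. ``d`` is taken from the
    actual census dates. Intervals with zero abundance at either end are
    dropped; populations contributing fewer than one usable interval are
    logged and yield no rows.
    """
    _check_measure(measure)
    if skip_through_census < 0:
        raise ValueError("skip_through_census must be >= 0")
    rows: list[GrowthObservation] = []
    n_dropped_zero = 0
    for series in iter_series(census):
        days = np.asarray(series.days, dtype=float)
        vals = series.values(measure)
        post = days > 0  # exclude the founding census from the census count
        days, vals = days[post], vals[post]
        days, vals = days[skip_through_census:], vals[skip_through_census:]
        n_before = len(rows)
        for i in range(len(days) - 1):
            if vals[i] <= 0 or vals[i + 1] <= 0:
                n_dropped_zero += 1
                continue
            d = float(days[i + 1] - days[i])
            rows.append(
                GrowthObservation(
                    *series.key,
                    day_start=float(days[i]),
                    d=d,
                    N_start=float(vals[i]),
                    G=interval_growth_rate(float(vals[i]), float(vals[i + 1]), d),
                    measure=measure,
                )
            )
        if len(rows) == n_before:
            logger.info(
                "population %s/%s yields no usable growth intervals",
                series.clone_id, series.population_id,
            )
    if n_dropped_zero:
        logger.info("dropped %d intervals touching zero abundance", n_dropped_zero)
    frame = pd.DataFrame([vars(o) for o in rows], columns=GROWTH_COLUMNS)
    return frame
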