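"""Readers and writers for the package's plain-text interchange formats.

* census CSV — ``clone_id, group, population_id, day, count, biomass_mg``,
  one row per population x census (day 0 rows hold the founding abundance);
* growth CSV — one row per usable census interval;
* YAML config — study design + simulation parameters + seed;
* JSON — serialized model fits and comparisons.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import SimulationParams, StudyDesign
from .growth import CENSUS_COLUMNS, GROWTH_COLUMNS
from .theta import ThetaLogisticParams

__all__ = [
    "read_census_csv",
    "write_census_csv",
    "read_growth_csv",
    "write_growth_csv",
    "load_config",
    "save_config",
    "dump_json",
]


def write_census_csv(census: pd.DataFrame, path) -> None:
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise ValueError(f"census table lacks columns {missing}")
    census[CENSUS_COLUMNS].to_csv(path, index=False)


def read_census_csv(path) -> pd.DataFrame:
    census = pd.read_csv(
        path,
        dtype={
            "clone_id": str,
            "group": str,
            "population_id": str,
            "day": float,
            "count": float,
            "biomass_mg": float,
        },
    )
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise ValueError(f"census CSV lacks columns {missing}")
    if (census["count"] < 0).any() or (census["biomass_mg"] < 0).any():
        raise ValueError("census CSV contains negative abundances")
    return census[CENSUS_COLUMNS]


def write_growth_csv(growth: pd.DataFrame, path) -> None:
    growth[GROWTH_COLUMNS].to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    growth = pd.read_csv(path, dtype={"clone_id": str, "group": str,
                                      "population_id": str, "measure": str})
    missing = [c for c in GROWTH_COLUMNS if c not in growth.columns]
    if missing:
        raise ValueError(f"growth CSV lacks columns {missing}")
    return growth[GROWTH_COLUMNS]


def save_config(design: StudyDesign, params: SimulationParams, seed: int, path) -> None:
    """Write design + simulation parameters + seed as YAML."""
    doc = {
        "seed": int(seed),
        "design": {
            "groups": list(design.groups),
            "clones_per_group": {k: int(v) for k, v in design.clones_per_group.items()},
            "populations_per_clone": int(design.populations_per_clone),
            "initial_abundance": int(design.initial_abundance),
            "census_days": [float(d) for d in design.census_days],
            "mean_individual_mass": float(design.mean_individual_mass),
        },
        "params": {
            "group_params": {
                g: {"r": p.r, "K": p.K, "theta": p.theta}
                for g, p in params.group_params.items()
            },
            "sigma_clone": params.sigma_clone,
            "sigma_pop": params.sigma_pop,
            "sigma_r_clone": params.sigma_r_clone,
            "sigma_resid": params.sigma_resid,
            "demographic_stochasticity": params.demographic_stochasticity,
            "biomass_cv": params.biomass_cv,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> tuple[StudyDesign, SimulationParams, int]:
    doc = yaml.safe_load(Path(path).read_text())
    d = doc["design"]
    design = StudyDesign(
        groups=tuple(d["groups"]),
        clones_per_group={k: int(v) for k, v in d["clones_per_group"].items()},
        populations_per_clone=int(d["populations_per_clone"]),
        initial_abundance=int(d["initial_abundance"]),
        census_days=tuple(float(x) for x in d["census_days"]),
        mean_individual_mass=float(d["mean_individual_mass"]),
    )
    p = doc["params"]
    params = SimulationParams(
        group_params={
            g: ThetaLogisticParams(**gp) for g, gp in p["group_params"].items()
        },
        sigma_clone=float(p["sigma_clone"]),
        sigma_pop=float(p["sigma_pop"]),
        sigma_r_clone=float(p["sigma_r_clone"]),
        sigma_resid=float(p["sigma_resid"]),
        demographic_stochasticity=bool(p["demographic_stochasticity"]),
        biomass_cv=float(p["biomass_cv"]),
    )
    return design, params, int(doc.get("seed", 0))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
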