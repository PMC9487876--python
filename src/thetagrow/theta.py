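"""Theta-logistic growth model.

The theta-logistic model generalizes logistic growth by letting the shape
of density dependence vary: the expected daily per-capita growth rate at
density ``N`` is

    G(N) = r * (1 - (N / K) ** theta)

where ``r`` is the intrinsic growth rate (per day), ``K`` the carrying
capacity (in the units of ``N``: individuals or mg dry mass) and ``theta``
a dimensionless shape parameter. ``theta = 1`` recovers the ordinary
logistic; ``theta < 1`` means per-capita growth drops steeply already at
low density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThetaLogisticParams", "theta_logistic_growth"]


@dataclass(frozen=True)
class ThetaLogisticParams:
    """Parameters (r, K, theta) of a theta-logistic growth curve.

    Attributes
    ----------
    r : float
        Intrinsic (low-density) growth rate, per day.
    K : float
        Carrying capacity; density at which growth is zero. Must be > 0.
    theta : float
        Shape of density dependence, dimensionless. Must be > 0.
    """

    r: float
    K: float
    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r):
            raise ValueError(f"r must be finite, got {self.r!r}")
        if not (self.K > 0):
            raise ValueError(f"K must be > 0, got {self.K!r}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta!r}")


def theta_logistic_growth(params: ThetaLogisticParams, N):
    """Expected daily growth rate G = r(1 - (N/K)^theta) at density ``N``.

    Parameters
    ----------
    params : ThetaLogisticParams
    N : float or array-like
        Density (same units as ``params.K``). Must be >= 0; G(0) = r and
        G(K) = 0 exactly.

    Returns
    -------
    float or ndarray
        Expected growth rate, per day.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("density N must be non-negative")
    G = params.r * (1.0 - (N / params.K) ** params.theta)
    return float(G) if G.ndim == 0 else G
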