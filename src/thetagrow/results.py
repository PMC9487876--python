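"""Container for fitted mixed-model results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["FixedEffect", "ModelFit"]


@dataclass(frozen=True)
class FixedEffect:
    """One fixed-effect estimate with its Wald SE and normal-reference
    p-value (p is None for reference-level intercepts, matching the usual
    reporting convention)."""

    name: str
    estimate: float
    se: float | None = None
    p: float | None = None


@dataclass
class ModelFit:
    """A fitted candidate model.

    ``loglik_ml`` is the marginal ML log-likelihood used for AICc
    comparisons; ``loglik_reml`` the restricted-likelihood analogue used
    only for reporting variance components. ``k`` counts fixed effects plus
    variance components; ``n`` is the number of likelihood contributions.
    """

    label: str
    spec: Any
    loglik_ml: float
    k: int
    n: int
    fixed_effects: list[FixedEffect]
    random_sd: dict[str, float]
    loglik_reml: float | None = None
    converged: bool = True
    boundary: bool = False
    message: str = ""
    extra: dict = field(default_factory=dict)

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "spec": getattr(self.spec, "__dict__", str(self.spec)),
            "loglik_ml": self.loglik_ml,
            "loglik_reml": self.loglik_reml,
            "k": self.k,
            "n": self.n,
            "fixed_effects": [vars(fe) for fe in self.fixed_effects],
            "random_sd": self.random_sd,
            "converged": self.converged,
            "boundary": self.boundary,
            "message": self.message,
        }
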