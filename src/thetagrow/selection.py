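"""AICc model selection: small-sample AIC, Akaike weights and the derived
group contrasts.

AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); weights are
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) with Delta_i the AICc excess
over the best candidate. All candidates must be fitted to the same data
(same n, same response) to be comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["aicc", "compare", "relative_difference", "ModelComparison"]

_TIE_TOL = 1e-9


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples.

    ``k`` counts every estimated parameter (fixed effects plus variance
    components); ``n`` is the number of likelihood contributions. Requires
    ``n > k + 1`` or the correction term is undefined.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelComparison:
    """AICc-ranked candidate set.

    ``table`` has one row per candidate, ascending in AICc, with columns
    ``label, k, AICc, dAICc, weight``; ``best`` is the top label (ties
    broken toward fewer parameters).
    """

    table: pd.DataFrame
    best: str

    def weight(self, label: str) -> float:
        return float(self.table.set_index("label").loc[label, "weight"])


def compare(fits) -> ModelComparison:
    """Rank candidate models by AICc and attach Akaike weights.

    ``fits`` is either a list of fitted-model objects exposing ``label``,
    ``loglik_ml``, ``k`` and ``n`` attributes, or a mapping
    ``label -> AICc`` of already-computed criterion values. With fit
    objects, all candidates must share the same ``n`` (identical data) or
    the comparison is refused.
    """
    if isinstance(fits, dict):
        labels = list(fits)
        ks = [np.nan] * len(labels)
        aiccs = [float(v) for v in fits.values()]
    else:
        fits = list(fits)
        if not fits:
            raise ValueError("need at least one fit to compare")
        ns = {f.n for f in fits}
        if len(ns) > 1:
            raise ValueError(f"fits are on different data (n values {sorted(ns)})")
        labels = [f.label for f in fits]
        ks = [f.k for f in fits]
        aiccs = [aicc(f.loglik_ml, f.k, f.n) for f in fits]
    if not labels:
        raise ValueError("need at least one candidate to compare")
    if len(set(labels)) != len(labels):
        raise ValueError("candidate labels must be unique")

    aiccs = np.asarray(aiccs, dtype=float)
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    table = pd.DataFrame(
        {"label": labels, "k": ks, "AICc": aiccs, "dAICc": delta, "weight": w}
    )
    # ascending AICc; near-ties (< 1e-9) resolved toward fewer parameters
    table["_k_sort"] = pd.to_numeric(table["k"], errors="coerce").fillna(np.inf)
    table = (
        table.sort_values(["AICc", "_k_sort"], kind="mergesort")
        .drop(columns="_k_sort")
        .reset_index(drop=True)
    )
    top = table[table["AICc"] <= table["AICc"].iloc[0] + _TIE_TOL]
    k_num = pd.to_numeric(top["k"], errors="coerce").fillna(np.inf)
    best = top.loc[k_num.idxmin(), "label"]
    return ModelComparison(table=table, best=str(best))


def relative_difference(intercept_post: float, difference_pre: float) -> float:
    """Percent change of the reference (post) level relative to the other
    (pre) level, ``100 * (post / (post + diff) - 1)``.

    Fitted group effects are reported as a reference-level intercept plus a
    difference; this converts them to the "post is X% higher than pre"
    statement. The pre level (intercept + difference) must be positive.
    """
    pre = intercept_post + difference_pre
    if not (pre > 0):
        raise ValueError(f"pre-invasion level must be > 0, got {pre}")
    return 100.0 * (intercept_post / pre - 1.0)
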