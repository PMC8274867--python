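"""E-value sensitivity analysis for unmeasured confounding.

A fitted temporal or spatial effect b1 (t C/ha) is standardized by an outcome
SD sigma, converted to a risk-ratio-scale effect ratio, and summarised as the
E-value — the minimum strength of association (risk-ratio scale) an
unmeasured confounder would need with both the tenure assignment and carbon
stocks to explain the effect away:

    d  = b1 / sigma
    ER = exp(1.81 * d)
    E  = ER + sqrt(ER * (ER - 1))

The 1.81 constant is the standard conversion from a standardized mean
difference to an approximate log odds ratio (pi/sqrt(3)), which presumes
sigma is an outcome SD; the default sigma is therefore the pooled SD of the
outcome in the matched sample, with the estimate's standard error available
as an alternative.  Protective effects (ER < 1) are inverted to 1/ER before
the E-value formula, per the usual convention, and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cem import MatchedSet
from .effects import EffectEstimate
from .landscape import LandscapeGrid

SMD_TO_LOG_RR = 1.81


@dataclass
class SensitivityResult:
    d: float
    sigma: float
    effect_ratio: float
    e_value: float
    inverted: bool  # ER < 1 was replaced by 1/ER
    sigma_source: str = "outcome_sd"

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "sigma": self.sigma,
            "effect_ratio": self.effect_ratio,
            "e_value": self.e_value,
            "inverted": self.inverted,
            "sigma_source": self.sigma_source,
        }


def standardized_effect(b1: float, sigma: float) -> float:
    """d = b1 / sigma; sigma must be positive."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return b1 / sigma


def effect_ratio(d: float) -> float:
    """ER = exp(1.81 * d), the risk-ratio-scale transform of d."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return math.exp(SMD_TO_LOG_RR * d)


def e_value(er: float) -> tuple[float, bool]:
    """E = ER + sqrt(ER*(ER-1)) for ER >= 1; protective ER < 1 is inverted.

    Returns (e_value, inverted_flag).  E(1) = 1 and E grows monotonically
    with how far ER sits from 1 on the ratio scale.
    """
    if er <= 0:
        raise ValueError("effect ratio must be positive")
    inverted = er < 1.0
    if inverted:
        er = 1.0 / er
    return er + math.sqrt(er * (er - 1.0)), inverted


def _pooled_outcome_sd(
    estimate: EffectEstimate, matched: MatchedSet, grid: LandscapeGrid
) -> float:
    idx = grid.table.set_index("cell_id")
    t = idx.loc[matched.treated_ids, estimate.outcome].to_numpy(float)
    c = idx.loc[matched.control_ids, estimate.outcome].to_numpy(float)
    vt = t.var(ddof=1) if len(t) > 1 else 0.0
    vc = c.var(ddof=1) if len(c) > 1 else 0.0
    return float(np.sqrt((vt + vc) / 2.0))


def sensitivity_for(
    estimate: EffectEstimate,
    matched: MatchedSet,
    grid: LandscapeGrid,
    sigma_source: str = "outcome_sd",
) -> SensitivityResult:
    """Chain d -> ER -> E-value for one fitted effect.

    ``sigma_source`` is ``outcome_sd`` (pooled SD of the outcome over the
    matched sample, the default) or ``se`` (the effect's standard error).
    """
    if sigma_source == "outcome_sd":
        sigma = _pooled_outcome_sd(estimate, matched, grid)
    elif sigma_source == "se":
        sigma = estimate.se_b1
    else:
        raise ValueError(f"unknown sigma_source {sigma_source!r}")
    if not (sigma > 0):
        raise ValueError("degenerate outcome: sigma is not positive")
    d = standardized_effect(estimate.b1, sigma)
    er = effect_ratio(d)
    ev, inverted = e_value(er)
    return SensitivityResult(
        d=d, sigma=sigma, effect_ratio=er, e_value=ev,
        inverted=inverted, sigma_source=sigma_source,
    )


def sensitivity_frame(
    pairs: list[tuple[EffectEstimate, SensitivityResult]]
) -> pd.DataFrame:
    """Tidy join of effects and their sensitivity results for CSV export."""
    rows = []
    for est, sens in pairs:
        rows.append(
            {
                "year": est.year,
                "tenure": est.tenure_class,
                "outcome": est.outcome,
                "b1": est.b1,
                "b0": est.b0,
                **sens.to_dict(),
            }
        )
    return pd.DataFrame(rows)
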