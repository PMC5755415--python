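"""Risk-based capitation: need scores per parish and budget allocation.

Each parish receives four component scores in {1, 2, 3}: level of higher
education (higher education -> lower need), non-domestic background,
proportion of families with low purchasing power, and the calculated
caries risk (the smoothed relative risk from disease mapping).  The total
need score is the weighted sum

    total = 0.2*education + 0.2*foreign_background + 0.2*purchasing + 0.4*caries_risk

bounded in [1.0, 3.0].  A fixed regional budget is then re-allocated so the
per-child annual amount scales linearly with the parish score — clinics
surrounded by high-risk parishes gain at the expense of low-risk ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import largest_remainder_round

HIGHER_IS_LOWER_RISK = "higher_is_lower_risk"
HIGHER_IS_HIGHER_RISK = "higher_is_higher_risk"

#: default cutoffs and directions for the socio-economic indicators
#: (proportions, not percent): score 1 = lowest need, 3 = highest need
DEFAULT_INDICATOR_RULES = {
    "prop_higher_education": ((0.177, 0.246), HIGHER_IS_LOWER_RISK),
    "prop_foreign_background": ((0.070, 0.095), HIGHER_IS_HIGHER_RISK),
    "prop_low_purchasing_power": ((0.179, 0.250), HIGHER_IS_HIGHER_RISK),
}

#: caries-risk cutoffs: <=0.60 -> 1, (0.60, 1.33] -> 2, >1.33 -> 3
DEFAULT_RISK_CUTOFFS = (0.60, 1.33)

DEFAULT_WEIGHTS = (0.2, 0.2, 0.2, 0.4)


@dataclass(frozen=True)
class ScoreBreakdown:
    education_score: int
    foreign_score: int
    purchasing_score: int
    caries_risk_score: int

    @property
    def total(self) -> float:
        return total_score(
            self.education_score,
            self.foreign_score,
            self.purchasing_score,
            self.caries_risk_score,
        )


def categorize_indicator(value: float, cutoffs: tuple[float, float], direction: str) -> int:
    """Three-band need score for one socio-economic proportion.

    ``cutoffs = (lo, hi)`` are the two band edges; boundary values fall in
    the band whose printed interval includes them: for a risk-increasing
    indicator 1 iff value <= lo, 2 iff lo < value <= hi, 3 iff value > hi;
    for a risk-decreasing indicator (e.g. higher education) 1 iff
    value > hi, 2 iff lo <= value <= hi, 3 iff value < lo.
    """
    lo, hi = cutoffs
    if not lo < hi:
        raise ValueError(f"cutoffs must be strictly ordered, got {cutoffs}")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"indicator proportion outside [0, 1]: {value}")
    if direction == HIGHER_IS_HIGHER_RISK:
        return 1 if value <= lo else (2 if value <= hi else 3)
    if direction == HIGHER_IS_LOWER_RISK:
        return 1 if value > hi else (2 if value >= lo else 3)
    raise ValueError(f"unknown direction {direction!r}")


def categorize_caries_risk(risk: float, cutoffs: tuple[float, float] = DEFAULT_RISK_CUTOFFS) -> int:
    """Need score for the calculated caries relative risk."""
    if risk < 0:
        raise ValueError(f"caries risk must be non-negative, got {risk}")
    lo, hi = cutoffs
    return 1 if risk <= lo else (2 if risk <= hi else 3)


def tertile_cutoffs(values) -> tuple[float, float]:
    """Empirical tertile cut points (33.3%/66.7%) as indicator cutoffs."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.percentile(arr, [100 / 3, 200 / 3], method="linear")
    return float(lo), float(hi)


def total_score(
    education: int,
    foreign: int,
    purchasing: int,
    caries_risk: int,
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Weighted total need score in [1.0, 3.0]."""
    components = (education, foreign, purchasing, caries_risk)
    for c in components:
        if c not in (1, 2, 3):
            raise ValueError(f"component scores must be in {{1,2,3}}, got {c}")
    # round away float noise: weights have one decimal place, scores are ints
    return float(round(np.dot(weights, components), 12))


def allocate_budget(
    scores,
    n_children,
    total_budget: float,
    *,
    unit: float = 1.0,
    parish_ids=None,
) -> pd.DataFrame:
    """Distribute a fixed budget across parishes in proportion to
    score x child count.

    ``per_child_amount`` is the exact (unrounded) annual amount per child,
    strictly increasing in the parish score; ``parish_budget`` is rounded
    to the currency ``unit`` by largest remainder so the parish budgets sum
    to ``total_budget`` exactly.
    """
    scores = np.asarray(scores, dtype=float)
    n_children = np.asarray(n_children, dtype=float)
    if total_budget <= 0:
        raise ValueError("total_budget must be positive")
    if np.any(scores <= 0):
        raise ValueError("scores must be positive")
    if n_children.sum() <= 0:
        raise ValueError("region has zero children")
    if parish_ids is None:
        parish_ids = np.arange(scores.size)
    denom = float(scores @ n_children)
    per_child = total_budget * scores / denom
    raw_budget = per_child * n_children
    rounded = largest_remainder_round(raw_budget, unit, total_budget)
    return pd.DataFrame(
        {
            "parish_id": list(parish_ids),
            "total_score": scores,
            "n_children": n_children.astype(int),
            "per_child_amount": per_child,
            "parish_budget": rounded,
        }
    )


class CapitationAllocator(BaseEstimator):
    """Transformer from parish SES + caries-risk tables to scores and money.

    Expects a DataFrame with columns ``parish_id``,
    ``prop_higher_education``, ``prop_foreign_background``,
    ``prop_low_purchasing_power``, ``caries_risk`` and ``n_children``.
    ``fit`` resolves cutoffs (printed defaults, or empirical tertiles when
    ``tertile_indicators=True``); ``transform`` returns the score table,
    with the allocation in ``allocation_`` when a budget is set.
    """

    def __init__(
        self,
        total_budget: float | None = None,
        unit: float = 1.0,
        weights: tuple = DEFAULT_WEIGHTS,
        risk_cutoffs: tuple = DEFAULT_RISK_CUTOFFS,
        indicator_rules: dict | None = None,
        tertile_indicators: bool = False,
    ):
        self.total_budget = total_budget
        self.unit = unit
        self.weights = weights
        self.risk_cutoffs = risk_cutoffs
        self.indicator_rules = indicator_rules
        self.tertile_indicators = tertile_indicators

    def fit(self, X: pd.DataFrame, y=None):
        rules = dict(self.indicator_rules or DEFAULT_INDICATOR_RULES)
        if self.tertile_indicators:
            rules = {
                col: (tertile_cutoffs(X[col]), direction)
                for col, (_, direction) in rules.items()
            }
        self.rules_ = rules
        self.scores_ = self.transform(X)
        if self.total_budget is not None:
            self.allocation_ = allocate_budget(
                self.scores_["total_score"],
                X["n_children"],
                self.total_budget,
                unit=self.unit,
                parish_ids=list(X["parish_id"]),
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rules = getattr(self, "rules_", None) or dict(
            self.indicator_rules or DEFAULT_INDICATOR_RULES
        )
        rows = []
        for _, r in X.iterrows():
            edu = categorize_indicator(
                r["prop_higher_education"], *rules["prop_higher_education"]
            )
            fbg = categorize_indicator(
                r["prop_foreign_background"], *rules["prop_foreign_background"]
            )
            ppw = categorize_indicator(
                r["prop_low_purchasing_power"], *rules["prop_low_purchasing_power"]
            )
            risk = categorize_caries_risk(r["caries_risk"], self.risk_cutoffs)
            rows.append(
                {
                    "parish_id": r["parish_id"],
                    "education_score": edu,
                    "foreign_score": fbg,
                    "purchasing_score": ppw,
                    "caries_risk_score": risk,
                    "total_score": total_score(edu, fbg, ppw, risk, self.weights),
                }
            )
        return pd.DataFrame(rows)
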