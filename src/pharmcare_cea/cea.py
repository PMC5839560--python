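"""Cost-effectiveness core: CER, ICER, dominance, the CE plane, the
3 x GDP-per-capita threshold, and Cochran's Q for repeated binary outcomes.

Conventions: effects are proportions in [0, 1] (a strategy controlling 54.4%
of patients has effect 0.544), costs are USD per patient-year.  The ICER when
the effect difference is zero is undefined (None) rather than infinite, so
Monte Carlo summaries stay finite; such comparisons are classified by the cost
sign alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CohortYearSummary
from .errors import UndefinedResultError, ValidationError

__all__ = [
    "Strategy",
    "CEComparison",
    "ThresholdConfig",
    "cer",
    "icer",
    "period_aggregate",
    "ce_plane",
    "cochran_q",
    "CochranQResult",
    "period_outcome_matrix",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADE_OFF_NE = "trade_off_ne"   # more costly, more effective (north-east)
TRADE_OFF_SW = "trade_off_sw"   # cheaper, less effective (south-west)


@dataclass(frozen=True)
class Strategy:
    """A care strategy: cost per patient-year and proportion controlled."""

    label: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValidationError(f"{self.label}: cost must be non-negative")
        if not 0.0 <= self.effect <= 1.0:
            raise ValidationError(f"{self.label}: effect must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdConfig:
    """Cost-effectiveness threshold: a multiple of GDP per capita.

    The printed threshold is canonical; if it disagrees with
    multiplier x gdp_per_capita beyond rounding, a warning is raised but the
    stated threshold is used.
    """

    gdp_per_capita: float = 10_240.43
    multiplier: int = 3
    threshold: float = 30_721.28

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        recomputed = self.multiplier * self.gdp_per_capita
        if abs(recomputed - self.threshold) > 0.05:
            warnings.warn(
                f"threshold {self.threshold} differs from "
                f"{self.multiplier} x {self.gdp_per_capita} = {recomputed:.2f}; "
                "using the stated threshold",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of a new strategy against a baseline."""

    new_label: str
    base_label: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str
    below_threshold: bool


def cer(s: Strategy) -> float:
    """Cost-effectiveness ratio: cost per unit of control achieved."""
    if s.effect == 0:
        raise UndefinedResultError(f"{s.label}: CER undefined at zero effect")
    return s.cost / s.effect


def _dominance(dc: float, de: float) -> str:
    if de > 0:
        return DOMINANT if dc < 0 else TRADE_OFF_NE
    if de < 0:
        return DOMINATED if dc > 0 else TRADE_OFF_SW
    # zero effect difference: classify by cost sign alone
    if dc > 0:
        return DOMINATED
    if dc < 0:
        return DOMINANT
    return TRADE_OFF_NE


def icer(
    new: Strategy, base: Strategy, threshold: ThresholdConfig | None = None
) -> CEComparison:
    """Incremental cost-effectiveness of ``new`` vs ``base``.

    ICER = Δcost / Δeffect; undefined (None) when Δeffect = 0.  A comparison is
    below the threshold when it is dominant, or when it buys effect at
    0 <= ICER <= threshold.
    """
    dc = new.cost - base.cost
    de = new.effect - base.effect
    ratio = dc / de if de != 0 else None
    dom = _dominance(dc, de)
    thr = (threshold or ThresholdConfig()).threshold
    below = dom == DOMINANT or (de > 0 and ratio is not None and 0 <= ratio <= thr)
    return CEComparison(
        new_label=new.label, base_label=base.label,
        delta_cost=dc, delta_effect=de, icer=ratio,
        dominance=dom, below_threshold=below,
    )


def period_aggregate(
    summaries: Iterable[CohortYearSummary],
    period: str,
    period_effect: float | None = None,
) -> Strategy:
    """Collapse a period's yearly summaries into one strategy.

    Cost is the unweighted mean of the yearly per-patient means.  The effect is
    ``period_effect`` when supplied — the study measures period-level control
    on the subset of patients observed in all periods, which is not the mean of
    the yearly proportions — otherwise the mean of yearly proportions.
    """
    years = [s for s in summaries if s.period == period]
    if not years:
        raise ValidationError(f"no yearly summaries for period {period!r}")
    cost = float(np.mean([s.mean_cost_per_patient for s in years]))
    effect = (period_effect if period_effect is not None
              else float(np.mean([s.controlled_prop for s in years])))
    return Strategy(label=period, cost=cost, effect=effect)


def ce_plane(
    points: Sequence[tuple[Strategy, Strategy]],
    threshold: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness plane coordinates (Δeffect, Δcost) with quadrants."""
    rows = []
    for new, base in points:
        c = icer(new, base, threshold)
        rows.append({
            "label": new.label, "base": base.label,
            "delta_effect": c.delta_effect, "delta_cost": c.delta_cost,
            "icer": c.icer, "dominance": c.dominance,
            "below_threshold": c.below_threshold,
        })
    return pd.DataFrame(rows)


class CochranQResult(NamedTuple):
    statistic: float
    df: int
    significant: bool


def cochran_q(matrix) -> CochranQResult:
    """Cochran's Q for a patients x conditions binary matrix.

    Q = k(k-1) Σ_j (C_j - N/k)^2 / (k Σ_i R_i - Σ_i R_i^2) with k conditions,
    column totals C_j, row totals R_i and grand total N; df = k - 1.
    Significance is judged against the chi-square 95th percentile (5.99 for
    the study's three periods).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("Cochran's Q needs a 2-D matrix with >= 2 rows and columns")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError("Cochran's Q needs a binary (0/1) matrix")
    k = x.shape[1]
    df = k - 1
    if (x == x[:, [0]]).all():
        # perfectly homogeneous conditions: no heterogeneity by definition
        return CochranQResult(statistic=0.0, df=df, significant=False)
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    grand = x.sum()
    denom = k * row.sum() - (row ** 2).sum()
    if denom == 0:
        raise UndefinedResultError("all rows constant: Cochran's Q undefined")
    q = float(k * (k - 1) * ((col - grand / k) ** 2).sum() / denom)
    critical = float(stats.chi2.ppf(0.95, df))
    return CochranQResult(statistic=q, df=df, significant=q > critical)


def period_outcome_matrix(
    outcomes_frame: pd.DataFrame, period_map: Mapping[int, str]
) -> np.ndarray:
    """Patients x periods binary matrix: controlled in the majority of the
    period's observed years (ties count as controlled).

    Input frame needs columns patient_id, year, controlled; patients missing a
    period are dropped (matched design).
    """
    df = outcomes_frame.copy()
    df["period"] = df["year"].map(period_map)
    periods = list(dict.fromkeys(period_map.values()))
    per = (df.groupby(["patient_id", "period"])["controlled"].mean() >= 0.5)
    wide = per.unstack("period").reindex(columns=periods).dropna()
    return wide.to_numpy(dtype=float)
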