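"""Report surfaces: the yearly and period CER/ICER tables and the
desk-scale reproduction of the published analysis from its printed inputs.

The "reference" builders take no data files: they assemble strategies from the
study constants (per-year costs with the PC program cost embedded in the
intervention year, yearly and period control proportions) so the whole
deterministic analysis can be recomputed from scratch in milliseconds.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import study
from .cea import Strategy, ThresholdConfig, cer, icer, period_aggregate
from .costing import CohortYearSummary, UnitCosts, add_pc_program_cost
from .errors import ValidationError
from .inb import WTPSweep, wtp_sweep

__all__ = [
    "reference_year_strategies",
    "reference_period_strategies",
    "reference_summaries",
    "yearly_cea_table",
    "period_cea_table",
    "reference_inb_sweeps",
    "sweep_to_frame",
]

BASELINE_YEARS = (2006, 2007, 2008)
COMPARISON_YEARS = (2009, 2010, 2011, 2012)


def reference_year_strategies() -> dict[int, Strategy]:
    """Per-year strategies from the printed study inputs.

    Intervention-year cost includes the PC program cost per patient
    (197.11 + 210.80 = 407.91); effects are the yearly control proportions.
    """
    out: dict[int, Strategy] = {}
    for y in study.YEARS:
        cost = study.COST_MEAN[y]
        if study.PERIOD_MAP[y] == "pc":
            cost += study.PC_COST_PER_PATIENT
        out[y] = Strategy(label=str(y), cost=cost, effect=study.OUTCOME_PROP[y])
    return out


def reference_summaries() -> list[CohortYearSummary]:
    """Printed Table-2-shaped yearly summaries (PC cost embedded in 2009)."""
    unit = UnitCosts(pc_cost_per_patient=study.PC_COST_PER_PATIENT)
    out = []
    for y in study.YEARS:
        s = CohortYearSummary(
            year=y, period=study.PERIOD_MAP[y],
            mean_cost_per_patient=study.COST_MEAN[y], sd_cost=study.COST_SD[y],
            overall_cost=study.OVERALL_COST[y],
            controlled_prop=study.OUTCOME_PROP[y],
            n_complete=study.N_COMPLETE, n_patients=study.N_PATIENTS,
        )
        out.append(add_pc_program_cost(s, unit) if s.period == "pc" else s)
    return out


def reference_period_strategies() -> dict[str, Strategy]:
    """Period strategies: mean of yearly costs, published period-level effects."""
    summaries = reference_summaries()
    return {p: period_aggregate(summaries, p, period_effect=study.PERIOD_EFFECT[p])
            for p in study.PERIODS}


def yearly_cea_table(
    strategies: Mapping[int, Strategy],
    baseline_years: Sequence[int] = BASELINE_YEARS,
    threshold: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Yearly table: cost and effect per year, CER row, one ICER row per
    baseline year (ICER of each later year against that baseline)."""
    years = sorted(strategies)
    rows: dict[str, dict[int, float | None]] = {
        "cost": {y: strategies[y].cost for y in years},
        "effect": {y: strategies[y].effect for y in years},
        "cer": {y: cer(strategies[y]) for y in years},
    }
    for base in baseline_years:
        if base not in strategies:
            raise ValidationError(f"baseline year {base} has no strategy")
        rows[f"icer_vs_{base}"] = {
            y: (icer(strategies[y], strategies[base], threshold).icer
                if y > base else None)
            for y in years
        }
    return pd.DataFrame(rows).T[years]


def period_cea_table(
    period_strategies: Mapping[str, Strategy],
    baseline_period: str = "pre_pc",
    threshold: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Period table: cost, effect, CER, and ICER/dominance vs the baseline."""
    rows = []
    base = period_strategies[baseline_period]
    for label, strat in period_strategies.items():
        row = {"period": label, "cost": strat.cost, "effect": strat.effect,
               "cer": cer(strat), "icer": None, "dominance": None,
               "below_threshold": None}
        if label != baseline_period:
            c = icer(strat, base, threshold)
            row.update(icer=c.icer, dominance=c.dominance,
                       below_threshold=c.below_threshold)
        rows.append(row)
    return pd.DataFrame(rows).set_index("period")


def reference_inb_sweeps(
    n_points: int = 512,
    lambda_min: float = 1.0,
    lambda_max: float = study.CE_THRESHOLD,
) -> dict[str, WTPSweep]:
    """Willingness-to-pay sweeps for the PC and post-PC period comparisons."""
    periods = reference_period_strategies()
    thr = ThresholdConfig()
    return {
        p: wtp_sweep(lambda_min, lambda_max, n_points,
                     icer(periods[p], periods["pre_pc"], thr))
        for p in ("pc", "post_pc")
    }


def sweep_to_frame(sweep: WTPSweep) -> pd.DataFrame:
    return pd.DataFrame({
        "lambda": sweep.lambdas,
        "inb": sweep.inb_values,
        "sign": np.sign(sweep.inb_values).astype(int),
    })
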