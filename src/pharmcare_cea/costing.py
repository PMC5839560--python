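"""Health-services costing: unit costs, per-patient cost items, currency
adjustment, and cohort-year aggregation.

The costing model follows Brazilian public-health-system accounting practice:

* consultations carry a "base cost" of the health unit (annual unit expenditure
  divided by the annual number of appointments);
* an emergency visit adds a bundle (urgent drugs, ECG, chest X-ray, CPK,
  administration) to the emergency unit's base cost;
* a specialised (cardiology) visit sums three cost categories — per-visit
  (category 1), annual routine exams spread over 3 yearly visits (category 2),
  and biennial complex exams spread over 6 visits (category 3);
* antihypertensive drugs are costed per milligram consumed;
* transport is the municipal flat fare, two trips per consultation, waived for
  exempt patients; absenteeism charges half a working day (4 h) per
  consultation at an hourly wage derived from labour-law constants
  (13 monthly salaries over 11 months x 20 days x 8 h = 1760 worked hours).

Cohort aggregation uses the study's scaling rule: the mean over patients with
complete cost data is multiplied by the full cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .cohort import OutcomeRecord, PatientYearCost
from .errors import ValidationError

__all__ = [
    "UnitCosts",
    "CurrencyConfig",
    "CohortYearSummary",
    "consultation_base_cost",
    "emergency_visit_cost",
    "specialized_visit_cost",
    "medication_cost",
    "absenteeism_cost",
    "transport_cost",
    "adjust_and_convert",
    "summarize_cohort_year",
    "add_pc_program_cost",
]

WORKED_HOURS_PER_YEAR = 11 * 20 * 8  # 1760: a month of vacation, 20 days, 8 h
MONTHLY_SALARIES_PER_YEAR = 13       # 12 months + mandatory 13th salary
ABSENCE_HOURS_PER_CONSULTATION = 4   # half a working day per appointment
TRIPS_PER_CONSULTATION = 2           # to and return


@dataclass
class UnitCosts:
    """Unit costs feeding every per-patient cost item (currency units/yr)."""

    test_unit_costs: Mapping[str, float] = field(default_factory=dict)
    base_cost_primary: float = 0.0
    base_cost_emergency: float = 0.0
    emergency_bundle: float = 0.0      # drugs + ECG + X-ray + CPK + administration
    spec_cat1: float = 0.0             # per specialised consultation
    spec_cat2_annual: float = 0.0      # routine exams, once a year
    spec_cat3_biennial: float = 0.0    # complex exams, every two years
    drug_cost_per_mg: Mapping[str, float] = field(default_factory=dict)
    transport_fare: float = 0.0
    mean_monthly_salary: float = 0.0
    pc_cost_per_patient: float = 210.80

    def __post_init__(self) -> None:
        scalars = [self.base_cost_primary, self.base_cost_emergency,
                   self.emergency_bundle, self.spec_cat1, self.spec_cat2_annual,
                   self.spec_cat3_biennial, self.transport_fare,
                   self.mean_monthly_salary, self.pc_cost_per_patient]
        if any(v < 0 for v in scalars) \
                or any(v < 0 for v in self.test_unit_costs.values()) \
                or any(v < 0 for v in self.drug_cost_per_mg.values()):
            raise ValidationError("unit costs must be non-negative")


@dataclass(frozen=True)
class CurrencyConfig:
    """Single inflation adjustment to 2015 plus BRL->USD conversion."""

    inflation_factor: float = 1.0
    fx_brl_per_usd: float = 3.87

    def __post_init__(self) -> None:
        if self.inflation_factor <= 0 or self.fx_brl_per_usd <= 0:
            raise ValidationError("inflation factor and FX rate must be positive")


@dataclass
class CohortYearSummary:
    """Per-year cohort cost/outcome summary (mean-of-complete x N scaling)."""

    year: int
    period: str
    mean_cost_per_patient: float
    sd_cost: float
    overall_cost: float
    controlled_prop: float
    n_complete: int
    n_patients: int
    pc_cost_added: bool = False


def consultation_base_cost(annual_unit_cost: float, annual_consultations: int) -> float:
    """Base cost per consultation: annual unit expenditure / annual appointments."""
    if annual_consultations <= 0:
        raise ValidationError("annual consultation count must be positive")
    if annual_unit_cost < 0:
        raise ValidationError("annual unit cost must be non-negative")
    return annual_unit_cost / annual_consultations


def emergency_visit_cost(u: UnitCosts) -> float:
    """Emergency consultation: unit base cost plus the urgent-care bundle."""
    return u.base_cost_emergency + u.emergency_bundle


def specialized_visit_cost(u: UnitCosts) -> float:
    """Cardiology consultation: cat. 1 + cat. 2 / 3 visits + cat. 3 / 6 visits."""
    return u.spec_cat1 + u.spec_cat2_annual / 3.0 + u.spec_cat3_biennial / 6.0


def medication_cost(consumption_mg: Mapping[str, float], u: UnitCosts) -> float:
    """Annual drug cost: sum over drugs of mg consumed x cost per mg."""
    total = 0.0
    for drug, mg in consumption_mg.items():
        if mg < 0:
            raise ValidationError(f"negative consumption for {drug!r}")
        if drug not in u.drug_cost_per_mg:
            raise ValidationError(f"no cost/mg on file for drug {drug!r}")
        total += mg * u.drug_cost_per_mg[drug]
    return total


def absenteeism_cost(mean_monthly_salary: float, consultations: int) -> float:
    """Lost-wage cost: hourly wage x 4 h per consultation.

    Hourly wage = 13 monthly salaries / 1760 worked hours per year.
    """
    if mean_monthly_salary < 0 or consultations < 0:
        raise ValidationError("salary and consultation count must be non-negative")
    hourly = MONTHLY_SALARIES_PER_YEAR * mean_monthly_salary / WORKED_HOURS_PER_YEAR
    return hourly * ABSENCE_HOURS_PER_CONSULTATION * consultations


def transport_cost(fare: float, consultations: int, pays_fare: bool) -> float:
    """Round-trip public-transport cost per consultation; exempt patients pay 0."""
    if fare < 0 or consultations < 0:
        raise ValidationError("fare and consultation count must be non-negative")
    return fare * TRIPS_PER_CONSULTATION * consultations if pays_fare else 0.0


def adjust_and_convert(amount_brl: float, c: CurrencyConfig) -> float:
    """Inflate a BRL amount to 2015 and convert to USD."""
    if amount_brl < 0:
        raise ValidationError("amount must be non-negative")
    return amount_brl * c.inflation_factor / c.fx_brl_per_usd


def summarize_cohort_year(
    records: Iterable[PatientYearCost],
    outcomes: Iterable[OutcomeRecord],
    year: int,
    n_patients: int,
    period: str = "",
) -> CohortYearSummary:
    """Mean/SD cost over patients with data for ``year``, scaled to the cohort.

    ``overall_cost = mean x n_patients`` reproduces the study's rule of
    extrapolating the complete-data mean to all enrolled patients.  The SD is
    the sample SD (n-1 denominator).
    """
    totals = [r.total for r in records if r.year == year]
    if not totals:
        raise ValidationError(f"no cost records for year {year}")
    year_outcomes = [o.controlled for o in outcomes if o.year == year]
    mean = float(np.mean(totals))
    sd = float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0
    return CohortYearSummary(
        year=year,
        period=period,
        mean_cost_per_patient=mean,
        sd_cost=sd,
        overall_cost=mean * n_patients,
        controlled_prop=float(np.mean(year_outcomes)) if year_outcomes else math.nan,
        n_complete=len(totals),
        n_patients=n_patients,
    )


def add_pc_program_cost(summary: CohortYearSummary, u: UnitCosts) -> CohortYearSummary:
    """Add the PC program cost per patient to an intervention-year summary.

    Refuses to apply twice (the flag travels with the summary).
    """
    if summary.pc_cost_added:
        raise ValidationError(
            f"PC program cost already added to the {summary.year} summary"
        )
    mean = summary.mean_cost_per_patient + u.pc_cost_per_patient
    return replace(
        summary,
        mean_cost_per_patient=mean,
        overall_cost=mean * summary.n_patients,
        pc_cost_added=True,
    )
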