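"""Reference configuration: the published study conditions.

One place holds every constant of the source analysis — 104 hypertensive
patients followed 2006-2012 through a Brazilian public-health-system
pharmaceutical-care (PC) program, with 2009 the intervention year — so the
desk-scale tables, the synthetic cohort and the probabilistic sensitivity
analysis all draw from the same numbers:

* per-year mean (sd) cost per patient in 2015 USD and the overall cohort cost;
* per-year proportion of patients with controlled blood pressure, and the
  period-level proportions measured on patients observed in all three periods;
* the cost-distribution family per period (log-logistic pre-PC, log-normal in
  the PC year, Weibull post-PC) with the published truncation limits;
* triangular outcome distributions (min, mode=yearly proportion, max);
* the PC program cost per patient-year, the BRL/USD rate, and the
  cost-effectiveness threshold of 3 x GDP per capita.
"""

from __future__ import annotations

from .distributions import DistributionSpec

YEARS: tuple[int, ...] = (2006, 2007, 2008, 2009, 2010, 2011, 2012)

PERIOD_MAP: dict[int, str] = {
    2006: "pre_pc", 2007: "pre_pc", 2008: "pre_pc",
    2009: "pc",
    2010: "post_pc", 2011: "post_pc", 2012: "post_pc",
}
PERIODS: tuple[str, ...] = ("pre_pc", "pc", "post_pc")

N_PATIENTS = 104
N_COMPLETE = 51

# Mean (sd) cost per patient-year, USD-2015, excluding the PC program cost.
COST_MEAN: dict[int, float] = {
    2006: 188.89, 2007: 187.55, 2008: 218.67, 2009: 197.11,
    2010: 208.42, 2011: 224.52, 2012: 211.92,
}
COST_SD: dict[int, float] = {
    2006: 122.60, 2007: 118.00, 2008: 141.10, 2009: 130.20,
    2010: 134.60, 2011: 145.30, 2012: 139.30,
}
# Overall cohort cost per year (mean of complete patients scaled to 104).
OVERALL_COST: dict[int, float] = {
    2006: 19_644.73, 2007: 19_505.39, 2008: 22_741.78, 2009: 20_499.89,
    2010: 21_676.18, 2011: 23_350.38, 2012: 22_039.80,
}

# Proportion of patients with satisfactory blood pressure control (VIII JNC).
OUTCOME_PROP: dict[int, float] = {
    2006: 0.56, 2007: 0.60, 2008: 0.64, 2009: 0.98,
    2010: 0.98, 2011: 0.88, 2012: 0.88,
}
# Period-level proportions, measured on patients with data in all three
# periods; these are inputs, not means of the yearly values.
PERIOD_EFFECT: dict[str, float] = {"pre_pc": 0.544, "pc": 0.982, "post_pc": 0.93}

COST_FAMILY_BY_PERIOD: dict[str, str] = {
    "pre_pc": "log_logistic", "pc": "log_normal", "post_pc": "weibull",
}

# Truncation limits for the cost distributions, USD per patient-year.
COST_TRUNCATION: dict[int, tuple[float, float]] = {
    2006: (7.00, 649.00), 2007: (8.50, 567.10), 2008: (12.80, 610.90),
    2009: (13.70, 560.70),
    2010: (5.90, 591.90), 2011: (4.80, 596.90), 2012: (8.00, 556.80),
}

# Triangular outcome limits (min, max); mode is the yearly proportion.
OUTCOME_TRUNCATION: dict[int, tuple[float, float]] = {
    2006: (0.25, 0.65), 2007: (0.25, 0.69), 2008: (0.25, 0.74),
    2009: (0.92, 1.00),
    2010: (0.92, 1.00), 2011: (0.83, 0.98), 2012: (0.83, 0.98),
}

PC_COST_PER_PATIENT = 210.80       # USD per patient-year, intervention year only
GDP_PER_CAPITA = 10_240.43         # USD, 2015 consolidation
CE_THRESHOLD = 30_721.28           # 3 x GDP per capita as printed
FX_BRL_PER_USD = 3.87


def cost_spec(year: int) -> DistributionSpec:
    """Fitted cost DistributionSpec for one study year (published truncation)."""
    lo, hi = COST_TRUNCATION[year]
    return DistributionSpec(
        family=COST_FAMILY_BY_PERIOD[PERIOD_MAP[year]],
        mean=COST_MEAN[year], sd=COST_SD[year], minimum=lo, maximum=hi,
    ).fit()


def outcome_spec(year: int) -> DistributionSpec:
    """Triangular outcome DistributionSpec for one study year."""
    lo, hi = OUTCOME_TRUNCATION[year]
    return DistributionSpec(
        family="triangular", mean=OUTCOME_PROP[year], minimum=lo,
        maximum=hi, mode=OUTCOME_PROP[year],
    ).fit()


def derive_outcome_truncation(
    props: dict[int, float] | None = None,
    period_map: dict[int, str] | None = None,
    pre_floor: float = 0.25,
) -> dict[int, tuple[float, float]]:
    """Approximate reconstruction of the outcome truncation-limit rule.

    The published limits were derived from descriptive statistics: a 25%
    control floor for the conventional-care years, and the period's highest
    relative variation of the yearly proportions applied around each year's
    value (the intervention year borrows the post-period variation; everything
    is capped at 1 because the outcome is a proportion).  This helper encodes
    that construction with the variation measured as (max - min)/min of the
    period's proportions; its output approximates but is not forced to match
    the published limits, which the source's own rule does not reproduce
    exactly either.
    """
    props = dict(OUTCOME_PROP) if props is None else props
    period_map = dict(PERIOD_MAP) if period_map is None else period_map
    by_period: dict[str, list[float]] = {}
    for y, p in props.items():
        by_period.setdefault(period_map[y], []).append(p)
    variation = {per: (max(v) - min(v)) / min(v) for per, v in by_period.items()}
    if "pc" in variation and "post_pc" in variation:
        variation["pc"] = variation["post_pc"]
    out: dict[int, tuple[float, float]] = {}
    for y, p in props.items():
        per = period_map[y]
        v = variation[per]
        hi = min(round(p * (1 + v), 2), 1.0)
        lo = pre_floor if per == "pre_pc" else round(p * (1 - v), 2)
        out[y] = (lo, hi)
    return out


def year_cost_specs() -> dict[int, DistributionSpec]:
    return {y: cost_spec(y) for y in YEARS}


def year_outcome_specs() -> dict[int, DistributionSpec]:
    return {y: outcome_spec(y) for y in YEARS}
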