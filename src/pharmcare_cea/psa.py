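"""Monte Carlo probabilistic sensitivity analysis (PSA).

Each iteration draws one cost per study year from its truncated parametric
distribution and one controlled-blood-pressure proportion from its triangular
distribution (all draws independent, as in the source analysis), adds the PC
program cost to intervention-year cost draws, averages years into period
costs/effects, and propagates to per-period CERs, CER differences against the
baseline period, and period ICERs.  Draws with a zero effect difference leave
the ICER undefined; they are excluded from ICER summaries and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import study
from .distributions import DistributionSpec, triangular_sample, truncated_sample
from .errors import ValidationError

__all__ = ["PSAConfig", "PSAResult", "run_psa"]


@dataclass
class PSAConfig:
    """Inputs of one PSA run; defaults are the published study conditions."""

    seed: int
    iterations: int = 10_000
    year_cost_specs: Mapping[int, DistributionSpec] = field(
        default_factory=study.year_cost_specs)
    year_outcome_specs: Mapping[int, DistributionSpec] = field(
        default_factory=study.year_outcome_specs)
    period_map: Mapping[int, str] = field(default_factory=lambda: dict(study.PERIOD_MAP))
    pc_cost_per_patient: float = study.PC_COST_PER_PATIENT

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be at least 1")
        for y in self.period_map:
            if y not in self.year_cost_specs:
                raise ValidationError(f"year {y} has no cost spec")
            if y not in self.year_outcome_specs:
                raise ValidationError(f"year {y} has no outcome spec")


@dataclass
class PSAResult:
    """Per-iteration draws plus their summaries.

    ``draws`` columns: cost_<period>, effect_<period>, cer_<period>,
    cer_diff_<period> and icer_<period> for each non-baseline period (NaN where
    undefined).  ``summary`` maps quantity -> {mean, min, max, p_positive,
    p_negative}; sign probabilities are over defined draws.
    """

    baseline_period: str
    draws: pd.DataFrame
    summary: dict[str, dict[str, float]]
    n_undefined_icer: dict[str, int]


def _summarize(values: np.ndarray) -> dict[str, float]:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {"mean": float("nan"), "min": float("nan"), "max": float("nan"),
                "p_positive": float("nan"), "p_negative": float("nan")}
    return {
        "mean": float(v.mean()), "min": float(v.min()), "max": float(v.max()),
        "p_positive": float((v > 0).mean()), "p_negative": float((v < 0).mean()),
    }


def run_psa(config: PSAConfig, baseline_period: str = "pre_pc") -> PSAResult:
    """Run the Monte Carlo propagation; bit-reproducible for a fixed seed."""
    periods = list(dict.fromkeys(config.period_map.values()))
    if baseline_period not in periods:
        raise ValidationError(f"baseline period {baseline_period!r} not in period map")
    rng = np.random.default_rng(config.seed)
    n = config.iterations

    cost_draws: dict[int, np.ndarray] = {}
    effect_draws: dict[int, np.ndarray] = {}
    for year in sorted(config.period_map):
        try:
            cost = truncated_sample(config.year_cost_specs[year], n, rng)
            eff = config.year_outcome_specs[year]
            effect = (np.full(n, float(eff.mean)) if eff.family == "degenerate"
                      else triangular_sample(eff, n, rng))
        except ValidationError as exc:
            raise ValidationError(f"year {year}: {exc}") from exc
        if config.period_map[year] == "pc":
            cost = cost + config.pc_cost_per_patient
        cost_draws[year] = cost
        effect_draws[year] = np.clip(effect, 0.0, 1.0)

    data: dict[str, np.ndarray] = {}
    for period in periods:
        years = [y for y, p in config.period_map.items() if p == period]
        data[f"cost_{period}"] = np.mean([cost_draws[y] for y in years], axis=0)
        data[f"effect_{period}"] = np.mean([effect_draws[y] for y in years], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            data[f"cer_{period}"] = np.where(
                data[f"effect_{period}"] > 0,
                data[f"cost_{period}"] / data[f"effect_{period}"], np.nan)

    n_undefined: dict[str, int] = {}
    for period in periods:
        if period == baseline_period:
            continue
        data[f"cer_diff_{period}"] = data[f"cer_{period}"] - data[f"cer_{baseline_period}"]
        dc = data[f"cost_{period}"] - data[f"cost_{baseline_period}"]
        de = data[f"effect_{period}"] - data[f"effect_{baseline_period}"]
        defined = de != 0
        icer = np.full(n, np.nan)
        icer[defined] = dc[defined] / de[defined]
        data[f"icer_{period}"] = icer
        n_undefined[period] = int(n - defined.sum())

    draws = pd.DataFrame(data)
    summary = {name: _summarize(draws[name].to_numpy())
               for name in draws.columns if not name.startswith(("cost_", "effect_"))}
    return PSAResult(
        baseline_period=baseline_period, draws=draws,
        summary=summary, n_undefined_icer=n_undefined,
    )
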