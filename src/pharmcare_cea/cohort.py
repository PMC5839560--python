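"""Synthetic patient-year cohort generator.

Emulates the statistical structure of the study data: per-year per-patient
total costs drawn from truncated parametric distributions, cost components
split from the total by configurable shares, a binary controlled-blood-pressure
outcome per patient-year, and the missing-data pattern in which only a subset
of patients has complete cost records (51 of 104 in the source study).

Only totals drive the downstream analysis; the component split exists so that
records look like real costing data and re-sum exactly to their totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import study
from .distributions import DistributionSpec, truncated_sample
from .errors import ValidationError

__all__ = [
    "CohortConfig",
    "PatientYearCost",
    "OutcomeRecord",
    "generate_cohort",
    "apply_missingness",
    "costs_to_frame",
    "outcomes_to_frame",
    "write_cohort_csv",
    "read_costs_csv",
    "read_outcomes_csv",
]

COMPONENTS = (
    "lab_tests", "primary_care", "emergency_care", "specialized_care",
    "medications", "transport", "absenteeism",
)

#: Default split of the per-patient total across cost components.  The source
#: analysis never reports shares (only totals enter the CEA); these keep every
#: component nonzero and summing to 1.
DEFAULT_COMPONENT_SHARES: dict[str, float] = {
    "medications": 0.35, "primary_care": 0.20, "specialized_care": 0.15,
    "emergency_care": 0.10, "lab_tests": 0.08, "transport": 0.05,
    "absenteeism": 0.07,
}


@dataclass(frozen=True)
class PatientYearCost:
    """One patient's cost components (USD) for one calendar year."""

    patient_id: int
    year: int
    lab_tests: float
    primary_care: float
    emergency_care: float
    specialized_care: float
    medications: float
    transport: float
    absenteeism: float
    pc_program: float
    total: float

    def __post_init__(self) -> None:
        parts = [getattr(self, c) for c in COMPONENTS] + [self.pc_program]
        if any(p < 0 for p in parts):
            raise ValidationError("cost components must be non-negative")
        if abs(sum(parts) - self.total) > 1e-9 * max(1.0, self.total):
            raise ValidationError("total must equal the sum of its components")


@dataclass(frozen=True)
class OutcomeRecord:
    """Blood-pressure control status (VIII JNC cutoffs) for one patient-year."""

    patient_id: int
    year: int
    controlled: bool


@dataclass
class CohortConfig:
    """Study-shaped cohort: sizes, periods, cost specs and outcome proportions."""

    seed: int
    n_patients: int = study.N_PATIENTS
    n_complete: int = study.N_COMPLETE
    years: Sequence[int] = study.YEARS
    period_map: Mapping[int, str] = field(default_factory=lambda: dict(study.PERIOD_MAP))
    cost_specs: Mapping[int, DistributionSpec] = field(default_factory=study.year_cost_specs)
    outcome_props: Mapping[int, float] = field(default_factory=lambda: dict(study.OUTCOME_PROP))
    component_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_SHARES))
    component_jitter_sd: float = 0.10  # lognormal sd of the multiplicative split noise
    outcome_persistence: float = 0.0   # P(repeat last year's state) before a fresh draw

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be at least 1")
        if not 0 <= self.n_complete <= self.n_patients:
            raise ValidationError("need 0 <= n_complete <= n_patients")
        for y in self.years:
            if y not in self.period_map:
                raise ValidationError(f"year {y} has no period label")
            if y not in self.cost_specs:
                raise ValidationError(f"year {y} has no cost spec")
            p = self.outcome_props.get(y)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValidationError(f"year {y} outcome proportion must lie in [0, 1]")
        share_sum = sum(self.component_shares.values())
        if abs(share_sum - 1.0) > 1e-9:
            raise ValidationError(f"component shares must sum to 1, got {share_sum}")
        if not 0.0 <= self.outcome_persistence <= 1.0:
            raise ValidationError("outcome_persistence must lie in [0, 1]")


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientYearCost], list[OutcomeRecord]]:
    """Draw the full cohort (no missingness yet); reproducible for a fixed seed.

    Totals come from each year's truncated cost distribution; components are the
    configured shares with multiplicative log-normal jitter renormalised so they
    re-sum to the total exactly.  Outcomes are Bernoulli draws whose expectation
    is the year's proportion (optionally with within-patient persistence).
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.component_shares)
    shares = np.array([config.component_shares[c] for c in names])
    costs: list[PatientYearCost] = []
    outcomes: list[OutcomeRecord] = []
    prev_state: np.ndarray | None = None
    n = config.n_patients

    for year in config.years:
        totals = truncated_sample(config.cost_specs[year], n, rng)
        jitter = rng.lognormal(0.0, config.component_jitter_sd, size=(n, len(names)))
        w = shares * jitter
        w /= w.sum(axis=1, keepdims=True)
        comp = w * totals[:, None]
        # exact re-sum: put any float residue on the largest component
        comp[np.arange(n), comp.argmax(axis=1)] += totals - comp.sum(axis=1)

        p = config.outcome_props[year]
        fresh = rng.random(n) < p
        if prev_state is not None and config.outcome_persistence > 0:
            keep = rng.random(n) < config.outcome_persistence
            state = np.where(keep, prev_state, fresh)
        else:
            state = fresh
        prev_state = state

        for i in range(n):
            by_name = dict(zip(names, comp[i]))
            costs.append(PatientYearCost(
                patient_id=i, year=year,
                pc_program=0.0, total=float(totals[i]),
                **{c: float(by_name[c]) for c in COMPONENTS},
            ))
            outcomes.append(OutcomeRecord(patient_id=i, year=year,
                                          controlled=bool(state[i])))
    return costs, outcomes


def apply_missingness(
    records: Iterable[PatientYearCost], config: CohortConfig
) -> list[PatientYearCost]:
    """Keep full cost data for ``n_complete`` patients; truncate the rest.

    Each incomplete patient loses a randomly chosen suffix of study years from
    their cost rows (dropout-style missingness); outcome records are untouched.
    """
    records = list(records)
    ids = sorted({r.patient_id for r in records})
    if config.n_complete > len(ids):
        raise ValidationError(
            f"n_complete={config.n_complete} exceeds the {len(ids)} distinct patients"
        )
    if config.n_complete == len(ids):
        return records
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    complete = set(rng.choice(ids, size=config.n_complete, replace=False).tolist())
    years = sorted(config.years)
    cutoff = {
        pid: years[len(years) - int(rng.integers(1, len(years) + 1))]
        for pid in ids if pid not in complete
    }
    return [r for r in records
            if r.patient_id in complete or r.year < cutoff[r.patient_id]]


# -- delimited-text I/O ----------------------------------------------------

COST_COLUMNS = ["patient_id", "year", *COMPONENTS, "pc_program", "total"]
OUTCOME_COLUMNS = ["patient_id", "year", "controlled"]


def costs_to_frame(records: Iterable[PatientYearCost]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=COST_COLUMNS)


def outcomes_to_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=OUTCOME_COLUMNS)
    df["controlled"] = df["controlled"].astype(int)
    return df


def write_cohort_csv(
    costs: Iterable[PatientYearCost],
    outcomes: Iterable[OutcomeRecord],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cost_path, outcome_path = out / "costs.csv", out / "outcomes.csv"
    costs_to_frame(costs).to_csv(cost_path, index=False)
    outcomes_to_frame(outcomes).to_csv(outcome_path, index=False)
    return cost_path, outcome_path


def read_costs_csv(path: str | Path) -> list[PatientYearCost]:
    df = pd.read_csv(path)
    return [PatientYearCost(**{k: (int(v) if k in ("patient_id", "year") else float(v))
                               for k, v in row.items()})
            for row in df[COST_COLUMNS].to_dict("records")]


def read_outcomes_csv(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path)
    return [OutcomeRecord(patient_id=int(r["patient_id"]), year=int(r["year"]),
                          controlled=bool(r["controlled"]))
            for r in df[OUTCOME_COLUMNS].to_dict("records")]
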