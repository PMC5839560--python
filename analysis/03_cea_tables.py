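"""Deterministic cost-effectiveness analysis from the reference inputs.

Recomputes, at desk scale, the yearly CER row, the ICER rows against each
conventional-care baseline year, the period-level CER/ICER with dominance
labels and the 3 x GDP-per-capita threshold check, the cost-effectiveness
plane, and Cochran's Q on the simulated cohort's period outcomes.  Writes
results/cea_yearly.csv, results/cea_period.csv, results/ce_plane.csv and
results/ce_plane.png.
"""

import argparse
from pathlib import Path

from pharmcare_cea import study
from pharmcare_cea.cea import (ThresholdConfig, ce_plane, cochran_q,
                               period_outcome_matrix)
from pharmcare_cea.cohort import outcomes_to_frame, read_outcomes_csv
from pharmcare_cea.plots import plot_ce_plane
from pharmcare_cea.report import (period_cea_table,
                                  reference_period_strategies,
                                  reference_year_strategies, yearly_cea_table)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    parser.add_argument("--cohort-dir", default="results/cohort",
                        help="Cohort for the Cochran-Q test (optional).")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    thr = ThresholdConfig()
    strategies = reference_year_strategies()
    periods = reference_period_strategies()

    yearly = yearly_cea_table(strategies, threshold=thr)
    period = period_cea_table(periods, threshold=thr)
    plane = ce_plane(
        [(strategies[y], strategies[base]) for base in (2006, 2008)
         for y in (2009, 2010, 2011, 2012)]
        + [(periods["pc"], periods["pre_pc"]),
           (periods["post_pc"], periods["pre_pc"])],
        thr,
    )
    yearly.to_csv(out / "cea_yearly.csv")
    period.to_csv(out / "cea_period.csv")
    plane.to_csv(out / "ce_plane.csv", index=False)
    plot_ce_plane(plane, out / "ce_plane.png")

    print("Period-level analysis (costs USD/patient-year):")
    print(period.to_string(float_format=lambda v: f"{v:.2f}"))
    print("\nYearly table:")
    print(yearly.to_string(float_format=lambda v: f"{v:.2f}"))
    dominant = plane[plane["dominance"] == "dominant"]
    pairs = [f"{r['label']} vs {r['base']}" for _, r in dominant.iterrows()]
    print(f"\ndominant comparisons: {pairs or 'none'}; every comparison below "
          f"the threshold of {thr.threshold:,.2f} USD: "
          f"{bool(plane['below_threshold'].all())}")

    outcomes_path = Path(args.cohort_dir) / "outcomes.csv"
    if outcomes_path.exists():
        frame = outcomes_to_frame(read_outcomes_csv(outcomes_path))
        q = cochran_q(period_outcome_matrix(frame, study.PERIOD_MAP))
        print(f"Cochran Q on simulated period outcomes: {q.statistic:.2f} "
              f"(df {q.df}), significant at 5%: {q.significant}")
    print(f"wrote {out / 'cea_yearly.csv'}, {out / 'cea_period.csv'}, "
          f"{out / 'ce_plane.csv'}")


if __name__ == "__main__":
    main()
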