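"""Plot writers: cost-effectiveness plane, INB sweep, PSA histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .inb import WTPSweep
from .psa import PSAResult

__all__ = ["plot_ce_plane", "plot_inb_sweep", "plot_psa_histograms"]


def plot_ce_plane(plane: pd.DataFrame, path: str | Path) -> Path:
    """Δeffect vs Δcost scatter with quadrant axes and dominance labels."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for dom, group in plane.groupby("dominance"):
        ax.scatter(group["delta_effect"], group["delta_cost"], label=dom)
    for _, r in plane.iterrows():
        ax.annotate(r["label"], (r["delta_effect"], r["delta_cost"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Δ effectiveness (proportion controlled)")
    ax.set_ylabel("Δ cost (USD per patient-year)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(fontsize=8)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_inb_sweep(sweeps: dict[str, WTPSweep], path: str | Path) -> Path:
    """INB vs willingness-to-pay for each comparison, with the zero line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sweep in sweeps.items():
        ax.plot(sweep.lambdas, sweep.inb_values, label=label)
        if sweep.break_even_lambda is not None and sweep.break_even_in_range:
            ax.axvline(sweep.break_even_lambda, ls=":", lw=0.8)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("willingness to pay λ (USD per controlled patient-year)")
    ax.set_ylabel("incremental net benefit (USD)")
    ax.legend()
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_psa_histograms(result: PSAResult, out_dir: str | Path) -> list[Path]:
    """One histogram per CER-difference / ICER quantity in the PSA draws."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    cols = [c for c in result.draws.columns
            if c.startswith(("cer_diff_", "icer_"))]
    for col in cols:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        values = result.draws[col].dropna()
        ax.hist(values, bins=60)
        ax.axvline(0, color="grey", lw=0.8)
        s = result.summary[col]
        ax.set_title(f"{col}: mean {s['mean']:.2f}, "
                     f"P(>0) {s['p_positive']:.1%}", fontsize=9)
        ax.set_xlabel("USD")
        p = out / f"psa_{col}.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
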