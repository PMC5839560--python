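"""Incremental net benefit (INB) and willingness-to-pay sweeps.

INB(λ) = λ·ΔE − ΔC: the monetary benefit, at willingness-to-pay λ per extra
controlled patient-year, of adopting the new strategy.  It is affine in λ and
crosses zero at λ = ICER when the effect gain is positive, so the one-way
sensitivity analysis reduces to evaluating the line over a λ grid from $1 up
to the cost-effectiveness threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cea import CEComparison
from .errors import ValidationError

__all__ = ["WTPSweep", "inb", "wtp_sweep"]


@dataclass(frozen=True)
class WTPSweep:
    """INB evaluated over a willingness-to-pay grid.

    ``break_even_lambda`` is ΔC/ΔE (the ICER) when ΔE > 0, else None;
    ``break_even_in_range`` says whether it falls inside the grid.
    """

    lambdas: np.ndarray
    inb_values: np.ndarray
    comparison: CEComparison
    break_even_lambda: float | None
    break_even_in_range: bool


def inb(wtp: float, comparison: CEComparison) -> float:
    """Incremental net benefit at one willingness-to-pay value."""
    return wtp * comparison.delta_effect - comparison.delta_cost


def wtp_sweep(
    lambda_min: float,
    lambda_max: float,
    n_points: int,
    comparison: CEComparison,
    log_spaced: bool = False,
) -> WTPSweep:
    """Evaluate INB on an evenly spaced λ grid inclusive of both endpoints.

    The break-even λ is computed in closed form (ΔC/ΔE), never searched.  A
    log-spaced grid is available for plots spanning several orders of
    magnitude; both endpoints must then be positive.
    """
    if not lambda_min < lambda_max:
        raise ValidationError("need lambda_min < lambda_max")
    if n_points < 2:
        raise ValidationError("need at least two grid points")
    if log_spaced:
        if lambda_min <= 0:
            raise ValidationError("log-spaced grid needs lambda_min > 0")
        lambdas = np.geomspace(lambda_min, lambda_max, n_points)
    else:
        lambdas = np.linspace(lambda_min, lambda_max, n_points)
    values = lambdas * comparison.delta_effect - comparison.delta_cost
    if comparison.delta_effect > 0:
        break_even = comparison.delta_cost / comparison.delta_effect
        in_range = lambda_min <= break_even <= lambda_max
    else:
        break_even, in_range = None, False
    return WTPSweep(
        lambdas=lambdas, inb_values=values, comparison=comparison,
        break_even_lambda=break_even, break_even_in_range=in_range,
    )
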