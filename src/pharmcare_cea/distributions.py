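"""Parametric cost/outcome distributions for the sensitivity analysis.

Cost distributions (log-logistic, log-normal, Weibull) are recovered from a
reported mean and standard deviation by method of moments, because patient-level
data behind the published fits is not available.  Sampling is restricted to a
plausible range by inverse-CDF truncation: draw u ~ Uniform(F(a), F(b)) and
return F^{-1}(u), which keeps the draw count deterministic and seed-stable.
Outcome (proportion-controlled) distributions are triangular, parameterised by
minimum / mode / maximum.

Family selection mirrors standard practice: fit every candidate family by
moments and rank by the Anderson-Darling statistic (lower = better fit; the
statistic only, no p-values).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import UndefinedResultError, ValidationError

__all__ = [
    "DistributionSpec",
    "fit_lognormal_moments",
    "fit_weibull_moments",
    "fit_loglogistic_moments",
    "ad_statistic",
    "select_family",
    "truncated_sample",
    "triangular_sample",
]

COST_FAMILIES = ("log_logistic", "log_normal", "weibull")

_PCLIP = 1e-12  # probability clamp for log-CDF evaluations


@dataclass
class DistributionSpec:
    """Family + moments + truncation bounds for one year's cost or outcome.

    ``params`` holds the family-native parameters after fitting and is filled
    lazily by :meth:`fit`.  ``sd`` is ignored for triangular specs; ``mode``
    is only meaningful for triangular specs.
    """

    family: str
    mean: float
    sd: float | None = None
    minimum: float = 0.0
    maximum: float = math.inf
    mode: float | None = None
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.minimum < self.maximum or self.family == "degenerate"
                or (self.family == "triangular" and self.minimum == self.maximum)):
            raise ValidationError(
                f"truncation bounds must satisfy min < max, got "
                f"[{self.minimum}, {self.maximum}]"
            )
        if self.family == "triangular":
            m = self.mode if self.mode is not None else self.mean
            if not (self.minimum <= m <= self.maximum):
                raise ValidationError(
                    f"triangular spec needs min <= mode <= max, got "
                    f"({self.minimum}, {m}, {self.maximum})"
                )
        elif self.family not in COST_FAMILIES and self.family != "degenerate":
            raise ValidationError(f"unknown distribution family {self.family!r}")

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "DistributionSpec":
        """Fill ``params`` by moment inversion; returns self for chaining."""
        if self.params:
            return self
        if self.family == "degenerate" or (self.sd is not None and self.sd == 0):
            self.params = {"value": float(self.mean)}
        elif self.family == "log_normal":
            self.params = fit_lognormal_moments(self.mean, self.sd)
        elif self.family == "weibull":
            self.params = fit_weibull_moments(self.mean, self.sd)
        elif self.family == "log_logistic":
            self.params = fit_loglogistic_moments(self.mean, self.sd)
        elif self.family == "triangular":
            m = self.mode if self.mode is not None else self.mean
            self.params = {"minimum": self.minimum, "mode": m, "maximum": self.maximum}
        return self

    def frozen(self):
        """Frozen scipy distribution (untruncated) for the fitted family."""
        self.fit()
        p = self.params
        if self.family == "log_normal":
            return stats.lognorm(s=p["scale"], scale=math.exp(p["location"]))
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "log_logistic":
            return stats.fisk(c=p["shape"], scale=p["scale"])
        if self.family == "triangular":
            span = p["maximum"] - p["minimum"]
            if span == 0:
                raise UndefinedResultError("degenerate triangular has no scipy frozen form")
            return stats.triang(
                c=(p["mode"] - p["minimum"]) / span, loc=p["minimum"], scale=span
            )
        raise UndefinedResultError("degenerate spec has no continuous distribution")

    @property
    def is_degenerate(self) -> bool:
        return self.family == "degenerate" or (self.sd is not None and self.sd == 0)

    def with_bounds(self, minimum: float, maximum: float) -> "DistributionSpec":
        return replace(self, minimum=minimum, maximum=maximum)


def fit_lognormal_moments(mean: float, sd: float) -> dict[str, float]:
    """(location, scale) of the underlying normal from the log-normal mean/sd.

    scale^2 = ln(1 + sd^2/mean^2), location = ln(mean) - scale^2/2.
    """
    if mean <= 0 or sd is None or sd <= 0:
        raise ValidationError("log-normal moment fit needs mean > 0 and sd > 0")
    s2 = math.log1p((sd / mean) ** 2)
    return {"location": math.log(mean) - s2 / 2.0, "scale": math.sqrt(s2)}


def _weibull_cv2(shape: float) -> float:
    # Gamma(1+2/k)/Gamma(1+1/k)^2 - 1, via lgamma for numerical range
    return math.exp(math.lgamma(1 + 2 / shape) - 2 * math.lgamma(1 + 1 / shape)) - 1


def fit_weibull_moments(mean: float, sd: float) -> dict[str, float]:
    """Weibull (shape k, scale lambda) matching mean and sd.

    k solves cv^2 = Gamma(1+2/k)/Gamma(1+1/k)^2 - 1 (strictly decreasing in k),
    then lambda = mean / Gamma(1+1/k).
    """
    if mean <= 0 or sd is None or sd <= 0:
        raise ValidationError("Weibull moment fit needs mean > 0 and sd > 0")
    cv2 = (sd / mean) ** 2
    lo, hi = 0.05, 500.0
    if not (_weibull_cv2(hi) <= cv2 <= _weibull_cv2(lo)):
        raise ValidationError(f"coefficient of variation {math.sqrt(cv2):.4g} outside "
                              "the supported Weibull range")
    shape = optimize.brentq(lambda k: _weibull_cv2(k) - cv2, lo, hi, xtol=1e-12, rtol=1e-15)
    scale = mean / math.gamma(1 + 1 / shape)
    return {"shape": shape, "scale": scale}


def _loglogistic_cv2(beta: float) -> float:
    # cv^2 = 2 sin^2(b) / (b sin 2b) - 1 with b = pi/beta; finite for beta > 2
    b = math.pi / beta
    return 2 * math.sin(b) ** 2 / (b * math.sin(2 * b)) - 1


def fit_loglogistic_moments(mean: float, sd: float) -> dict[str, float]:
    """Log-logistic (scale alpha, shape beta) matching mean and sd.

    With b = pi/beta: mean = alpha*b/sin(b) and
    var = alpha^2 (2b/sin 2b - b^2/sin^2 b); a finite variance needs beta > 2.
    """
    if mean <= 0 or sd is None or sd <= 0:
        raise ValidationError("log-logistic moment fit needs mean > 0 and sd > 0")
    cv2 = (sd / mean) ** 2
    lo, hi = 2.0 + 1e-9, 1e7
    if not (_loglogistic_cv2(hi) <= cv2 <= _loglogistic_cv2(lo)):
        raise ValidationError(f"coefficient of variation {math.sqrt(cv2):.4g} too large "
                              "for a finite-variance log-logistic")
    beta = optimize.brentq(lambda x: _loglogistic_cv2(x) - cv2, lo, hi, xtol=1e-12, rtol=1e-15)
    b = math.pi / beta
    alpha = mean * math.sin(b) / b
    return {"shape": beta, "scale": alpha}


def ad_statistic(sample: Sequence[float], spec: DistributionSpec) -> float:
    """Anderson-Darling A^2 of ``sample`` against the fitted untruncated CDF.

    A^2 = -n - (1/n) sum_{i=1..n} (2i-1) [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))].
    CDF values are clamped to [1e-12, 1 - 1e-12] so boundary points cannot
    produce infinities.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise ValidationError(f"Anderson-Darling needs at least 8 observations, got {n}")
    F = np.clip(spec.frozen().cdf(x), _PCLIP, 1 - _PCLIP)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log1p(-F[::-1]))))


def select_family(
    sample: Sequence[float], candidates: Sequence[str] = COST_FAMILIES
) -> tuple[str, dict[str, float]]:
    """Moment-fit every candidate family to the sample and rank by A^2.

    Returns ``(best_family, {family: A^2})``; the argmin wins, with ties (within
    1e-12) broken by input order.
    """
    if len(candidates) < 1:
        raise ValidationError("select_family needs at least one candidate family")
    x = np.asarray(sample, dtype=float)
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    table: dict[str, float] = {}
    for fam in candidates:
        try:
            spec = DistributionSpec(family=fam, mean=mean, sd=sd).fit()
            table[fam] = ad_statistic(x, spec)
        except (ValidationError, UndefinedResultError):
            continue
    if not table:
        raise ValidationError("no candidate family could be fitted to the sample")
    lowest = min(table.values())
    tied = [f for f in candidates if f in table and table[f] <= lowest + 1e-12]
    if len(tied) > 1:
        logging.getLogger(__name__).info(
            "Anderson-Darling tie between %s; keeping %s (input order)", tied, tied[0]
        )
    return tied[0], table


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def truncated_sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Draw n values from ``spec`` restricted to [minimum, maximum].

    Inverse-CDF restriction: u ~ Uniform(F(a), F(b)), x = F^{-1}(u).  Every
    draw lies inside the bounds by construction.  ``seed`` may be an int or a
    numpy Generator (shared streams keep multi-year simulations reproducible).
    """
    rng = _as_rng(seed)
    if spec.is_degenerate:
        return np.full(n, float(spec.mean))
    dist = spec.frozen()
    fa, fb = float(dist.cdf(spec.minimum)), float(dist.cdf(spec.maximum))
    if not fb > fa:
        raise ValidationError(
            f"no probability mass inside truncation bounds [{spec.minimum}, {spec.maximum}]"
        )
    u = rng.uniform(fa, fb, size=n)
    x = dist.ppf(u)
    return np.clip(x, spec.minimum, spec.maximum)


def triangular_sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Draw n values from a triangular spec; min = max collapses to a constant."""
    rng = _as_rng(seed)
    spec.fit()
    lo, mode, hi = spec.minimum, spec.params.get("mode", spec.mean), spec.maximum
    if lo == hi:
        return np.full(n, float(lo))
    return rng.triangular(lo, mode, hi, size=n)
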