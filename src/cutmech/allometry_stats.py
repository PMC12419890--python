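"""Power-law scaling fits on log10-transformed data and group contrasts.

Scaling relationships between a response variable and body mass are fitted as
ordinary least squares on log10-log10 axes (slope = scaling exponent), the
field's standard convention for allometry.  Group contrasts are summarized as
ratios of means with seeded percentile-bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import InvalidInputError

__all__ = ["PowerLawFit", "GroupRatio", "fit_power_law", "group_force_ratio"]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) = log10(prefactor) + exponent * log10(x)."""

    exponent: float
    prefactor: float  # units of y at x = 1
    exponent_ci: tuple[float, float]  # 95% t-interval on the slope
    exponent_se: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        lo, hi = self.exponent_ci
        if not lo <= self.exponent <= hi:
            raise InvalidInputError("exponent must lie within its CI")
        if self.n < 3:
            raise InvalidInputError("power-law fit needs n >= 3")


@dataclass(frozen=True)
class GroupRatio:
    """Ratio of group means with a percentile bootstrap interval."""

    ratio: float
    ci: tuple[float, float]
    n_a: int
    n_b: int
    n_boot: int


def _validate_positive(values: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise InvalidInputError(
            f"{label} must be strictly positive; offending indices: {bad.tolist()}"
        )
    return arr


def fit_power_law(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> PowerLawFit:
    """Fit y = prefactor * x**exponent by OLS on log10-transformed data.

    The exponent CI is the standard t-interval on the regression slope.
    Rescaling x or y by positive constants changes only the prefactor.
    """
    x = _validate_positive(x, "x")
    y = _validate_positive(y, "y")
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InvalidInputError(f"need n >= 3 points, got {x.size}")

    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(ly) == 0.0:  # constant response: exponent exactly zero
        return PowerLawFit(
            exponent=0.0, prefactor=float(y[0]), exponent_ci=(0.0, 0.0),
            exponent_se=0.0, r_squared=1.0, n=int(x.size),
        )
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    slope = float(res.params[1])
    lo, hi = (float(v) for v in res.conf_int(alpha=1 - ci_level)[1])
    r2 = float(res.rsquared)
    if not np.isfinite(r2):  # constant y: zero total variance, perfect fit
        r2 = 1.0
    return PowerLawFit(
        exponent=slope,
        prefactor=float(10.0 ** res.params[0]),
        exponent_ci=(lo, hi),
        exponent_se=float(res.bse[1]),
        r_squared=r2,
        n=int(x.size),
    )


def group_force_ratio(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_boot: int = 2000,
    ci_level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> GroupRatio:
    """Ratio mean(a)/mean(b) with a seeded percentile bootstrap interval."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be nonempty")
    mb = float(b.mean())
    if mb == 0:
        raise InvalidInputError("mean of group_b is zero; ratio undefined")
    ratio = float(a.mean()) / mb

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = gen.choice(a, size=a.size, replace=True).mean()
        rb = gen.choice(b, size=b.size, replace=True).mean()
        boots[i] = ra / rb if rb != 0 else np.nan
    alpha = 1 - ci_level
    lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return GroupRatio(
        ratio=ratio, ci=(float(lo), float(hi)), n_a=a.size, n_b=b.size, n_boot=n_boot
    )
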