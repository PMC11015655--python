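"""Effect-size container shared by every model in the package.

An :class:`Estimate` carries a point estimate (a regression beta in SD units,
or a log odds ratio), its standard error, confidence bounds, and both one- and
two-tailed p-values.  The one-tailed p is always taken in the *registered*
direction of the hypothesis the estimate serves (``negative`` for the
depression analyses: earlier menarche, more symptoms), which is why the
direction is metadata on the estimate rather than an argument to each test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy import stats

__all__ = ["Estimate"]

_SCALES = ("beta", "log_or")
_UNITS = ("per_year", "per_sd")
_DIRECTIONS = ("negative", "positive", "two_sided")


@dataclass
class Estimate:
    """A point estimate with its uncertainty and scale metadata.

    Parameters
    ----------
    theta_hat:
        Effect size: beta (SD units of the outcome per unit of exposure)
        when ``scale == "beta"``, or a log odds ratio when
        ``scale == "log_or"``.
    se:
        Standard error of ``theta_hat``; must be positive.
    n:
        Number of observations (or SNPs, for summary-data estimators).
    df:
        Degrees of freedom for t-based intervals; ``None`` means normal.
    direction:
        Registered direction of the hypothesis; sets the one-tailed p.
        For ``two_sided`` the one-tailed p is the tail on the side of the
        point estimate (i.e. half the two-tailed p).
    """

    theta_hat: float
    se: float
    n: int
    scale: str = "beta"
    exposure_unit: str = "per_year"
    direction: str = "two_sided"
    level: float = 0.95
    df: float | None = None
    adjusted_for: tuple[str, ...] = ()
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p_one: float = field(init=False)
    p_two: float = field(init=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta_hat):
            raise ValueError("theta_hat must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError("se must be positive and finite")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.exposure_unit not in _UNITS:
            raise ValueError(f"unknown exposure unit {self.exposure_unit!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        dist = stats.norm if self.df is None else stats.t(self.df)
        z = self.theta_hat / self.se
        crit = dist.ppf(0.5 + self.level / 2.0)
        self.ci_low = self.theta_hat - crit * self.se
        self.ci_high = self.theta_hat + crit * self.se
        self.p_two = min(1.0, 2.0 * dist.sf(abs(z)))
        if self.direction == "negative":
            self.p_one = dist.cdf(z)
        elif self.direction == "positive":
            self.p_one = dist.sf(z)
        else:
            self.p_one = dist.sf(abs(z))
        # p-values of exactly 0 underflow; clamp to the smallest positive float
        tiny = 5e-324
        self.p_one = max(self.p_one, tiny)
        self.p_two = max(self.p_two, tiny)

    @property
    def odds_ratio(self) -> float:
        """exp(theta_hat); only meaningful on the log-OR scale."""
        if self.scale != "log_or":
            raise ValueError("odds_ratio is defined on the log_or scale only")
        return math.exp(self.theta_hat)

    def with_(self, **changes) -> "Estimate":
        """Return a copy with fields replaced (CI/p recomputed)."""
        return replace(self, **changes)
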