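"""Geometric population growth: rate estimation, projection, doubling time.

The model is constant compound growth, P_t = P_0 (1 + r/100)^t, with r in
percent per year.  Rates are exchanged in percent everywhere ("per year
per 100 people"); conversion to a multiplicative factor happens once,
inside these functions.  Projections carry full floating-point precision;
rounding to whole persons is a reporting concern, applied by callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import GrowthDomainError

STRATA = ("total", "age_65_plus")


@dataclass(frozen=True)
class GrowthRate:
    """An annual geometric growth rate, in percent per year, observed or
    assumed over ``[period_start, period_end]`` for one population stratum."""

    rate: float
    period_start: int
    period_end: int
    stratum: str = "total"

    def __post_init__(self) -> None:
        if self.period_end <= self.period_start:
            raise GrowthDomainError("period_end must exceed period_start")
        if self.rate <= -100.0:
            raise GrowthDomainError("rate must exceed -100 percent/year")

    @property
    def years(self) -> int:
        return self.period_end - self.period_start


def geometric_growth_rate(
    p_start: float,
    p_end: float,
    years: float,
    *,
    period_start: int = 0,
    stratum: str = "total",
) -> GrowthRate:
    """Annual geometric growth rate between two counts ``years`` apart:

        r = 100 * ((p_end / p_start)^(1/years) - 1)

    Exact inverse of :func:`project`.
    """
    if p_start <= 0 or p_end <= 0:
        raise GrowthDomainError("populations must be positive")
    if years <= 0:
        raise GrowthDomainError("duration must be positive")
    rate = 100.0 * ((p_end / p_start) ** (1.0 / years) - 1.0)
    return GrowthRate(
        rate=rate,
        period_start=period_start,
        period_end=period_start + round(years),
        stratum=stratum,
    )


def project(p0: float, rate: GrowthRate | float, years: float) -> float:
    """Project ``p0`` forward ``years`` years at constant rate:
    ``p0 * (1 + rate/100)**years``.

    ``rate`` may be a :class:`GrowthRate` or a bare percent-per-year
    number.  Returns full precision; round only when reporting.
    """
    r = rate.rate if isinstance(rate, GrowthRate) else float(rate)
    if p0 < 0:
        raise GrowthDomainError("p0 must be non-negative")
    if r <= -100.0:
        raise GrowthDomainError("rate must exceed -100 percent/year")
    if years < 0:
        raise GrowthDomainError("projection horizon must be non-negative")
    return p0 * (1.0 + r / 100.0) ** years


def doubling_time(rate: GrowthRate | float) -> float:
    """Years for a population to double at constant rate:
    ``ln(2) / ln(1 + rate/100)``.  Requires a strictly positive rate."""
    r = rate.rate if isinstance(rate, GrowthRate) else float(rate)
    if r <= 0:
        raise GrowthDomainError("doubling time undefined for rate <= 0")
    return math.log(2.0) / math.log1p(r / 100.0)
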