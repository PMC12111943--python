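"""Surgical-demand estimation from projected elderly populations.

The estimator is prevalence-based: the decade "prevalence" is the
decade-cumulative count of surgical aortic valve replacements (SAVR) in
patients >=65, divided by the *end-of-decade* >=65 census population
(a surgery-to-population ratio, not a point prevalence of disease; the
name follows field usage).  The latest observed ratio is applied to each
projected >=65 population to obtain expected surgeries per future
decade, reported alongside the increment over the reference decade and
its per-year equivalent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy import stats

from .errors import SavrcastError, ValidationError

ROUNDING_POLICIES = ("exact", "ceil", "nearest")


@dataclass(frozen=True)
class SurgeryDecade:
    """SAVR count in patients >=65 over one decade of a surgical registry."""

    start_year: int
    end_year: int
    n_surgeries: int

    def __post_init__(self) -> None:
        if self.end_year - self.start_year != 10:
            raise ValidationError(
                f"decade must span 10 years, got {self.start_year}-{self.end_year}"
            )
        if self.n_surgeries < 0:
            raise ValidationError("n_surgeries must be non-negative")


def decade_prevalence(decade: SurgeryDecade, pop_65_plus_at_end: float) -> float:
    """Decade surgery-to-population ratio, percent:
    100 x n_surgeries / (end-of-decade >=65 population).

    Full precision returned; report to 2 decimals.
    """
    if pop_65_plus_at_end <= 0:
        raise SavrcastError("end-of-decade >=65 population must be positive")
    return 100.0 * decade.n_surgeries / pop_65_plus_at_end


def projected_surgeries(prevalence: float, projected_pop_65_plus: float) -> int:
    """Expected SAVR count per decade when ``prevalence`` (percent) is
    applied to a projected >=65 population; rounded to the nearest whole
    surgery."""
    if prevalence < 0:
        raise SavrcastError("prevalence must be non-negative")
    if projected_pop_65_plus < 0:
        raise SavrcastError("population must be non-negative")
    return round(prevalence / 100.0 * projected_pop_65_plus)


@dataclass(frozen=True)
class DemandEstimate:
    """Decade demand summary relative to a reference registry decade.

    ``per_year_increase_exact`` is the one-decimal-faithful value
    (increment / 10); ``per_year_increase_reported`` applies the chosen
    integer rounding policy (``nearest`` or ``ceil``; ``exact`` reports
    the nearest integer alongside the exact value).
    """

    prevalence: float | None
    projected_surgeries: int
    reference: SurgeryDecade
    decade_increase: int
    per_year_increase_exact: float
    per_year_increase_reported: int
    rounding_policy: str


def demand_summary(
    projected: int,
    reference: SurgeryDecade,
    rounding_policy: str = "exact",
    prevalence: float | None = None,
) -> DemandEstimate:
    """Summarize projected decade demand against the reference decade.

    decade_increase = projected - reference count; per-year exact value
    is increase/10.  The integer per-year figure depends on the policy:
    ``ceil`` rounds up (a capacity-planning floor is conservative),
    ``nearest``/``exact`` round to nearest.
    """
    if rounding_policy not in ROUNDING_POLICIES:
        raise ValueError(f"rounding_policy must be one of {ROUNDING_POLICIES}")
    increase = int(projected) - reference.n_surgeries
    per_year = increase / 10.0
    if rounding_policy == "ceil":
        reported = math.ceil(per_year)
    else:
        reported = round(per_year)
    return DemandEstimate(
        prevalence=prevalence,
        projected_surgeries=int(projected),
        reference=reference,
        decade_increase=increase,
        per_year_increase_exact=per_year,
        per_year_increase_reported=reported,
        rounding_policy=rounding_policy,
    )


def annual_trend(series: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least-squares trend of an annual surgery series.

    ``series`` is (year, surgeries/year) pairs, >=3 points.  Returns
    (slope in surgeries/year per year, R^2).
    """
    if len(series) < 3:
        raise SavrcastError("annual_trend needs at least 3 points")
    x = [float(a) for a, _ in series]
    y = [float(b) for _, b in series]
    if len(set(x)) < 2:
        raise SavrcastError("degenerate series: no variance in year")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def read_registry_csv(path: str | Path) -> list[SurgeryDecade]:
    """Read decade surgery counts from a ``start_year,end_year,n_surgeries``
    CSV, sorted by start year."""
    decades = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"start_year", "end_year", "n_surgeries"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SavrcastError(f"{path}: missing registry columns {sorted(missing)}")
        for row in reader:
            decades.append(
                SurgeryDecade(
                    start_year=int(row["start_year"]),
                    end_year=int(row["end_year"]),
                    n_surgeries=int(row["n_surgeries"]),
                )
            )
    return sorted(decades, key=lambda d: d.start_year)


def write_registry_csv(decades: Sequence[SurgeryDecade], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_year", "end_year", "n_surgeries"])
        for d in sorted(decades, key=lambda d: d.start_year):
            writer.writerow([d.start_year, d.end_year, d.n_surgeries])
    return path
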