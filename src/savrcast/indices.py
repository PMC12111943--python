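"""Aging and longevity indices and their across-year comparison.

The *aging index* is 100 x (population >=65) / (population 0-14): values
above 100 mean the elderly outnumber the young.  The *longevity index*
is 100 x (population >=75) / (population >=65): the per-100 share of the
elderly who are in advanced old age.  Both are dimensionless and
reported on the per-100 scale, rounded to one decimal for display;
internal computation keeps full precision.

Across-year shifts in a panel of municipality-level index values are
tested with the Kruskal-Wallis omnibus test (with tie correction)
followed by Dunn's pairwise z-tests on mean ranks with Bonferroni
adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .census import CensusPanel
from .errors import CapabilityError, InsufficientDataError, UndefinedIndexError, ValidationError

INDEX_NAMES = ("aging", "longevity")


def aging_index(pop_65_plus: int, pop_0_14: int) -> float:
    """Aging index: 100 x pop_65_plus / pop_0_14.

    Raises :class:`UndefinedIndexError` when there are no 0-14 year olds
    (the index is undefined, not infinite).
    """
    if pop_0_14 <= 0:
        raise UndefinedIndexError("aging index undefined: pop_0_14 is zero")
    if pop_65_plus < 0:
        raise ValidationError("pop_65_plus must be non-negative")
    return 100.0 * pop_65_plus / pop_0_14


def longevity_index(pop_75_plus: int, pop_65_plus: int) -> float:
    """Longevity index: 100 x pop_75_plus / pop_65_plus, in [0, 100]."""
    if pop_65_plus <= 0:
        raise UndefinedIndexError("longevity index undefined: pop_65_plus is zero")
    if pop_75_plus < 0 or pop_75_plus > pop_65_plus:
        raise ValidationError(
            f"pop_75_plus ({pop_75_plus}) must lie in [0, pop_65_plus={pop_65_plus}]"
        )
    return 100.0 * pop_75_plus / pop_65_plus


@dataclass
class IndexTable:
    """Per-(municipality, year) values of one index.

    ``undefined`` lists the (municipality, year) cells where the index
    denominator was zero — flagged, never silently dropped.
    """

    index_name: str
    values: dict[tuple[str, int], float]
    undefined: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.index_name not in INDEX_NAMES:
            raise ValueError(f"index_name must be one of {INDEX_NAMES}")

    @property
    def years(self) -> list[int]:
        return sorted({y for (_, y) in self.values})

    def year_values(self, year: int) -> np.ndarray:
        return np.array(
            [v for (_, y), v in sorted(self.values.items()) if y == year]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy ``index,municipality,year,value`` frame (full precision)."""
        rows = [
            {"index": self.index_name, "municipality": m, "year": y, "value": v}
            for (m, y), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["index", "municipality", "year", "value"])

    def summary(self, spread: str = "range") -> pd.DataFrame:
        """Per-year median and spread.

        ``spread="range"`` gives the min-max envelope (the default
        reading of "median (low-high)" reports); ``spread="iqr"`` gives
        the 25th/75th percentiles.
        """
        if spread not in ("range", "iqr"):
            raise ValueError("spread must be 'range' or 'iqr'")
        rows = []
        for year in self.years:
            vals = self.year_values(year)
            if spread == "range":
                low, high = float(vals.min()), float(vals.max())
            else:
                low, high = (float(q) for q in np.percentile(vals, [25, 75]))
            rows.append(
                {
                    "index": self.index_name,
                    "year": year,
                    "median": float(np.median(vals)),
                    "low": low,
                    "high": high,
                    "n": len(vals),
                }
            )
        return pd.DataFrame(rows, columns=["index", "year", "median", "low", "high", "n"])

    def count_below(self, threshold: float, year: int) -> int:
        """Number of municipalities with index value < threshold in a year."""
        return int((self.year_values(year) < threshold).sum())


def index_table(panel: CensusPanel, index_name: str) -> IndexTable:
    """Compute one index for every (municipality, year) in the panel.

    Uses all-sex records.  Cells with a zero denominator are flagged in
    ``undefined``.  A longevity table on a panel lacking the >=75 band
    raises :class:`CapabilityError`.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"index_name must be one of {INDEX_NAMES}")
    values: dict[tuple[str, int], float] = {}
    undefined: list[tuple[str, int]] = []
    for muni in panel.municipalities:
        for year in panel.years:
            rec = panel.get(muni, year, "all")
            if index_name == "longevity" and rec.pop_75_plus is None:
                raise CapabilityError(
                    f"longevity index needs the >=75 band; missing for "
                    f"({muni}, {year})"
                )
            try:
                if index_name == "aging":
                    values[(muni, year)] = aging_index(rec.pop_65_plus, rec.pop_0_14)
                else:
                    values[(muni, year)] = longevity_index(
                        rec.pop_75_plus, rec.pop_65_plus
                    )
            except UndefinedIndexError:
                undefined.append((muni, year))
    return IndexTable(index_name=index_name, values=values, undefined=undefined)


@dataclass(frozen=True)
class PairwiseComparison:
    year_a: int
    year_b: int
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    """Kruskal-Wallis omnibus result plus Dunn-Bonferroni pairwise tests."""

    omnibus_statistic: float
    omnibus_p: float
    pairwise: tuple[PairwiseComparison, ...]


def _dunn_pairwise(
    groups: dict[int, np.ndarray]
) -> tuple[PairwiseComparison, ...]:
    """Dunn's z-tests on mean ranks, tie-corrected, two-sided,
    Bonferroni-adjusted (multiplied by the number of pairs, capped at 1)."""
    labels = sorted(groups)
    pooled = np.concatenate([groups[y] for y in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[int, float] = {}
    start = 0
    for y in labels:
        n = len(groups[y])
        mean_rank[y] = float(ranks[start : start + n].mean())
        start += n
    # tie correction term: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    results = []
    for ya, yb in itertools.combinations(labels, 2):
        na, nb = len(groups[ya]), len(groups[yb])
        var = (
            n_total * (n_total + 1) / 12.0
            - tie_term / (12.0 * (n_total - 1))
        ) * (1.0 / na + 1.0 / nb)
        if var <= 0:  # all observations tied
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[ya] - mean_rank[yb]) / math.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        results.append(
            PairwiseComparison(
                year_a=ya,
                year_b=yb,
                z=float(z),
                p_unadjusted=float(p),
                p_adjusted=float(min(1.0, p * n_pairs)),
            )
        )
    return tuple(results)


def compare_years(table: IndexTable) -> ComparisonResult:
    """Test whether an index's distribution over municipalities shifts
    across census years.

    Kruskal-Wallis H (tie-corrected) as the omnibus test over the per-year
    groups of municipality values, then Dunn's pairwise mean-rank z-tests
    with Bonferroni adjustment for every year pair.  Requires at least two
    years with at least two values each.
    """
    years = table.years
    if len(years) < 2:
        raise InsufficientDataError("need >= 2 census years to compare")
    groups = {y: table.year_values(y) for y in years}
    for y, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(f"year {y} has fewer than 2 values")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        # every observation identical: no evidence of any shift
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())
    return ComparisonResult(
        omnibus_statistic=float(h),
        omnibus_p=float(p),
        pairwise=_dunn_pairwise(groups),
    )
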