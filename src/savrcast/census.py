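"""Municipality-level census panels.

The unit of observation is one municipality in one census wave (2001,
2011, 2021 in the motivating application), with population counts in the
three standard age bands 0-14, 15-64 and >=65, optionally the >=75
sub-band, and optionally stratified by sex.  A :class:`CensusPanel`
collects such records, enforces key uniqueness and band-partition
invariants, and supports aggregation to a referral-region total.

Counts are integers throughout; no rescaling or imputation is performed.
The >=75 band may be absent (the longevity index is then unavailable).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CapabilityError, SchemaError, ValidationError

SEXES = ("all", "female", "male")

#: canonical CSV column order
CSV_COLUMNS = (
    "municipality",
    "year",
    "sex",
    "pop_total",
    "pop_0_14",
    "pop_15_64",
    "pop_65_plus",
    "pop_75_plus",
)

_REQUIRED_COLUMNS = tuple(c for c in CSV_COLUMNS if c != "pop_75_plus")

# integer with optional US-style thousands separators; decimal commas
# ("3,5") and decimal points are rejected because counts are integers
_INT_RE = re.compile(r"^\d{1,3}(,\d{3})+$|^\d+$")


def _parse_count(cell: str, context: str) -> int:
    cell = cell.strip()
    if not _INT_RE.match(cell):
        raise ValidationError(
            f"{context}: {cell!r} is not a non-negative integer count"
        )
    return int(cell.replace(",", ""))


@dataclass(frozen=True)
class CensusRecord:
    """One municipality x census-year (x sex) row of population counts.

    Invariants enforced on construction:

    * all counts are non-negative integers;
    * ``pop_0_14 + pop_15_64 + pop_65_plus == pop_total`` exactly;
    * ``0 <= pop_75_plus <= pop_65_plus`` when the >=75 band is present.
    """

    municipality: str
    year: int
    pop_total: int
    pop_0_14: int
    pop_15_64: int
    pop_65_plus: int
    pop_75_plus: int | None = None
    sex: str = "all"

    def __post_init__(self) -> None:
        where = f"{self.municipality}/{self.year}/{self.sex}"
        if self.sex not in SEXES:
            raise ValidationError(f"{where}: sex must be one of {SEXES}")
        counts = {
            "pop_total": self.pop_total,
            "pop_0_14": self.pop_0_14,
            "pop_15_64": self.pop_15_64,
            "pop_65_plus": self.pop_65_plus,
        }
        if self.pop_75_plus is not None:
            counts["pop_75_plus"] = self.pop_75_plus
        for name, value in counts.items():
            if not isinstance(value, int) or value < 0:
                raise ValidationError(
                    f"{where}: {name}={value!r} must be a non-negative integer"
                )
        band_sum = self.pop_0_14 + self.pop_15_64 + self.pop_65_plus
        if band_sum != self.pop_total:
            raise ValidationError(
                f"{where}: age bands sum to {band_sum}, "
                f"pop_total is {self.pop_total}"
            )
        if self.pop_75_plus is not None and self.pop_75_plus > self.pop_65_plus:
            raise ValidationError(
                f"{where}: pop_75_plus ({self.pop_75_plus}) exceeds "
                f"pop_65_plus ({self.pop_65_plus})"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.municipality, self.year, self.sex)


@dataclass
class CensusPanel:
    """A validated collection of :class:`CensusRecord` spanning
    municipalities and census waves.

    ``(municipality, year, sex)`` keys are unique.  ``complete`` is True
    when every municipality has an all-sex record in every year (the
    balanced-panel case the downstream analysis assumes).
    """

    records: list[CensusRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValidationError(f"duplicate record key {rec.key}")
            seen.add(rec.key)
        self._by_key: dict[tuple[str, int, str], CensusRecord] = {
            rec.key: rec for rec in self.records
        }

    @property
    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    @property
    def municipalities(self) -> list[str]:
        return sorted({r.municipality for r in self.records})

    @property
    def sexes(self) -> list[str]:
        return sorted({r.sex for r in self.records})

    @property
    def complete(self) -> bool:
        keys = {(r.municipality, r.year) for r in self.records if r.sex == "all"}
        return all(
            (m, y) in keys for m in self.municipalities for y in self.years
        )

    def get(self, municipality: str, year: int, sex: str = "all") -> CensusRecord:
        try:
            return self._by_key[(municipality, year, sex)]
        except KeyError:
            raise KeyError(
                f"no census record for ({municipality!r}, {year}, {sex!r})"
            ) from None

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CensusPanel):
            return NotImplemented
        return self._by_key == other._by_key

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame with one row per record, canonical column order."""
        rows = [
            {c: getattr(r, c) for c in CSV_COLUMNS}
            for r in sorted(self.records, key=lambda r: r.key)
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def read_census_csv(path: str | Path, *, delimiter: str = ",") -> CensusPanel:
    """Read and validate a census panel from CSV.

    Expected header: ``municipality,year,sex,pop_total,pop_0_14,
    pop_15_64,pop_65_plus,pop_75_plus``.  The ``sex`` column may be
    omitted (defaults to ``all``) and the ``pop_75_plus`` column may be
    omitted or blank.  Counts accept plain digits and US-style thousands
    separators (``1,042,214``); anything else is rejected.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for rows violating record invariants or
    duplicate keys.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col == "sex":
                continue  # optional
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        has_sex = "sex" in header
        has_75 = "pop_75_plus" in header
        records = []
        for lineno, row in enumerate(reader, start=2):
            muni = (row["municipality"] or "").strip()
            if not muni:
                raise ValidationError(f"{path}:{lineno}: empty municipality")
            context = f"{path}:{lineno} ({muni})"
            year = _parse_count(row["year"], context)
            sex = (row["sex"].strip() if has_sex and row["sex"] else "all")
            p75_cell = row.get("pop_75_plus") if has_75 else None
            p75 = (
                _parse_count(p75_cell, context)
                if p75_cell is not None and p75_cell.strip() != ""
                else None
            )
            records.append(
                CensusRecord(
                    municipality=muni,
                    year=year,
                    sex=sex,
                    pop_total=_parse_count(row["pop_total"], context),
                    pop_0_14=_parse_count(row["pop_0_14"], context),
                    pop_15_64=_parse_count(row["pop_15_64"], context),
                    pop_65_plus=_parse_count(row["pop_65_plus"], context),
                    pop_75_plus=p75,
                )
            )
    return CensusPanel(records)


def write_census_csv(panel: CensusPanel, path: str | Path) -> Path:
    """Write a panel to CSV in the canonical schema; inverse of
    :func:`read_census_csv`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in sorted(panel.records, key=lambda r: r.key):
            writer.writerow(
                [
                    rec.municipality,
                    rec.year,
                    rec.sex,
                    rec.pop_total,
                    rec.pop_0_14,
                    rec.pop_15_64,
                    rec.pop_65_plus,
                    "" if rec.pop_75_plus is None else rec.pop_75_plus,
                ]
            )
    return path


def aggregate_region(
    panel: CensusPanel,
    municipalities: Sequence[str] | str = "all",
    year: int | None = None,
    sex: str = "all",
) -> CensusRecord:
    """Sum records over a set of municipalities for one census year.

    The result is a :class:`CensusRecord` for the synthetic municipality
    ``"region"`` whose every count is the column sum; it satisfies all
    record invariants by additivity.  The >=75 band is propagated only
    if every summed record carries it.
    """
    if year is None:
        raise ValueError("year is required")
    munis = panel.municipalities if municipalities == "all" else list(municipalities)
    recs = [panel.get(m, year, sex) for m in munis]
    if not recs:
        raise KeyError("no municipalities to aggregate")
    p75: int | None
    if all(r.pop_75_plus is not None for r in recs):
        p75 = sum(r.pop_75_plus for r in recs)  # type: ignore[misc]
    else:
        p75 = None
    return CensusRecord(
        municipality="region" if len(recs) > 1 else recs[0].municipality,
        year=year,
        sex=sex,
        pop_total=sum(r.pop_total for r in recs),
        pop_0_14=sum(r.pop_0_14 for r in recs),
        pop_15_64=sum(r.pop_15_64 for r in recs),
        pop_65_plus=sum(r.pop_65_plus for r in recs),
        pop_75_plus=p75,
    )


#: band name -> record field
_BAND_FIELDS: Mapping[str, str] = {
    "0-14": "pop_0_14",
    "15-64": "pop_15_64",
    "65+": "pop_65_plus",
    "75+": "pop_75_plus",
    "total": "pop_total",
}

DEFAULT_BANDS = ("0-14", "15-64", "65+")


def pyramid_summary(
    panel: CensusPanel,
    year: int,
    bands: Iterable[str] = DEFAULT_BANDS,
    sexes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Region-level age-band counts for one census year, per sex.

    Returns a tidy ``(band, sex, count)`` DataFrame summing over all
    municipalities — the numbers behind a population-pyramid chart.
    ``sexes`` defaults to ``("female", "male")`` when the panel carries
    sex-stratified records and ``("all",)`` otherwise; requesting a sex
    split on an all-only panel raises :class:`CapabilityError`.
    """
    bands = list(bands)
    unknown = [b for b in bands if b not in _BAND_FIELDS]
    if unknown:
        raise ValueError(f"unknown bands {unknown}; choose from {list(_BAND_FIELDS)}")
    available = set(panel.sexes)
    if sexes is None:
        sexes = (
            ("female", "male") if {"female", "male"} <= available else ("all",)
        )
    missing = [s for s in sexes if s not in available]
    if missing:
        raise CapabilityError(
            f"panel has no records for sex {missing}; available: {sorted(available)}"
        )
    rows = []
    for sex in sexes:
        region = aggregate_region(panel, "all", year, sex=sex)
        for band in bands:
            count = getattr(region, _BAND_FIELDS[band])
            if count is None:
                raise CapabilityError(
                    f"band {band!r} unavailable: >=75 counts missing for {year}"
                )
            rows.append({"band": band, "sex": sex, "count": count})
    return pd.DataFrame(rows, columns=["band", "sex", "count"])
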