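"""Two-phase, multi-scenario population projection.

A :class:`ScenarioSpec` turns one observed base rate into a schedule of
per-phase rates by subtracting an absolute percentage-point decrement
``delta`` per projected decade.  Two presets mirror the usual planning
pair for a 2021->2041 horizon:

* ``decreasing`` — the recent inter-decade slow-down continues, so the
  decrement applies from the first projected decade onward
  (e.g. base 1.40, delta 0.29 -> phases [1.11, 0.82]);
* ``stagnation`` — the first projected decade keeps the last observed
  rate and the decrement starts in the second
  (base 1.40, delta 0.29 -> phases [1.40, 1.11]).

Rates may legitimately go negative (population decline).  Projections
chain at full precision; integers appear only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import growth

PRESET_NAMES = ("decreasing", "stagnation")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named projection scenario.

    ``base_rate`` is the observed percent/year rate for the stratum over
    the most recent census decade; ``decrement`` is subtracted per
    projected decade (absolute percentage points, not proportional);
    ``decrement_from_first_phase`` controls whether phase 1 already
    carries one decrement (True for ``decreasing``) or starts at the
    base rate (False for ``stagnation``).
    """

    name: str
    base_rate: float
    decrement: float = 0.0
    phase_length: int = 10
    n_phases: int = 2
    decrement_from_first_phase: bool = False

    def __post_init__(self) -> None:
        if self.phase_length <= 0:
            raise ValueError("phase_length must be positive")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")


def decreasing(base_rate: float, decrement: float, **kwargs) -> ScenarioSpec:
    """Preset: continued slow-down; decrement applies from phase 1."""
    return ScenarioSpec(
        name="decreasing",
        base_rate=base_rate,
        decrement=decrement,
        decrement_from_first_phase=True,
        **kwargs,
    )


def stagnation(base_rate: float, decrement: float, **kwargs) -> ScenarioSpec:
    """Preset: phase 1 holds the observed rate; decrement from phase 2."""
    return ScenarioSpec(
        name="stagnation",
        base_rate=base_rate,
        decrement=decrement,
        decrement_from_first_phase=False,
        **kwargs,
    )


def phase_rates(spec: ScenarioSpec) -> list[float]:
    """Percent/year rate for each projection phase.

    Phase i (0-based) rate = base_rate - delta * (i + offset), offset 1
    when the decrement applies from the first phase.
    """
    offset = 1 if spec.decrement_from_first_phase else 0
    return [
        spec.base_rate - spec.decrement * (i + offset)
        for i in range(spec.n_phases)
    ]


@dataclass(frozen=True)
class ProjectionResult:
    """Projected populations at each phase end under one scenario."""

    scenario: ScenarioSpec
    stratum: str
    p0: float
    base_year: int
    phase_rates: tuple[float, ...]
    phase_end_years: tuple[int, ...]
    phase_end_populations: tuple[float, ...]

    def reported(self) -> list[tuple[int, int]]:
        """(year, population rounded to whole persons) per phase end."""
        return [
            (y, round(p))
            for y, p in zip(self.phase_end_years, self.phase_end_populations)
        ]


def run_scenario(
    p0: float,
    base_year: int,
    spec: ScenarioSpec,
    stratum: str = "total",
) -> ProjectionResult:
    """Chain full-precision geometric projection over the scenario's
    phases, starting from the base-year population ``p0``."""
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    rates = phase_rates(spec)
    pops: list[float] = []
    years: list[int] = []
    p = float(p0)
    year = base_year
    for r in rates:
        p = growth.project(p, r, spec.phase_length)
        year += spec.phase_length
        pops.append(p)
        years.append(year)
    return ProjectionResult(
        scenario=spec,
        stratum=stratum,
        p0=float(p0),
        base_year=base_year,
        phase_rates=tuple(rates),
        phase_end_years=tuple(years),
        phase_end_populations=tuple(pops),
    )


def scenario_table(
    p0_total: float,
    p0_65plus: float,
    base_rates: Mapping[str, float],
    decrements: Mapping[str, float],
    base_year: int = 2021,
    n_phases: int = 2,
    phase_length: int = 10,
) -> pd.DataFrame:
    """Full scenario x stratum x phase projection table.

    ``base_rates`` and ``decrements`` map stratum (``"total"``,
    ``"age_65_plus"``) to the observed rate and per-decade decrement.
    Returns one row per (scenario, stratum) with the base-year census
    value and rounded projected populations at each phase end.
    """
    p0 = {"total": p0_total, "age_65_plus": p0_65plus}
    rows = []
    for preset in (decreasing, stagnation):
        for stratum in ("total", "age_65_plus"):
            spec = preset(
                base_rates[stratum],
                decrements[stratum],
                n_phases=n_phases,
                phase_length=phase_length,
            )
            res = run_scenario(p0[stratum], base_year, spec, stratum)
            row = {
                "scenario": spec.name,
                "stratum": stratum,
                str(base_year): round(p0[stratum]),
            }
            for year, pop in res.reported():
                row[str(year)] = pop
            rows.append(row)
    return pd.DataFrame(rows)


def scenario_from_dict(cfg: Mapping) -> ScenarioSpec:
    """Build a spec from a config mapping
    ``{name, base_rate, decrement, phases, phase_length,
    decrement_from_first_phase}``; unspecified fields take preset or
    dataclass defaults."""
    name = cfg["name"]
    kwargs = dict(
        base_rate=float(cfg["base_rate"]),
        decrement=float(cfg.get("decrement", 0.0)),
        n_phases=int(cfg.get("phases", 2)),
        phase_length=int(cfg.get("phase_length", 10)),
    )
    if "decrement_from_first_phase" in cfg:
        dffp = bool(cfg["decrement_from_first_phase"])
    elif name in PRESET_NAMES:
        dffp = name == "decreasing"
    else:
        dffp = False
    return ScenarioSpec(name=name, decrement_from_first_phase=dffp, **kwargs)


def load_scenarios(path: str | Path) -> list[ScenarioSpec]:
    """Load scenario specs from a YAML/JSON file holding a list of
    scenario mappings (or one mapping)."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, Mapping):
        data = [data]
    return [scenario_from_dict(d) for d in data]
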