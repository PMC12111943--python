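"""End-to-end orchestration: load -> indices -> rates -> scenarios ->
demand -> report.

:func:`run_analysis` drives the full analysis from a census panel and a
surgical registry (files or the synthetic generator) and emits CSV
tables plus a machine-readable JSON summary.  :func:`reference_analysis`
runs the same projection chain from the packaged region-level published
figures, which contain no municipality detail, so the index/comparison
stage is skipped there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import demand as demand_mod
from . import growth, reference, reporting, scenarios
from .census import CensusPanel, aggregate_region, read_census_csv
from .demand import SurgeryDecade
from .errors import CapabilityError, SavrcastError
from .indices import compare_years, index_table
from .synthetic import SyntheticConfig, generate_panel, generate_registry

log = logging.getLogger("savrcast")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input source: either ``census_path`` (with optional
    ``registry_path``) or ``synthetic``.  ``horizon`` must lie beyond
    the last census wave; projection phases are 10-year decades.
    """

    census_path: str | Path | None = None
    registry_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    horizon: int = 2041
    phase_length: int = 10
    spread: str = "range"
    output_dir: str | Path | None = None
    rounding_policy: str = "exact"

    def __post_init__(self) -> None:
        if (self.census_path is None) == (self.synthetic is None):
            raise SavrcastError(
                "exactly one input source required: census_path or synthetic"
            )


def _growth_section(panel: CensusPanel) -> dict:
    """Observed inter-census geometric rates for both strata."""
    years = panel.years
    rates: dict[str, dict[str, float]] = {"total": {}, "age_65_plus": {}}
    for a, b in zip(years, years[1:]):
        ra = aggregate_region(panel, "all", a)
        rb = aggregate_region(panel, "all", b)
        for stratum, pa, pb in (
            ("total", ra.pop_total, rb.pop_total),
            ("age_65_plus", ra.pop_65_plus, rb.pop_65_plus),
        ):
            g = growth.geometric_growth_rate(pa, pb, b - a, period_start=a,
                                             stratum=stratum)
            rates[stratum][f"{a}-{b}"] = g.rate
            log.info("rate %s %s-%s: %.4f %%/yr (reported %.2f)",
                     stratum, a, b, g.rate, reporting.rate(g.rate))
    return rates


def _scenario_section(panel: CensusPanel, rates: dict, horizon: int,
                      phase_length: int) -> tuple[dict, dict]:
    years = panel.years
    last = years[-1]
    if horizon <= last:
        raise SavrcastError(f"horizon {horizon} must exceed last census year {last}")
    n_phases = -(-(horizon - last) // phase_length)  # ceil
    base_rates, decrements = {}, {}
    for stratum in ("total", "age_65_plus"):
        windows = sorted(rates[stratum])
        base_rates[stratum] = rates[stratum][windows[-1]]
        decrements[stratum] = (
            rates[stratum][windows[-2]] - rates[stratum][windows[-1]]
            if len(windows) >= 2 else 0.0
        )
    region = aggregate_region(panel, "all", last)
    table = scenarios.scenario_table(
        region.pop_total, region.pop_65_plus, base_rates, decrements,
        base_year=last, n_phases=n_phases, phase_length=phase_length,
    )
    meta = {
        "base_year": last,
        "base_rates": {k: reporting.rate(v) for k, v in base_rates.items()},
        "decrements": {k: reporting.rate(v) for k, v in decrements.items()},
        "n_phases": n_phases,
    }
    return table.to_dict(orient="records"), meta


def _demand_section(panel: CensusPanel, registry: list[SurgeryDecade],
                    scenario_rows: list[dict], horizon: int,
                    rounding_policy: str) -> dict:
    reference_decade = max(registry, key=lambda d: d.start_year)
    end_rec = aggregate_region(panel, "all", reference_decade.end_year)
    prev = demand_mod.decade_prevalence(reference_decade, end_rec.pop_65_plus)
    log.info("latest decade prevalence: %.4f%% (reported %.2f)",
             prev, reporting.prevalence(prev))
    prevalences = {}
    for dec in registry:
        try:
            pop = aggregate_region(panel, "all", dec.end_year).pop_65_plus
        except KeyError:
            continue
        prevalences[f"{dec.start_year}-{dec.end_year}"] = reporting.prevalence(
            demand_mod.decade_prevalence(dec, pop)
        )
    rows = []
    for row in scenario_rows:
        if row["stratum"] != "age_65_plus":
            continue
        pop_h = row[str(horizon)]
        projected = demand_mod.projected_surgeries(reporting.prevalence(prev), pop_h)
        est = demand_mod.demand_summary(projected, reference_decade,
                                        rounding_policy, prevalence=prev)
        rows.append({
            "scenario": row["scenario"],
            "projected_pop_65_plus": pop_h,
            "projected_surgeries": est.projected_surgeries,
            "decade_increase": est.decade_increase,
            "per_year_increase_exact": reporting.per_year(est.per_year_increase_exact),
            "per_year_increase_reported": est.per_year_increase_reported,
        })
    return {
        "reference_decade": {
            "start_year": reference_decade.start_year,
            "end_year": reference_decade.end_year,
            "n_surgeries": reference_decade.n_surgeries,
        },
        "prevalence_by_decade_pct": prevalences,
        "applied_prevalence_pct": reporting.prevalence(prev),
        "by_scenario": rows,
    }


def _indices_section(panel: CensusPanel, spread: str) -> dict:
    out: dict = {}
    for name in ("aging", "longevity"):
        try:
            table = index_table(panel, name)
        except CapabilityError as exc:
            out[name] = {"available": False, "reason": str(exc)}
            continue
        summary = table.summary(spread)
        cmp_res = compare_years(table)
        out[name] = {
            "available": True,
            "summary": [
                {**row, "median": reporting.index_value(row["median"]),
                 "low": reporting.index_value(row["low"]),
                 "high": reporting.index_value(row["high"])}
                for row in summary.to_dict(orient="records")
            ],
            "kruskal_wallis": {"H": cmp_res.omnibus_statistic,
                               "p": cmp_res.omnibus_p},
            "dunn_bonferroni": [
                {"year_a": c.year_a, "year_b": c.year_b, "z": c.z,
                 "p_adjusted": c.p_adjusted}
                for c in cmp_res.pairwise
            ],
            "n_undefined": len(table.undefined),
        }
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline and return the report bundle.

    When ``config.output_dir`` is set, also writes ``indices.csv``,
    ``indices_summary.csv``, ``scenario_table.csv``, ``demand.csv`` and
    ``summary.json`` there.
    """
    if config.synthetic is not None:
        panel = generate_panel(config.synthetic)
        registry = generate_registry(panel, config.synthetic.true_prevalence,
                                     config.synthetic.seed + 1)
        source = {"kind": "synthetic", "seed": config.synthetic.seed}
    else:
        panel = read_census_csv(config.census_path)
        registry = (demand_mod.read_registry_csv(config.registry_path)
                    if config.registry_path else [])
        source = {"kind": "files", "census": str(config.census_path),
                  "registry": (str(config.registry_path)
                               if config.registry_path else None)}
    log.info("panel: %d municipalities x %d years, complete=%s",
             len(panel.municipalities), len(panel.years), panel.complete)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "source": source,
        "panel": {
            "municipalities": len(panel.municipalities),
            "years": panel.years,
            "complete": panel.complete,
        },
    }
    report["indices"] = _indices_section(panel, config.spread)
    rates = _growth_section(panel)
    report["growth_rates_pct_per_year"] = {
        s: {w: reporting.rate(v) for w, v in d.items()} for s, d in rates.items()
    }
    scen_rows, scen_meta = _scenario_section(panel, rates, config.horizon,
                                             config.phase_length)
    report["scenarios"] = {"meta": scen_meta, "table": scen_rows}
    if registry:
        report["demand"] = _demand_section(panel, registry, scen_rows,
                                           config.horizon,
                                           config.rounding_policy)

    if config.output_dir is not None:
        _write_bundle(report, panel, config)
    return report


def _write_bundle(report: dict, panel: CensusPanel, config: RunConfig) -> None:
    import pandas as pd

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    summaries = []
    for name in ("aging", "longevity"):
        sec = report["indices"].get(name, {})
        if not sec.get("available"):
            continue
        table = index_table(panel, name)
        frames.append(table.to_frame())
        summaries.append(table.summary(config.spread))
    if frames:
        pd.concat(frames).to_csv(outdir / "indices.csv", index=False)
        pd.concat(summaries).to_csv(outdir / "indices_summary.csv", index=False)
    pd.DataFrame(report["scenarios"]["table"]).to_csv(
        outdir / "scenario_table.csv", index=False)
    if "demand" in report:
        pd.DataFrame(report["demand"]["by_scenario"]).to_csv(
            outdir / "demand.csv", index=False)
    with (outdir / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    log.info("report bundle written to %s", outdir)


def reference_analysis(rounding_policy: str = "exact") -> dict:
    """Run the projection chain on the packaged published region-level
    figures (2021 census totals, observed decade rates, registry decade
    counts) and return the report bundle.

    Reproduces the headline planning numbers: the ~50-year doubling time
    of the >=65 population at its 2011-2021 rate, the >1 million >=65
    projection for 2071, the two-scenario 2031/2041 population table,
    and the decade/per-year SAVR increments under the latest observed
    prevalence.
    """
    r65 = reference.RATE_65_2011_2021
    dt = growth.doubling_time(r65)
    p65_2071 = growth.project(reference.POP_65_PLUS_2021, r65, 50)
    table = scenarios.scenario_table(
        reference.TOTAL_POP_2021,
        reference.POP_65_PLUS_2021,
        reference.BASE_RATES,
        reference.DECREMENTS,
        base_year=reference.BASE_YEAR,
    )
    rows = table.to_dict(orient="records")
    ref_decade = reference.SURGERIES_2011_2021
    prev = demand_mod.decade_prevalence(ref_decade, reference.POP_65_PLUS_2021)
    # 2011 >=65 population back-projected at the observed 2011-2021 rate
    pop65_2011 = reference.POP_65_PLUS_2021 / (1.0 + r65 / 100.0) ** 10
    prev_early = demand_mod.decade_prevalence(reference.SURGERIES_2001_2011,
                                              pop65_2011)
    demand_rows = []
    for row in rows:
        if row["stratum"] != "age_65_plus":
            continue
        pop_h = row[str(reference.HORIZON)]
        projected = demand_mod.projected_surgeries(reporting.prevalence(prev),
                                                   pop_h)
        est = demand_mod.demand_summary(projected, ref_decade, rounding_policy,
                                        prevalence=prev)
        demand_rows.append({
            "scenario": row["scenario"],
            "projected_pop_65_plus": pop_h,
            "projected_surgeries": est.projected_surgeries,
            "decade_increase": est.decade_increase,
            "per_year_increase_exact": reporting.per_year(est.per_year_increase_exact),
            "per_year_increase_reported": est.per_year_increase_reported,
        })
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "source": {"kind": "reference",
                   "description": "published referral-area census and "
                                  "registry figures"},
        "growth": {
            "rates_pct_per_year": {
                "total": {"2001-2011": reference.RATE_TOTAL_2001_2011,
                          "2011-2021": reference.RATE_TOTAL_2011_2021},
                "age_65_plus": {"2001-2011": reference.RATE_65_2001_2011,
                                "2011-2021": reference.RATE_65_2011_2021},
            },
            "doubling_time_years_65_plus": dt,
            "doubling_time_years_reported": round(dt),
            "pop_65_plus_2071": reporting.persons(p65_2071),
        },
        "scenarios": {
            "meta": {"base_year": reference.BASE_YEAR,
                     "base_rates": dict(reference.BASE_RATES),
                     "decrements": dict(reference.DECREMENTS)},
            "table": rows,
        },
        "demand": {
            "reference_decade": {"start_year": ref_decade.start_year,
                                 "end_year": ref_decade.end_year,
                                 "n_surgeries": ref_decade.n_surgeries},
            "prevalence_by_decade_pct": {
                "2001-2011": reporting.prevalence(prev_early),
                "2011-2021": reporting.prevalence(prev),
            },
            "applied_prevalence_pct": reporting.prevalence(prev),
            "by_scenario": demand_rows,
        },
    }
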