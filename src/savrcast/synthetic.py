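"""Synthetic census panels and surgical registries.

Generates data with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any external
download.  The generator emulates a referral region of ~41
municipalities observed at three census waves (2001, 2011, 2021):

* municipality sizes are log-normal, so a few large municipalities
  dominate regional aggregates;
* each municipality's total population follows geometric growth at a
  municipality-specific rate drawn around a regional mean;
* the >=65 population follows its own, faster geometric growth, so the
  region ages;
* the 0-14 share declines (``aging_drift``) and the >=75 share of the
  elderly rises (``longevity_drift``) across decades;
* decade surgery counts are Binomial(end-of-decade regional >=65
  population, true_prevalence/100).

Age-band counts are rounded to integers with the residual assigned to
the 15-64 band, so the band-partition invariant holds exactly.  A single
seed determines all output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .census import CensusPanel, CensusRecord
from .demand import SurgeryDecade
from .errors import SavrcastError


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults mirror the motivating study region: 41 municipalities over
    the 2001/2011/2021 waves; log-normal base sizes (median ~22k
    inhabitants, heavy right tail); total population growing 0.49 %/yr
    and the >=65 population 1.69 %/yr on average, each with 0.6
    percentage-point municipality-level noise; 2001 age structure of
    16% aged 0-14, 17% aged >=65 with 42.6% of those >=75, dispersed
    across municipalities by a log-normal factor (``share_noise_sd``) so
    baseline aging indices span a realistic range; shares drifting to
    reproduce falling youth and rising longevity; a decade
    surgery-to-population ratio of 0.45%.
    """

    n_municipalities: int = 41
    census_years: tuple[int, ...] = (2001, 2011, 2021)
    base_pop_log_mean: float = 10.0
    base_pop_log_sd: float = 1.1
    growth_total: float = 0.49
    growth_total_sd: float = 0.6
    growth_65: float = 1.69
    growth_65_sd: float = 0.6
    share_0_14_start: float = 0.16
    share_65_start: float = 0.17
    share_75_of_65_start: float = 0.426
    share_noise_sd: float = 0.12
    aging_drift: float = 0.015
    longevity_drift: float = 0.033
    true_prevalence: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("share_0_14_start", "share_65_start", "share_75_of_65_start"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SavrcastError(f"{name} must lie in (0, 1), got {v}")
        if self.n_municipalities < 1:
            raise SavrcastError("need at least one municipality")
        if len(self.census_years) < 2:
            raise SavrcastError("need at least two census waves")
        if self.true_prevalence < 0:
            raise SavrcastError("true_prevalence must be non-negative")


def _clip_share(x: float) -> float:
    return float(np.clip(x, 1e-6, 1.0 - 1e-6))


def generate_panel(config: SyntheticConfig) -> CensusPanel:
    """Draw one balanced synthetic census panel.

    Every record satisfies the census invariants; with positive
    ``aging_drift`` (and non-degenerate growth) the regional aging index
    increases across waves.  The same seed yields byte-identical panels.
    """
    rng = np.random.default_rng(config.seed)
    y0 = config.census_years[0]
    base_total = np.exp(
        rng.normal(config.base_pop_log_mean, config.base_pop_log_sd,
                   config.n_municipalities)
    )
    g_total = rng.normal(config.growth_total, config.growth_total_sd,
                         config.n_municipalities)
    g_65 = rng.normal(config.growth_65, config.growth_65_sd,
                      config.n_municipalities)
    # time-constant municipality-level dispersion of baseline shares
    noise = rng.normal(0.0, config.share_noise_sd,
                       (config.n_municipalities, 3))
    records = []
    for i in range(config.n_municipalities):
        name = f"M{i:02d}"
        s014_base = _clip_share(config.share_0_14_start * np.exp(noise[i, 0]))
        s65_base = _clip_share(config.share_65_start * np.exp(noise[i, 1]))
        s75_base = _clip_share(config.share_75_of_65_start * np.exp(noise[i, 2]))
        p65_base = s65_base * base_total[i]
        for year in config.census_years:
            t = year - y0
            decades = t / 10.0
            total = base_total[i] * (1.0 + g_total[i] / 100.0) ** t
            p65 = p65_base * (1.0 + g_65[i] / 100.0) ** t
            s014 = _clip_share(s014_base - config.aging_drift * decades)
            s75 = _clip_share(s75_base + config.longevity_drift * decades)
            n_total = max(1, round(total))
            n65 = min(round(p65), n_total)
            n014 = round(s014 * n_total)
            n1564 = n_total - n65 - n014  # residual keeps partition exact
            if n1564 < 0:
                raise SavrcastError(
                    f"infeasible shares: 15-64 band negative for {name}/{year}"
                )
            n75 = min(round(s75 * n65), n65)
            records.append(
                CensusRecord(
                    municipality=name,
                    year=year,
                    pop_total=n_total,
                    pop_0_14=n014,
                    pop_15_64=n1564,
                    pop_65_plus=n65,
                    pop_75_plus=n75,
                )
            )
    return CensusPanel(records)


def generate_registry(
    panel: CensusPanel,
    true_prevalence: float,
    seed: int,
) -> list[SurgeryDecade]:
    """Draw decade SAVR counts for each inter-census decade of ``panel``.

    For each consecutive pair of census years 10 years apart, surgeries
    ~ Binomial(end-of-decade regional >=65 population,
    true_prevalence/100).
    """
    from .census import aggregate_region

    years = panel.years
    for a, b in zip(years, years[1:]):
        if b - a != 10:
            raise SavrcastError(
                f"census waves must be 10 years apart, got {a}->{b}"
            )
    if true_prevalence < 0:
        raise SavrcastError("true_prevalence must be non-negative")
    rng = np.random.default_rng(seed)
    decades = []
    for a, b in zip(years, years[1:]):
        pop65 = aggregate_region(panel, "all", b).pop_65_plus
        n = int(rng.binomial(pop65, true_prevalence / 100.0))
        decades.append(SurgeryDecade(start_year=a, end_year=b, n_surgeries=n))
    return decades


def null_dynamics(config: SyntheticConfig) -> SyntheticConfig:
    """A copy of ``config`` with all growth, noise and drift switched
    off — age structure is then identical across waves (useful as a
    degenerate control)."""
    return replace(
        config,
        growth_total=0.0,
        growth_total_sd=0.0,
        growth_65=0.0,
        growth_65_sd=0.0,
        aging_drift=0.0,
        longevity_drift=0.0,
    )
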