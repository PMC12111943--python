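import pytest

from savrcast.census import CensusPanel, CensusRecord
from savrcast.synthetic import SyntheticConfig, generate_panel


def record(muni, year, p014, p1564, p65, p75=None, sex="all"):
    """Build a consistent record from band counts (total derived)."""
    return CensusRecord(
        municipality=muni,
        year=year,
        sex=sex,
        pop_total=p014 + p1564 + p65,
        pop_0_14=p014,
        pop_15_64=p1564,
        pop_65_plus=p65,
        pop_75_plus=p75,
    )


@pytest.fixture
def small_panel():
    """3 municipalities x 3 census waves, hand-built, aging over time."""
    recs = []
    bands = {
        "Alfa": {2001: (200, 700, 100, 40), 2011: (180, 690, 130, 55),
                 2021: (160, 660, 180, 85)},
        "Beta": {2001: (50, 300, 80, 35), 2011: (45, 290, 100, 46),
                 2021: (40, 280, 130, 64)},
        "Gama": {2001: (400, 2000, 350, 140), 2011: (380, 1950, 450, 200),
                 2021: (350, 1900, 600, 290)},
    }
    for muni, by_year in bands.items():
        for year, (p014, p1564, p65, p75) in by_year.items():
            recs.append(record(muni, year, p014, p1564, p65, p75))
    return CensusPanel(recs)


@pytest.fixture
def sex_panel():
    """One municipality, one year, all/female/male strata that add up."""
    recs = [
        record("Alfa", 2021, 160, 660, 180, 85, sex="all"),
        record("Alfa", 2021, 80, 340, 100, 50, sex="female"),
        record("Alfa", 2021, 80, 320, 80, 35, sex="male"),
    ]
    return CensusPanel(recs)


@pytest.fixture
def synth_config():
    return SyntheticConfig(seed=42)


@pytest.fixture
def synth_panel(synth_config):
    return generate_panel(synth_config)
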