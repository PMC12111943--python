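"""Census data model, CSV I/O, aggregation and pyramid summaries."""

import pytest

from savrcast.census import (
    CensusPanel,
    CensusRecord,
    aggregate_region,
    pyramid_summary,
    read_census_csv,
    write_census_csv,
)
from savrcast.errors import CapabilityError, SchemaError, ValidationError

from conftest import record


class TestRecordInvariants:
    def test_valid_record_accepted(self):
        rec = record("Lisboa", 2021, 100, 300, 80, 40)
        assert rec.pop_total == 480

    @pytest.mark.parametrize(
        "kwargs",
        [
            # band sum != total
            dict(pop_total=500, pop_0_14=100, pop_15_64=300, pop_65_plus=80),
            # >=75 exceeds >=65
            dict(pop_total=480, pop_0_14=100, pop_15_64=300, pop_65_plus=80,
                 pop_75_plus=81),
            # negative count
            dict(pop_total=280, pop_0_14=-100, pop_15_64=300, pop_65_plus=80),
            # non-integer count
            dict(pop_total=480.0, pop_0_14=100, pop_15_64=300, pop_65_plus=80),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CensusRecord(municipality="X", year=2021, **kwargs)

    def test_duplicate_keys_rejected(self):
        recs = [record("A", 2021, 1, 2, 3), record("A", 2021, 2, 2, 2)]
        with pytest.raises(ValidationError, match="duplicate"):
            CensusPanel(recs)

    def test_missing_75_band_is_allowed(self):
        rec = record("A", 2021, 100, 300, 80, p75=None)
        assert rec.pop_75_plus is None


class TestCsvRoundTrip:
    def test_write_read_identity_on_synthetic_panel(self, synth_panel, tmp_path):
        path = write_census_csv(synth_panel, tmp_path / "panel.csv")
        assert read_census_csv(path) == synth_panel

    def test_write_read_identity_on_sex_panel(self, sex_panel, tmp_path):
        path = write_census_csv(sex_panel, tmp_path / "panel.csv")
        again = read_census_csv(path)
        assert again == sex_panel
        # one row per (municipality, year, sex) plus header
        assert len(path.read_text().strip().splitlines()) == 1 + len(sex_panel)

    def test_empty_panel_writes_header_only(self, tmp_path):
        path = write_census_csv(CensusPanel([]), tmp_path / "empty.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("municipality,")
        assert len(read_census_csv(path)) == 0

    def test_thousands_separators_accepted(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "municipality,year,sex,pop_total,pop_0_14,pop_15_64,"
            "pop_65_plus,pop_75_plus\n"
            'Lisboa,2021,all,"2,319,319","300,000","1,483,425","535,894",'
            '"250,000"\n'
        )
        panel = read_census_csv(p)
        assert panel.get("Lisboa", 2021).pop_total == 2_319_319

    @pytest.mark.parametrize("bad", ["3,5", "1.5", "12,34", "-5", "1e3"])
    def test_non_integer_counts_rejected(self, tmp_path, bad):
        p = tmp_path / "t.csv"
        p.write_text(
            "municipality,year,sex,pop_total,pop_0_14,pop_15_64,"
            "pop_65_plus,pop_75_plus\n"
            f"X,2021,all,{bad},0,0,0,\n"
        )
        with pytest.raises(ValidationError):
            read_census_csv(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("municipality,year,pop_total,pop_0_14,pop_15_64\nX,2021,1,1,0\n")
        with pytest.raises(SchemaError, match="pop_65_plus"):
            read_census_csv(p)

    def test_band_sum_mismatch_names_the_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "municipality,year,sex,pop_total,pop_0_14,pop_15_64,"
            "pop_65_plus,pop_75_plus\n"
            "Beja,2021,all,100,10,10,10,\n"
        )
        with pytest.raises(ValidationError, match="Beja"):
            read_census_csv(p)


class TestAggregation:
    def test_single_municipality_is_identity(self, small_panel):
        agg = aggregate_region(small_panel, ["Alfa"], 2021)
        assert agg == small_panel.get("Alfa", 2021)

    def test_additivity(self, small_panel):
        agg = aggregate_region(small_panel, ["Alfa", "Beta"], 2021)
        assert agg.pop_65_plus == 180 + 130
        assert agg.pop_total == 1000 + 450

    def test_matches_column_sum_oracle(self, synth_panel):
        year = synth_panel.years[-1]
        df = synth_panel.to_frame()
        sub = df[(df.year == year) & (df.sex == "all")]
        agg = aggregate_region(synth_panel, "all", year)
        for col in ("pop_total", "pop_0_14", "pop_15_64", "pop_65_plus",
                    "pop_75_plus"):
            assert getattr(agg, col) == sub[col].sum()

    def test_order_independent_and_associative(self, small_panel):
        munis = ["Alfa", "Beta", "Gama"]
        direct = aggregate_region(small_panel, munis, 2011)
        reverse = aggregate_region(small_panel, munis[::-1], 2011)
        assert direct == reverse
        # associativity: fold a pre-aggregated pair with the remainder
        pair = aggregate_region(small_panel, ["Alfa", "Beta"], 2011)
        assert direct.pop_total == pair.pop_total + small_panel.get("Gama", 2011).pop_total

    def test_missing_year_raises(self, small_panel):
        with pytest.raises(KeyError):
            aggregate_region(small_panel, "all", 1991)


class TestPyramid:
    def test_single_band_all_sexes_is_total(self, small_panel):
        out = pyramid_summary(small_panel, 2021, bands=["total"])
        assert out["count"].iloc[0] == sum(
            small_panel.get(m, 2021).pop_total for m in small_panel.municipalities
        )

    def test_sex_partition(self, sex_panel):
        by_sex = pyramid_summary(sex_panel, 2021)
        alls = pyramid_summary(sex_panel, 2021, sexes=["all"])
        merged = by_sex.groupby("band")["count"].sum()
        for _, row in alls.iterrows():
            assert merged[row["band"]] == row["count"]

    def test_reproduces_configured_sex_total(self):
        # a panel built so the male 2001 total is 1,042,214 returns that cell
        male = record("Region", 2001, 160_000, 750_214, 132_000, sex="male")
        assert male.pop_total == 1_042_214
        panel = CensusPanel([
            male,
            record("Region", 2001, 170_000, 800_005, 155_000, sex="female"),
        ])
        out = pyramid_summary(panel, 2001, bands=["total"])
        cell = out[(out.sex == "male") & (out.band == "total")]["count"].iloc[0]
        assert cell == 1_042_214

    def test_sex_split_on_all_only_panel_raises(self, small_panel):
        with pytest.raises(CapabilityError):
            pyramid_summary(small_panel, 2021, sexes=["female", "male"])

    def test_missing_75_band_raises(self):
        panel = CensusPanel([record("A", 2021, 10, 20, 5, p75=None)])
        with pytest.raises(CapabilityError):
            pyramid_summary(panel, 2021, bands=["75+"])
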