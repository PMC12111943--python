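"""Aging/longevity indices and the across-year rank comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from savrcast.census import CensusPanel
from savrcast.errors import (
    CapabilityError,
    InsufficientDataError,
    UndefinedIndexError,
    ValidationError,
)
from savrcast.indices import (
    IndexTable,
    aging_index,
    compare_years,
    index_table,
    longevity_index,
)

from conftest import record


class TestIndexFormulas:
    @pytest.mark.parametrize(
        "p65,p014,expected", [(100, 100, 100.0), (200, 100, 200.0), (0, 50, 0.0)]
    )
    def test_aging_examples(self, p65, p014, expected):
        assert aging_index(p65, p014) == expected

    @pytest.mark.parametrize(
        "p75,p65,expected", [(50, 100, 50.0), (0, 100, 0.0), (100, 100, 100.0)]
    )
    def test_longevity_examples(self, p75, p65, expected):
        assert longevity_index(p75, p65) == expected

    def test_random_pairs_match_ratio_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b = rng.integers(1, 10**6, 2)
            assert aging_index(a, b) == pytest.approx(100 * a / b, abs=1e-12)
            lo, hi = min(a, b), max(a, b)
            assert longevity_index(lo, hi) == pytest.approx(100 * lo / hi, abs=1e-12)

    def test_zero_denominators_are_undefined_not_infinite(self):
        with pytest.raises(UndefinedIndexError):
            aging_index(10, 0)
        with pytest.raises(UndefinedIndexError):
            longevity_index(0, 0)

    def test_more_75_than_65_rejected(self):
        with pytest.raises(ValidationError):
            longevity_index(101, 100)

    @given(
        p014=st.integers(1, 10**6),
        p65=st.integers(1, 10**6),
        k=st.integers(2, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, p014, p65, k):
        """Multiplying all band counts by k leaves both indices unchanged."""
        assert aging_index(k * p65, k * p014) == pytest.approx(
            aging_index(p65, p014), rel=1e-12
        )
        p75 = p65 // 2
        assert longevity_index(k * p75, k * p65) == pytest.approx(
            longevity_index(p75, p65), rel=1e-12
        )

    @given(p014=st.integers(1, 10**5), p65=st.integers(1, 10**5))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_in_elderly_count(self, p014, p65):
        """More >=65 (others fixed): aging index strictly up, longevity
        strictly down."""
        assert aging_index(p65 + 1, p014) > aging_index(p65, p014)
        p75 = p65 // 2
        if p75 > 0:
            assert longevity_index(p75, p65 + 1) < longevity_index(p75, p65)


class TestIndexTable:
    def test_single_cell_median(self):
        panel = CensusPanel([record("A", 2021, 100, 300, 150, 60)])
        table = index_table(panel, "aging")
        summary = table.summary()
        assert table.values[("A", 2021)] == 150.0
        assert summary["median"].iloc[0] == 150.0
        assert summary["n"].iloc[0] == 1

    def test_threshold_count_matches_bruteforce(self, synth_panel):
        table = index_table(synth_panel, "aging")
        year = synth_panel.years[0]
        brute = sum(
            1
            for m in synth_panel.municipalities
            if 100 * synth_panel.get(m, year).pop_65_plus
            / synth_panel.get(m, year).pop_0_14 < 100
        )
        assert table.count_below(100, year) == brute

    def test_medians_match_numpy_oracle(self, synth_panel):
        for name in ("aging", "longevity"):
            table = index_table(synth_panel, name)
            summary = table.summary()
            for year in synth_panel.years:
                vals = [v for (m, y), v in table.values.items() if y == year]
                row = summary[summary.year == year]
                assert row["median"].iloc[0] == pytest.approx(np.median(vals))
                assert row["low"].iloc[0] == min(vals)
                assert row["high"].iloc[0] == max(vals)

    def test_iqr_spread_option(self, synth_panel):
        table = index_table(synth_panel, "aging")
        rng = table.summary("range")
        iqr = table.summary("iqr")
        assert (iqr["low"] >= rng["low"]).all()
        assert (iqr["high"] <= rng["high"]).all()

    def test_undefined_cells_flagged_not_dropped(self):
        panel = CensusPanel(
            [record("A", 2021, 0, 300, 150, 60), record("B", 2021, 10, 20, 5, 2)]
        )
        table = index_table(panel, "aging")
        assert ("A", 2021) in table.undefined
        assert ("B", 2021) in table.values

    def test_longevity_needs_75_band(self):
        panel = CensusPanel([record("A", 2021, 10, 20, 5, p75=None)])
        with pytest.raises(CapabilityError):
            index_table(panel, "longevity")


def _table(groups: dict[int, list[float]]) -> IndexTable:
    values = {}
    for year, vals in groups.items():
        for i, v in enumerate(vals):
            values[(f"M{i}", year)] = float(v)
    return IndexTable("aging", values)


class TestCompareYears:
    def test_identical_groups_no_signal(self):
        res = compare_years(_table({2001: [1, 2, 3], 2011: [1, 2, 3], 2021: [1, 2, 3]}))
        assert res.omnibus_statistic == pytest.approx(0.0)
        assert res.omnibus_p == pytest.approx(1.0)

    def test_all_values_tied(self):
        res = compare_years(_table({2001: [5, 5], 2011: [5, 5]}))
        assert res.omnibus_statistic == 0.0
        assert res.omnibus_p == 1.0
        assert all(c.p_adjusted == 1.0 for c in res.pairwise)

    def test_matches_bruteforce_rank_oracle(self):
        """Hand-computed ranks for {1,2,3},{4,5,6},{7,8,9}: rank sums
        6/15/24 give H = 7.2; Dunn z from mean ranks 2/5/8."""
        res = compare_years(_table({2001: [1, 2, 3], 2011: [4, 5, 6], 2021: [7, 8, 9]}))
        assert res.omnibus_statistic == pytest.approx(7.2)
        assert res.omnibus_p == pytest.approx(stats.chi2.sf(7.2, 2))
        # Dunn: sigma = sqrt(N(N+1)/12 * (1/3+1/3)) = sqrt(5), no ties
        sigma = math.sqrt(5.0)
        expected = {
            (2001, 2011): (2 - 5) / sigma,
            (2001, 2021): (2 - 8) / sigma,
            (2011, 2021): (5 - 8) / sigma,
        }
        assert len(res.pairwise) == 3
        for c in res.pairwise:
            z = expected[(c.year_a, c.year_b)]
            assert c.z == pytest.approx(z)
            p = 2 * stats.norm.sf(abs(z))
            assert c.p_unadjusted == pytest.approx(p)
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * p))

    def test_tie_correction_matches_scipy(self):
        groups = {2001: [1, 1, 2, 3], 2011: [2, 2, 3, 4], 2021: [3, 4, 4, 5]}
        res = compare_years(_table(groups))
        h, p = stats.kruskal(*[np.array(v, float) for v in groups.values()])
        assert res.omnibus_statistic == pytest.approx(h)
        assert res.omnibus_p == pytest.approx(p)

    def test_invariant_to_municipality_ordering(self):
        rng = np.random.default_rng(3)
        base = {y: list(rng.normal(y - 2000, 1, 8)) for y in (2001, 2011, 2021)}
        shuffled = {y: list(np.array(v)[rng.permutation(len(v))])
                    for y, v in base.items()}
        a, b = compare_years(_table(base)), compare_years(_table(shuffled))
        assert a.omnibus_statistic == pytest.approx(b.omnibus_statistic)
        for ca, cb in zip(a.pairwise, b.pairwise):
            assert ca.p_adjusted == pytest.approx(cb.p_adjusted)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_years(_table({2001: [1, 2, 3]}))
        with pytest.raises(InsufficientDataError):
            compare_years(_table({2001: [1, 2], 2011: [3]}))

    def test_pairwise_count_is_year_pairs(self):
        res = compare_years(
            _table({y: [1, 2, 3, 4] for y in (2001, 2011, 2021, 2031)})
        )
        assert len(res.pairwise) == 6
        assert all(0 <= c.p_adjusted <= 1 for c in res.pairwise)
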