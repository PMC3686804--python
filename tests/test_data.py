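"""IO, validation, region assignment, filtering and species allocation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cbctrend as ct
from cbctrend.data import SurveyDataset, coverage_summary
from cbctrend.errors import (AllocationWarning, EmptyDatasetError, ParseError,
                             RegionAssignmentError, ValidationError)


def _dataset(rows, year_range=None):
    """Build a SurveyDataset from (circle, lat, year, species, count) rows."""
    rec = pd.DataFrame(
        [(c, y, sp, n, 8.0, 0) for c, _, y, sp, n in rows],
        columns=["circle_id", "year", "species", "count", "effort_hours",
                 "boat_used"])
    circ = (pd.DataFrame(
        [(c, lat, -120.0, 10.0, "Salish Sea") for c, lat, _, _, _ in rows],
        columns=["circle_id", "latitude", "longitude", "coast_distance_km",
                 "region"]).drop_duplicates("circle_id"))
    return SurveyDataset(rec, circ, year_range)


class TestReadCountTable:
    def test_toy_csv_parses(self, toy_csv):
        ds = ct.read_count_table(toy_csv)
        assert len(ds.records) == 3
        assert ds.n_circles == 1
        assert set(ds.records.species) == {"WEST", "CLARK", "UNID"}

    def test_negative_count_rejected(self, tmp_path, toy_csv):
        bad = tmp_path / "bad.csv"
        bad.write_text(toy_csv.read_text().replace("90", "-2"))
        with pytest.raises(ValidationError, match="negative count"):
            ct.read_count_table(bad)

    def test_malformed_numeric_names_row(self, tmp_path, toy_csv):
        bad = tmp_path / "bad.csv"
        bad.write_text(toy_csv.read_text().replace(",90,", ",ninety,"))
        with pytest.raises(ParseError, match="line 2"):
            ct.read_count_table(bad)

    def test_missing_effort_rejected(self, tmp_path, toy_csv):
        bad = tmp_path / "bad.csv"
        bad.write_text(toy_csv.read_text().replace(",10,0", ",,0"))
        with pytest.raises(ValidationError, match="effort"):
            ct.read_count_table(bad)

    def test_duplicate_rows_rejected(self, tmp_path, toy_csv):
        txt = toy_csv.read_text()
        bad = tmp_path / "bad.csv"
        bad.write_text(txt + "C1,48.5,-123.1,5,2000,WEST,7,10,0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            ct.read_count_table(bad)

    def test_round_trip_of_simulated_dataset(self, tmp_path, default_sim):
        dataset, _ = default_sim
        path = tmp_path / "rt.csv"
        dataset.write_csv(path)
        back = ct.read_count_table(path, year_range=dataset.year_range)
        a = dataset.records.sort_values(
            ["circle_id", "year", "species"]).reset_index(drop=True)
        b = back.records.sort_values(
            ["circle_id", "year", "species"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_zero_counts_survive_round_trip(self, tmp_path, toy_csv):
        txt = toy_csv.read_text() + "C1,48.5,-123.1,5,2001,WEST,0,6,1\n"
        path = tmp_path / "z.csv"
        path.write_text(txt)
        ds = ct.read_count_table(path)
        zero = ds.records.query("year == 2001")
        assert len(zero) == 1 and zero["count"].iloc[0] == 0
        # 2002 has no rows: a missing survey, not a zero
        assert (2000, 2001) == ds.year_range


class TestAssignRegion:
    def test_coastal_northern_california(self):
        assert ct.assign_region(37.5, -122.4, 30.0) == "Northern California Coast"

    def test_50km_is_interior(self):
        assert ct.assign_region(43.0, -120.0, 50.0) == "Northern Interior"

    def test_just_under_50km_is_coastal(self):
        assert ct.assign_region(43.0, -124.0, 49.99) == \
            "Outer Washington/Oregon Coast"

    def test_missing_coast_distance_is_interior(self):
        assert ct.assign_region(33.0, -106.0, None) == "Southwestern Interior"

    def test_no_match_raises(self):
        rules = [{"region": "nowhere", "coastal": True, "lat_min": 89.0}]
        with pytest.raises(RegionAssignmentError, match="C9"):
            ct.assign_region(40.0, -120.0, 10.0, rules=rules, circle_id="C9")

    @pytest.mark.parametrize("lat,lon,coast,region", [
        (55.0, -131.0, 5, "Alaska/North BC"),
        (48.7, -123.2, 3, "Salish Sea"),
        (46.9, -124.1, 2, "Outer Washington/Oregon Coast"),
        (35.0, -120.6, 8, "Southern California Coast"),
        (47.0, -119.5, 300, "Northern Interior"),
        (39.5, -119.8, 250, "Interior California/Nevada"),
        (33.4, -112.0, 350, "Southwestern Interior"),
    ])
    def test_table_regions(self, lat, lon, coast, region):
        assert ct.assign_region(lat, lon, coast) == region

    def test_assignment_single_valued_over_grid(self):
        # total and single-valued: every plausible circle matches exactly once
        for lat in np.arange(25, 62, 2.1):
            for lon in (-150.0, -123.0, -110.0):
                for coast in (5.0, 120.0, None):
                    assert isinstance(ct.assign_region(lat, lon, coast), str)


class TestFilterCircles:
    def _two_circle_dataset(self, total_a, years_a):
        rows = [("A", 48.0, 1975 + t, "WEST", total_a // years_a)
                for t in range(years_a)]
        rows += [("B", 48.5, 1975 + t, "WEST", 5) for t in range(36)]
        return _dataset(rows, year_range=(1975, 2010))

    def test_nine_birds_total_excluded(self):
        ds = self._two_circle_dataset(total_a=9, years_a=9)
        kept, report = ct.filter_circles(ds)
        assert list(kept.circles.circle_id) == ["B"]
        assert "total count 9 < 10" in report.reason.iloc[0]

    def test_half_coverage_retained(self):
        ds = self._two_circle_dataset(total_a=180, years_a=18)
        kept, _ = ct.filter_circles(ds)
        assert set(kept.circles.circle_id) == {"A", "B"}

    def test_just_under_half_coverage_excluded(self):
        ds = self._two_circle_dataset(total_a=170, years_a=17)
        kept, report = ct.filter_circles(ds)
        assert list(kept.circles.circle_id) == ["B"]
        assert "17 of 36" in report.reason.iloc[0]

    def test_filtering_idempotent(self, default_sim):
        dataset, _ = default_sim
        once, _ = ct.filter_circles(dataset)
        twice, _ = ct.filter_circles(once)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_empty_result_raises(self):
        rows = [("A", 48.0, 2000, "WEST", 1)]
        ds = _dataset(rows, year_range=(1975, 2010))
        with pytest.raises(EmptyDatasetError):
            ct.filter_circles(ds)


class TestAllocateUnidentified:
    def test_proportional_split(self):
        rows = [("A", 48.0, 2000, "WEST", 90), ("A", 48.0, 2000, "CLARK", 10),
                ("A", 48.0, 2000, "UNID", 20)]
        out = ct.allocate_unidentified(_dataset(rows))
        w = out.records.query("species == 'WEST'")["count"].iloc[0]
        c = out.records.query("species == 'CLARK'")["count"].iloc[0]
        assert (w, c) == (108.0, 12.0)
        assert not (out.records.species == "UNID").any()

    def test_no_unidentified_is_identity(self):
        rows = [("A", 48.0, 2000, "WEST", 90), ("A", 48.0, 2000, "CLARK", 10)]
        ds = _dataset(rows)
        out = ct.allocate_unidentified(ds)
        pd.testing.assert_frame_equal(
            ds.records.sort_values("species").reset_index(drop=True),
            out.records.sort_values("species").reset_index(drop=True),
            check_dtype=False)

    def test_fallback_to_region_year_ratio(self):
        # A has only UNID in 2000; B (same region, same year) identified
        # 19 WEST : 1 CLARK, so A's 40 split 38 : 2.
        rows = [("A", 48.0, 2000, "UNID", 40),
                ("B", 48.5, 2000, "WEST", 19), ("B", 48.5, 2000, "CLARK", 1)]
        out = ct.allocate_unidentified(_dataset(rows))
        a = out.records.query("circle_id == 'A'").set_index("species")["count"]
        assert a["WEST"] == pytest.approx(38.0)
        assert a["CLARK"] == pytest.approx(2.0)

    def test_fallback_to_region_all_years_ratio(self):
        # nothing identified anywhere in 2000; region history is 3:1
        rows = [("A", 48.0, 2000, "UNID", 8),
                ("B", 48.5, 2001, "WEST", 30), ("B", 48.5, 2001, "CLARK", 10)]
        out = ct.allocate_unidentified(_dataset(rows))
        a = out.records.query("circle_id == 'A'").set_index("species")["count"]
        assert a["WEST"] == pytest.approx(6.0)
        assert a["CLARK"] == pytest.approx(2.0)

    def test_no_identified_anywhere_warns_and_keeps_unid(self):
        rows = [("A", 48.0, 2000, "UNID", 8)]
        with pytest.warns(AllocationWarning):
            out = ct.allocate_unidentified(_dataset(rows))
        assert out.records.query("species == 'UNID'")["count"].iloc[0] == 8

    @given(w=st.integers(0, 500), c=st.integers(0, 500),
           u=st.integers(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_totals_conserved_exactly(self, w, c, u):
        rows = [("A", 48.0, 2000, "WEST", w), ("A", 48.0, 2000, "CLARK", c),
                ("A", 48.0, 2000, "UNID", u)]
        ds = _dataset(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AllocationWarning)
            out = ct.allocate_unidentified(ds)
        assert out.records["count"].sum() == pytest.approx(w + c + u, abs=1e-9)


class TestCoverageSummary:
    @staticmethod
    def _with_missing(spec):
        """spec: list of (n_circles, n_missing_years) over a 36-year span."""
        rows, k = [], 0
        for n, miss in spec:
            for _ in range(n):
                cid = f"C{k:03d}"
                k += 1
                rows += [(cid, 48.0, 1975 + t, "WEST", 1)
                         for t in range(36 - miss)]
        return _dataset(rows, year_range=(1975, 2010))

    def test_survey_coverage_percentages(self):
        ds = self._with_missing([(50, 0), (54, 3), (28, 8), (31, 14)])
        tab = coverage_summary(ds).set_index("bin")
        assert tab.loc["complete", "n_circles"] == 50
        assert tab.loc["complete", "percent"] == pytest.approx(30.7, abs=0.05)
        assert tab.loc["1-5 missing", "percent"] == pytest.approx(33.1, abs=0.05)
        assert tab.loc["11-18 missing", "percent"] == pytest.approx(19.0, abs=0.05)
        assert tab["percent"].sum() == pytest.approx(100.0)

    def test_all_complete(self):
        ds = self._with_missing([(10, 0)])
        tab = coverage_summary(ds).set_index("bin")
        assert tab.loc["complete", "percent"] == 100.0
        assert tab["n_circles"].sum() == 10

    def test_empty_dataset(self):
        empty = SurveyDataset(
            pd.DataFrame(columns=["circle_id", "year", "species", "count",
                                  "effort_hours", "boat_used"]),
            pd.DataFrame(columns=["circle_id", "latitude", "longitude",
                                  "coast_distance_km", "region"]),
            year_range=(1975, 2010))
        tab = coverage_summary(empty)
        assert (tab["n_circles"] == 0).all()
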