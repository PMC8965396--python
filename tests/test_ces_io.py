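"""Reading, validation, CES filtering and reshaping of ringing records."""

import numpy as np
import pandas as pd
import pytest

from cesdemog import ces_io
from cesdemog.ces_io import (
    FormatError,
    MissingEffortError,
    RecordSet,
    RecordValidationError,
    apply_ces_filters,
    build_capture_histories,
    build_site_year_counts,
    read_records,
)
from conftest import make_records, random_fixture
from helpers import brute_force_counts, brute_force_filter


def effort_table(sites, years, n_visits=10):
    return pd.DataFrame(
        [(s, y, n_visits) for s in sites for y in years],
        columns=["site_id", "year", "n_visits"],
    )


class TestReadRecords:
    def test_well_formed_csv_reads_identity(self, records_csv):
        path = records_csv(
            [
                ("R1", "SP01", "ST01", 2005, 1, "adult"),
                ("R2", "SP01", "ST01", 2005, 2, "juvenile"),
                ("R3", "SP02", "ST02", 2006, 3, "adult"),
            ]
        )
        rs = read_records(path)
        assert len(rs) == 3
        assert list(rs.records["ring_id"]) == ["R1", "R2", "R3"]

    def test_unknown_age_class_names_offending_line(self, records_csv):
        path = records_csv(
            [
                ("R1", "SP01", "ST01", 2005, 1, "unknown"),
                ("R2", "SP01", "ST01", 2005, 2, "adult"),
            ]
        )
        with pytest.raises(RecordValidationError) as err:
            read_records(path)
        assert "line 2" in str(err.value)

    def test_duplicate_capture_rows_collapse_to_one(self, records_csv):
        path = records_csv(
            [
                ("R1", "SP01", "ST01", 2005, 1, "adult"),
                ("R1", "SP01", "ST01", 2005, 1, "adult"),
            ]
        )
        assert len(read_records(path)) == 1

    def test_year_outside_study_window_rejected(self, records_csv):
        path = records_csv([("R1", "SP01", "ST01", 1999, 1, "adult")])
        with pytest.raises(RecordValidationError, match="study window"):
            read_records(path)
        assert len(read_records(path, study_window=None)) == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ring_id,species_code\nR1,SP01\n")
        with pytest.raises(FormatError, match="missing mandatory column"):
            read_records(path)

    def test_unparseable_year_reports_line(self, records_csv):
        path = records_csv([("R1", "SP01", "ST01", "two-thousand", 1, "adult")])
        with pytest.raises(RecordValidationError, match="line 2"):
            read_records(path)

    def test_column_mapping_and_tsv(self, tmp_path):
        path = tmp_path / "r.tsv"
        pd.DataFrame(
            {"ring": ["R1"], "sp": ["SP01"], "plot": ["ST01"], "yr": [2005],
             "v": [1], "age": ["adult"]}
        ).to_csv(path, sep="\t", index=False)
        rs = read_records(
            path,
            format_config={"ring_id": "ring", "species_code": "sp", "site_id": "plot",
                           "year": "yr", "visit": "v", "age_class": "age"},
        )
        assert rs.records.loc[0, "site_id"] == "ST01"


class TestCesFilters:
    def test_site_with_four_qualifying_years_removed(self):
        rows = [(f"R{y}", "SP01", "ST01", y, 1, "adult") for y in range(2004, 2008)]
        rs = RecordSet(make_records(rows))
        effort = effort_table(["ST01"], range(2004, 2008))
        out = apply_ces_filters(rs, effort, min_adults=0, min_juveniles=0)
        assert len(out) == 0

    def test_low_effort_year_removed_others_kept(self):
        rows = [(f"R{y}", "SP01", "ST01", y, 1, "adult") for y in range(2004, 2010)]
        rs = RecordSet(make_records(rows))
        effort = effort_table(["ST01"], range(2004, 2010))
        effort.loc[effort["year"] == 2006, "n_visits"] = 7
        out = apply_ces_filters(rs, effort, min_adults=0, min_juveniles=0)
        assert sorted(out.records["year"]) == [2004, 2005, 2007, 2008, 2009]

    @pytest.mark.parametrize("n_juv, kept", [(24, 0), (25, 50)])
    def test_species_site_capture_minimum_boundary(self, n_juv, kept):
        rows = [(f"A{i}", "SP01", "ST01", 2004 + i % 6, 1, "adult") for i in range(25)]
        rows += [(f"J{i}", "SP01", "ST01", 2004 + i % 6, 2, "juvenile") for i in range(n_juv)]
        rs = RecordSet(make_records(rows))
        effort = effort_table(["ST01"], range(2004, 2010))
        out = apply_ces_filters(rs, effort)
        assert len(out) == (25 + n_juv if kept else 0)

    def test_missing_effort_entry_is_an_error(self):
        rs = RecordSet(make_records([("R1", "SP01", "ST01", 2005, 1, "adult")]))
        effort = effort_table(["ST01"], [2004])
        with pytest.raises(MissingEffortError):
            apply_ces_filters(rs, effort)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        records, effort = random_fixture(rng)
        rs = RecordSet(records)
        out = apply_ces_filters(
            rs, effort, min_years=3, min_visits=8, min_adults=4, min_juveniles=4
        )
        expected = brute_force_filter(rs.records, effort, 3, 8, 4, 4)
        assert len(out) == len(expected)
        got = out.records.sort_values(list(out.records.columns)).reset_index(drop=True)
        want = expected.sort_values(list(expected.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotent_and_monotone(self, seed):
        rng = np.random.default_rng(100 + seed)
        records, effort = random_fixture(rng)
        rs = RecordSet(records)
        kw = dict(min_years=3, min_visits=8, min_adults=3, min_juveniles=3)
        once = apply_ces_filters(rs, effort, **kw)
        twice = apply_ces_filters(once, effort, **kw)
        pd.testing.assert_frame_equal(once.records, twice.records)
        for harder in (
            dict(kw, min_years=4), dict(kw, min_visits=9),
            dict(kw, min_adults=5), dict(kw, min_juveniles=5),
        ):
            assert len(apply_ces_filters(rs, effort, **harder)) <= len(once)


class TestSiteYearCounts:
    def test_repeat_captures_within_season_count_once(self):
        rs = RecordSet(
            make_records(
                [
                    ("R1", "SP01", "ST01", 2005, 3, "adult"),
                    ("R1", "SP01", "ST01", 2005, 7, "adult"),
                ]
            )
        )
        counts = build_site_year_counts(rs)
        assert counts.loc[0, "n_adult"] == 1

    def test_distinct_individuals_counted(self):
        rows = [(f"A{i}", "SP01", "ST01", 2005, 1, "adult") for i in range(10)]
        rows += [(f"J{i}", "SP01", "ST01", 2005, 1, "juvenile") for i in range(15)]
        counts = build_site_year_counts(RecordSet(make_records(rows)))
        assert (counts.loc[0, "n_adult"], counts.loc[0, "n_juvenile"]) == (10, 15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_cross_year_recaptures(self, seed):
        rng = np.random.default_rng(200 + seed)
        records, _ = random_fixture(rng, n_records=150)
        rs = RecordSet(records)
        counts = build_site_year_counts(rs)
        expected = brute_force_counts(rs.records)
        assert len(counts) == len(expected)
        for row in counts.itertuples():
            assert expected[(row.species_code, row.site_id, row.year)] == (
                row.n_adult,
                row.n_juvenile,
            )

    def test_total_individuals_identity(self):
        rng = np.random.default_rng(7)
        records, _ = random_fixture(rng, n_records=300)
        rs = RecordSet(records)
        counts = build_site_year_counts(rs)
        distinct = rs.records.drop_duplicates(subset=["species_code", "site_id", "year", "ring_id"])
        assert (counts["n_adult"] + counts["n_juvenile"]).sum() == len(distinct)


class TestCaptureHistories:
    def test_direct_encoding_with_gap(self):
        rs = RecordSet(
            make_records(
                [
                    ("R1", "SP01", "ST01", 2005, 1, "adult"),
                    ("R1", "SP01", "ST01", 2007, 2, "adult"),
                ]
            )
        )
        chms = build_capture_histories(rs, site_years={"ST01": range(2004, 2009)})
        assert len(chms) == 1
        np.testing.assert_array_equal(chms[0].histories[0], [0, 1, 0, 1, 0])
        assert chms[0].first_idx[0] == 1

    def test_first_capture_as_juvenile_excluded(self):
        rs = RecordSet(
            make_records(
                [
                    ("R1", "SP01", "ST01", 2005, 1, "juvenile"),
                    ("R1", "SP01", "ST01", 2006, 1, "adult"),
                    ("R2", "SP01", "ST01", 2006, 1, "adult"),
                ]
            )
        )
        chms = build_capture_histories(rs)
        assert chms[0].ring_ids == ["R2"]

    def test_two_sites_give_independent_histories(self):
        rs = RecordSet(
            make_records(
                [
                    ("R1", "SP01", "ST01", 2005, 1, "adult"),
                    ("R1", "SP01", "ST02", 2006, 1, "adult"),
                ]
            )
        )
        chms = build_capture_histories(rs)
        assert {(c.site_id, c.n_individuals) for c in chms} == {("ST01", 1), ("ST02", 1)}

    def test_matches_brute_force_presence_table(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            site = f"ST{rng.integers(1, 3):02d}"
            first = int(rng.integers(2004, 2009))
            rows.append((f"R{i:03d}", "SP01", site, first, 1, "adult"))
            for y in range(first + 1, 2010):
                if rng.random() < 0.4:
                    rows.append((f"R{i:03d}", "SP01", site, y, 2, "adult"))
        rs = RecordSet(make_records(rows))
        site_years = {"ST01": range(2004, 2010), "ST02": range(2004, 2010)}
        chms = build_capture_histories(rs, site_years=site_years)
        df = rs.records
        for chm in chms:
            for ring, hist in zip(chm.ring_ids, chm.histories):
                seen = set(df[(df.ring_id == ring) & (df.site_id == chm.site_id)]["year"])
                np.testing.assert_array_equal(hist, [int(y in seen) for y in chm.years])

    def test_roundtrip_through_delimited_file(self, tmp_path):
        rng = np.random.default_rng(4)
        records, _ = random_fixture(rng, n_records=80)
        rs = RecordSet(records)
        chms = build_capture_histories(rs)
        path = tmp_path / "h.csv"
        ces_io.write_histories(chms, path)
        back = ces_io.read_histories(path)
        assert len(back) == len(chms)
        for a, b in zip(chms, sorted(back, key=lambda c: (c.species_code, c.site_id))):
            np.testing.assert_array_equal(a.histories, b.histories)
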