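"""Occurrence fetching, user-CSV ingestion and record cleaning."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import occ_set
from lcscreen.backends import FixtureOccurrenceBackend
from lcscreen.errors import ConfigurationError, SchemaError
from lcscreen.occurrences import (
    OccurrenceRecord,
    OccurrenceSet,
    clean_records,
    fetch_occurrences,
    load_user_occurrences,
)


def _backend(records):
    return FixtureOccurrenceBackend({"7": {"records": records}})


def test_fetch_drops_ungeoreferenced_records():
    backend = _backend(
        [
            {"decimalLongitude": 1.0, "decimalLatitude": 2.0, "gbifID": "a"},
            {"decimalLongitude": None, "decimalLatitude": None, "gbifID": "b"},
            {"decimalLongitude": 3.0, "decimalLatitude": 4.0, "gbifID": "c"},
            {"decimalLatitude": 5.0, "gbifID": "d"},
            {"decimalLongitude": 5.0, "decimalLatitude": 6.0, "gbifID": "e"},
        ]
    )
    out = fetch_occurrences("7", backend)
    assert [r.source_id for r in out.records] == ["a", "c", "e"]
    assert out.truncated is False


def test_fetch_drops_issue_flagged_records():
    backend = _backend(
        [
            {"decimalLongitude": 1.0, "decimalLatitude": 2.0, "gbifID": "a",
             "hasGeospatialIssue": True},
            {"decimalLongitude": 3.0, "decimalLatitude": 4.0, "gbifID": "b"},
        ]
    )
    assert [r.source_id for r in fetch_occurrences("7", backend).records] == ["b"]


def test_fetch_empty_backend_yields_empty_set():
    out = fetch_occurrences("7", _backend([]))
    assert len(out) == 0 and out.truncated is False


@pytest.mark.parametrize("limit", [500, 999, 10001, 0, -5])
def test_fetch_limit_outside_bounds_is_a_configuration_error(limit):
    with pytest.raises(ConfigurationError):
        fetch_occurrences("7", _backend([]), limit=limit)


def test_fetch_truncates_in_backend_order():
    records = [
        {"decimalLongitude": i * 0.1, "decimalLatitude": 1.0, "gbifID": str(i)}
        for i in range(1500)
    ]
    out = fetch_occurrences("7", _backend(records), limit=1000)
    assert len(out) == 1000
    assert out.truncated is True
    assert [r.source_id for r in out.records] == [str(i) for i in range(1000)]


def test_user_csv_grouped_and_malformed_rows_counted(tmp_path):
    path = tmp_path / "points.csv"
    path.write_text(
        "name,decimalLatitude,decimalLongitude\n"
        "Sp one,1.0,2.0\n"
        "Sp one,abc,3.0\n"
        "Sp one,1.5,2.5\n"
        "Sp two,-4.0,5.0\n",
        encoding="utf-8",
    )
    sets = load_user_occurrences(path)
    assert len(sets["Sp one"]) == 2 and sets["Sp one"].dropped_count == 1
    assert len(sets["Sp two"]) == 1 and sets["Sp two"].dropped_count == 0


def test_user_csv_missing_columns_is_a_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("name\nSp one\n", encoding="utf-8")
    with pytest.raises(SchemaError) as err:
        load_user_occurrences(path)
    assert "decimalLatitude" in str(err.value)


def test_user_csv_null_island_row_dropped(tmp_path):
    path = tmp_path / "points.csv"
    path.write_text(
        "name,decimalLatitude,decimalLongitude\nSp,0,0\nSp,1.0,1.0\n",
        encoding="utf-8",
    )
    sets = load_user_occurrences(path)
    assert sets["Sp"].coordinates() == [(1.0, 1.0)]
    assert sets["Sp"].dropped_count == 1


def test_clean_collapses_duplicates_and_enforces_bounds():
    raw = occ_set([(1.0, 2.0), (1.0, 2.0), (3.0, 95.0), (181.0, 0.0), (4.0, 5.0)])
    out = clean_records(raw)
    assert out.coordinates() == [(1.0, 2.0), (4.0, 5.0)]
    assert out.dropped_count == 2  # out-of-range rows; duplicates just collapse


def test_clean_ten_records_three_duplicate_pairs():
    coords = [(0.0, 1.0), (2.0, 3.0), (0.0, 1.0), (4.0, 5.0), (2.0, 3.0),
              (6.0, 7.0), (8.0, 9.0), (4.0, 5.0), (10.0, 11.0), (12.0, 13.0)]
    out = clean_records(occ_set(coords))
    assert len(out) == len(set(coords)) == 7


def test_retained_limit_invariant_enforced():
    with pytest.raises(ValueError):
        OccurrenceSet(
            taxon_ref="t",
            records=(OccurrenceRecord(1.0, 2.0), OccurrenceRecord(3.0, 4.0)),
            requested_limit=1,
        )


coord = st.tuples(
    st.floats(min_value=-200, max_value=200, allow_nan=False),
    st.floats(min_value=-100, max_value=100, allow_nan=False),
)


@settings(max_examples=100, derandomize=True)
@given(st.lists(coord, max_size=30))
def test_clean_is_idempotent_and_a_subset(coords):
    raw = occ_set(coords)
    once = clean_records(raw)
    twice = clean_records(once)
    assert twice.records == once.records
    assert set(once.records) <= set(raw.records)
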