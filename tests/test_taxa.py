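"""Name normalization, backbone matching and batch screening."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcscreen.backends import FixtureBackbone, FixtureRangeProvider
from lcscreen.errors import BatchLimitError, ConfigurationError
from lcscreen.taxa import (
    MatchType,
    NameMatchResult,
    NativeRange,
    TaxonQuery,
    lookup_native_range,
    match_name,
    screen_batch,
)

BACKBONE = FixtureBackbone(
    [
        {"canonicalName": "Aloe zebrina", "authorship": "Baker",
         "family": "Asphodelaceae", "usageKey": 1, "status": "ACCEPTED"},
        {"canonicalName": "Aloe zebrifolia", "authorship": "X.",
         "family": "Asphodelaceae", "usageKey": 2, "status": "ACCEPTED"},
        {"canonicalName": "Aloe platyphylla", "authorship": "Baker",
         "family": "Asphodelaceae", "usageKey": 3, "status": "SYNONYM",
         "acceptedName": "Aloe zebrina"},
        {"canonicalName": "Aloe", "authorship": "L.", "family": "Asphodelaceae",
         "usageKey": 4, "status": "ACCEPTED", "rank": "GENUS"},
    ]
)

RANGES = FixtureRangeProvider(
    {
        "Aloe zebrina": {"powo_id": "p1", "native": ["ANG", "ZAM"], "introduced": ["CPP"]},
        "Aloe zebrifolia": {"powo_id": "p2", "native": ["BER"], "introduced": []},
    }
)


@pytest.mark.parametrize(
    "raw, normalized, is_binomial, had_infra",
    [
        ("Aloe zebrina", "Aloe zebrina", True, False),
        ("  aloe   ZEBRINA ", "Aloe zebrina", True, False),
        ("Aloe zebrina var. laeta", "Aloe zebrina", True, True),
        ("Aloe zebrina subsp. foo", "Aloe zebrina", True, True),
        ("Aloe", "Aloe", False, False),
        ("", "", False, False),
    ],
)
def test_query_normalization(raw, normalized, is_binomial, had_infra):
    q = TaxonQuery.from_raw(raw)
    assert q.normalized_name == normalized
    assert q.is_binomial is is_binomial
    assert q.had_infraspecific is had_infra


def test_exact_match_tops_the_list():
    res = match_name(TaxonQuery.from_raw("Aloe zebrina"), BACKBONE)
    assert res[0].canonical_name == "Aloe zebrina"
    assert res[0].authorship == "Baker"
    assert res[0].match_type is MatchType.EXACT
    assert res[0].confidence == 100.0


def test_fuzzy_match_scores_strictly_below_exact():
    exact = match_name(TaxonQuery.from_raw("Aloe zebrina"), BACKBONE)[0]
    fuzzy = match_name(TaxonQuery.from_raw("Aloe zebrna"), BACKBONE)[0]
    assert fuzzy.canonical_name == "Aloe zebrina"
    assert fuzzy.match_type is MatchType.FUZZY
    assert fuzzy.confidence < exact.confidence


def test_confidence_sequence_non_increasing_and_ties_deterministic():
    res = match_name(TaxonQuery.from_raw("Aloe zebrina"), BACKBONE)
    confs = [r.confidence for r in res]
    assert confs == sorted(confs, reverse=True)
    # rerun yields the identical ordering
    again = match_name(TaxonQuery.from_raw("Aloe zebrina"), BACKBONE)
    assert [r.canonical_name for r in res] == [r.canonical_name for r in again]


def test_empty_query_errors_without_touching_the_backend():
    class ExplodingBackbone:
        def search(self, name):  # pragma: no cover - must never run
            raise AssertionError("backend was called for an empty query")

    with pytest.raises(ConfigurationError):
        match_name(TaxonQuery.from_raw(""), ExplodingBackbone())


def test_no_candidate_returns_empty_list():
    assert match_name(TaxonQuery.from_raw("Fakeus notrealis"), BACKBONE) == []


def test_match_result_invariants_enforced():
    with pytest.raises(ValueError):
        NameMatchResult("X y", "", "", None, 150.0, MatchType.EXACT, False, "X y")
    with pytest.raises(ValueError):
        NameMatchResult("X y", "", "", 1, 50.0, MatchType.NONE, False, "X y")
    with pytest.raises(ValueError):
        NameMatchResult("X y", "", "", 1, 50.0, MatchType.EXACT, True, None)


def test_native_range_passthrough_and_disjointness():
    match = match_name(TaxonQuery.from_raw("Aloe zebrina"), BACKBONE)[0]
    nrange = lookup_native_range(match, RANGES)
    assert nrange.native_codes == {"ANG", "ZAM"}
    assert nrange.introduced_codes == {"CPP"}
    with pytest.raises(ValueError):
        NativeRange("p", frozenset({"ANG"}), frozenset({"ANG"}))
    with pytest.raises(ValueError):
        NativeRange("p", frozenset({"angola"}))


def test_range_not_found_is_a_value_not_an_error():
    match = NameMatchResult("Nowhere plantus", "", "", 9, 100.0,
                            MatchType.EXACT, False, "Nowhere plantus")
    assert lookup_native_range(match, RANGES) is None
    with pytest.raises(ConfigurationError):
        lookup_native_range(
            NameMatchResult("X y", "", "", None, 0.0, MatchType.NONE, False, None),
            RANGES,
        )


def test_screen_batch_partitions_accepted_synonym_unmatched():
    queries = [TaxonQuery.from_raw(n) for n in
               ["Aloe zebrina", "Aloe platyphylla", "Fakeus notrealis"]]
    report = screen_batch(queries, BACKBONE, RANGES)
    assert len(report.accepted) == 1
    assert report.excluded_synonyms == ["Aloe platyphylla"]
    assert report.synonym_accepted_names["Aloe platyphylla"] == "Aloe zebrina"
    assert report.unmatched == ["Fakeus notrealis"]


def test_screen_batch_limits():
    with pytest.raises(ConfigurationError):
        screen_batch([], BACKBONE, RANGES)
    names = [TaxonQuery.from_raw(f"Genus sp{i}") for i in range(101)]
    with pytest.raises(BatchLimitError) as err:
        screen_batch(names, BACKBONE, RANGES)
    assert "100" in str(err.value)


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.sampled_from(
            ["Aloe zebrina", "Aloe zebrifolia", "Aloe platyphylla",
             "Fakeus notrealis", "Aloe", "Aloe zebrna"]
        ),
        min_size=1, max_size=20,
    )
)
def test_screen_batch_partition_property(names):
    """|accepted| + |synonyms| + |unmatched| always equals the input size."""
    queries = [TaxonQuery.from_raw(n) for n in names]
    report = screen_batch(queries, BACKBONE, RANGES)
    total = len(report.accepted) + len(report.excluded_synonyms) + len(report.unmatched)
    assert total == len(names)
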