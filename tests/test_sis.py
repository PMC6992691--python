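"""Assessment-bundle construction, serialization and validation."""

import numpy as np
import pytest

from conftest import filtered
from lcscreen.classify import GaugeResult
from lcscreen.errors import ConfigurationError
from lcscreen.metrics import RangeMetrics
from lcscreen.sis import (
    TABLE_NAMES,
    AssessedTaxon,
    AssessmentDefaults,
    build_bundle,
    empty_bundle,
    read_bundle,
    validate_bundle,
    write_bundle,
)
from lcscreen.taxa import MatchType, NameMatchResult, NativeRange

PASS_GAUGE = GaugeResult(True, True, True, True, least_concern=True)
FAIL_GAUGE = GaugeResult(False, True, True, True, least_concern=False)


def make_taxon(name="Sedum bermudense", family="Crassulaceae", native=("BER",),
               gauge=PASS_GAUGE, n_points=0, seed=0):
    match = NameMatchResult(name, "Auth.", family, 1, 100.0,
                            MatchType.EXACT, False, name)
    rng = np.random.default_rng(seed)
    pts = filtered(
        [tuple(c) for c in rng.uniform(-60, -55, (n_points, 2))],
        regions_hit=set(native),
    ) if n_points else None
    return AssessedTaxon(
        match=match,
        native_range=NativeRange("powo-1", frozenset(native)),
        metrics=RangeMetrics(50000.0, 5000.0, 120, 6),
        gauge=gauge,
        occurrences=pts,
    )


def test_single_taxon_bundle_content():
    bundle = build_bundle([make_taxon()])
    assert len(bundle.tables["taxonomy"]) == 1
    tax = bundle.tables["taxonomy"][0]
    assert (tax["genus"], tax["species"]) == ("Sedum", "bermudense")
    countries = bundle.tables["countries"]
    assert len(countries) == 1
    assert countries[0]["country"] == "Bermuda"
    assert countries[0]["wgsrpd_l3_code"] == "BER"
    assess = bundle.tables["assessments"][0]
    assert assess["redlist_category"] == "LC"
    assert "Sedum bermudense" in assess["rationale"]
    assert validate_bundle(bundle) == []


def test_ids_sequential_and_key_discipline():
    bundle = build_bundle([make_taxon("Aloe zebrina"), make_taxon("Protea repens")])
    assert bundle.taxon_ids() == {"1", "2"}
    for name in TABLE_NAMES:
        assert {row["internal_taxon_id"] for row in bundle.tables[name]} <= {"1", "2"}


def test_non_lc_taxon_rejected():
    with pytest.raises(ConfigurationError, match="did not pass"):
        build_bundle([make_taxon(gauge=FAIL_GAUGE)])


def test_unknown_l3_code_falls_back_to_the_code():
    bundle = build_bundle([make_taxon(native=("QQQ",))])
    assert bundle.tables["countries"][0]["country"] == "QQQ"


def test_multiple_habitats_repeat_the_key():
    defaults = AssessmentDefaults(
        habitats=(("1", "Forest"), ("3.5", "Subtropical/Tropical Dry Shrubland"))
    )
    bundle = build_bundle([make_taxon()], defaults)
    habs = bundle.tables["habitats"]
    assert len(habs) == 2
    assert {h["internal_taxon_id"] for h in habs} == {"1"}
    assert validate_bundle(bundle) == []


def test_points_table_carries_map_standard_attributes():
    bundle = build_bundle([make_taxon(n_points=5)])
    assert len(bundle.points) == 5
    row = bundle.points[0]
    assert (row["presence"], row["origin"], row["seasonal"]) == (
        "Extant", "Native", "Resident")
    assert row["binomial"] == "Sedum bermudense"


def test_write_read_round_trip_identity(tmp_path):
    bundle = build_bundle(
        [make_taxon("Aloe zebrina", native=("ANG", "ZAM"), n_points=7),
         make_taxon("Protea repens", native=("CPP",), n_points=3)]
    )
    paths = write_bundle(bundle, tmp_path)
    assert paths.zip_path.exists() and paths.points_path.exists()
    again = read_bundle(tmp_path)
    assert again.tables == bundle.tables
    assert again.points == bundle.points


def test_empty_bundle_writes_header_only_csvs(tmp_path):
    paths = write_bundle(empty_bundle(), tmp_path)
    for name, path in paths.csv_paths.items():
        lines = path.read_text(encoding="utf-8").strip().splitlines()
        assert len(lines) == 1 and "internal_taxon_id" in lines[0]
    import zipfile

    with zipfile.ZipFile(paths.zip_path) as zf:
        assert sorted(zf.namelist()) == sorted(f"{n}.csv" for n in TABLE_NAMES)
    assert read_bundle(tmp_path).tables == empty_bundle().tables


def test_validation_flags_orphans_duplicates_and_bad_category():
    bundle = build_bundle([make_taxon()])
    bundle.tables["habitats"].append({"internal_taxon_id": "99", "habitat_code": "1"})
    violations = validate_bundle(bundle)
    assert any("orphan" in v and "habitats" in v and "99" in v for v in violations)

    bundle2 = build_bundle([make_taxon()])
    bundle2.tables["taxonomy"].append(dict(bundle2.tables["taxonomy"][0]))
    assert any("duplicate" in v for v in validate_bundle(bundle2))

    bundle3 = build_bundle([make_taxon()])
    bundle3.tables["assessments"][0]["redlist_category"] = "VU"
    assert any("expected 'LC'" in v for v in validate_bundle(bundle3))
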