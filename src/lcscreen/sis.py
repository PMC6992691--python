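"""Assessment-bundle export in the SIS Connect multi-CSV exchange format.

Species passing the Least Concern screen are documented as a bundle of
seven cross-linked CSV tables — allfields, assessments, countries,
credits, habitats, plantspecific, taxonomy — all keyed by
``internal_taxon_id``, plus a per-occurrence point-distribution CSV for
the range map. Most tables carry one row per taxon; one-to-many tables
(countries, habitats) repeat the key.

The exchange format's exact column sets are not frozen anywhere public,
so they ship as a versioned schema config (``data/sis_schema.json``):
schema drift is a configuration change, not a code change. Required
fields with no computable value are filled from overridable defaults
(category "LC", population trend "Unknown", habitat "Unknown", …).
"""

from __future__ import annotations

import csv
import json
import zipfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .classify import GaugeResult
from .errors import ConfigurationError
from .metrics import RangeMetrics
from .regions import FilteredOccurrences
from .taxa import NameMatchResult, NativeRange

TABLE_NAMES = (
    "allfields", "assessments", "countries", "credits",
    "habitats", "plantspecific", "taxonomy",
)

DEFAULT_RATIONALE = (
    "{name} has a wide distribution (extent of occurrence {eoo:.0f} km2, "
    "area of occupancy {aoo:.0f} km2 on a 10 km grid, {records} unique "
    "occurrence records across {tdwg} botanical countries in its native "
    "range) and no known major range-wide threats. It is therefore "
    "assessed as Least Concern."
)


def _load_schema() -> dict:
    with resources.files("lcscreen.data").joinpath("sis_schema.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


def _load_country_lookup() -> dict[str, str]:
    lookup: dict[str, str] = {}
    with resources.files("lcscreen.data").joinpath("wgsrpd_l3_countries.csv").open(
        encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(fh):
            lookup[row["l3_code"]] = row["country"]
    return lookup


@dataclass(frozen=True)
class AssessmentDefaults:
    """Overridable boilerplate for the generated assessment documents."""

    category_code: str = "LC"
    rationale_template: str = DEFAULT_RATIONALE
    population_trend: str = "Unknown"
    ecological_system: str = "Terrestrial"
    #: (code, name) pairs of the IUCN habitat classification; 18 = Unknown.
    habitats: tuple[tuple[str, str], ...] = (("18", "Unknown"),)
    growth_form: str = "Unknown"
    assessor: str = "Range-based screening pipeline"
    assessment_date: str = ""
    language: str = "English"
    bibliography: tuple[str, ...] = (
        "GBIF.org: GBIF occurrence download.",
        "POWO: Plants of the World Online. Royal Botanic Gardens, Kew.",
    )


@dataclass(frozen=True)
class AssessedTaxon:
    """Everything known about one screened taxon, ready for export."""

    match: NameMatchResult
    native_range: NativeRange
    metrics: RangeMetrics
    gauge: GaugeResult
    occurrences: FilteredOccurrences | None = None


@dataclass
class SISBundle:
    """Seven cross-linked tables plus the point-distribution table.

    All cell values are strings (the on-disk representation), so a
    write/read round trip reproduces the bundle exactly.
    """

    tables: dict[str, list[dict[str, str]]]
    points: list[dict[str, str]] = field(default_factory=list)
    schema_version: str = "1.0"

    def taxon_ids(self) -> set[str]:
        return {row["internal_taxon_id"] for row in self.tables["taxonomy"]}


@dataclass(frozen=True)
class BundlePaths:
    """Filesystem locations of a written bundle."""

    zip_path: Path
    csv_paths: dict[str, Path]
    points_path: Path


def empty_bundle() -> SISBundle:
    return SISBundle(tables={name: [] for name in TABLE_NAMES})


def build_bundle(
    taxa: list[AssessedTaxon], defaults: AssessmentDefaults | None = None
) -> SISBundle:
    """Assemble the bundle for taxa that passed the Least Concern screen.

    ``internal_taxon_id`` is assigned sequentially from 1 in input order.
    Countries rows are derived from the native Level-3 codes through the
    bundled region-to-country lookup (unknown codes fall back to the code
    itself so nothing is silently dropped). Any taxon that did not pass
    the screen is rejected: the bundle documents Least Concern
    assessments only.
    """
    defaults = defaults or AssessmentDefaults()
    lookup = _load_country_lookup()
    bundle = empty_bundle()
    for i, taxon in enumerate(taxa, start=1):
        if not taxon.gauge.least_concern:
            raise ConfigurationError(
                f"taxon {taxon.match.canonical_name!r} did not pass the "
                "Least Concern screen; refusing to document it as LC"
            )
        tid = str(i)
        name = taxon.match.canonical_name
        parts = name.split(" ", 1)
        genus, species = parts[0], parts[1] if len(parts) > 1 else ""
        m = taxon.metrics
        bundle.tables["taxonomy"].append(
            {
                "internal_taxon_id": tid,
                "family": taxon.match.family,
                "genus": genus,
                "species": species,
                "taxonomic_authority": taxon.match.authorship,
            }
        )
        bundle.tables["assessments"].append(
            {
                "internal_taxon_id": tid,
                "redlist_category": defaults.category_code,
                "redlist_criteria": "",
                "rationale": defaults.rationale_template.format(
                    name=name, eoo=m.eoo_km2, aoo=m.aoo_km2,
                    records=m.record_count, tdwg=m.tdwg_count,
                ),
                "population_trend": defaults.population_trend,
                "assessment_date": defaults.assessment_date,
                "language": defaults.language,
            }
        )
        bundle.tables["allfields"].append(
            {
                "internal_taxon_id": tid,
                "eoo_km2": repr(float(m.eoo_km2)),
                "aoo_km2": repr(float(m.aoo_km2)),
                "record_count": str(m.record_count),
                "tdwg_count": str(m.tdwg_count),
                "ecological_system": defaults.ecological_system,
                "bibliography": " | ".join(defaults.bibliography),
            }
        )
        for code in sorted(taxon.native_range.native_codes):
            bundle.tables["countries"].append(
                {
                    "internal_taxon_id": tid,
                    "country": lookup.get(code, code),
                    "wgsrpd_l3_code": code,
                    "presence": "Extant",
                    "origin": "Native",
                    "seasonality": "Resident",
                }
            )
        bundle.tables["credits"].append(
            {
                "internal_taxon_id": tid,
                "credit_type": "Assessor",
                "name": defaults.assessor,
                "order": "1",
            }
        )
        for code, hab_name in defaults.habitats:
            bundle.tables["habitats"].append(
                {
                    "internal_taxon_id": tid,
                    "habitat_code": code,
                    "habitat_name": hab_name,
                    "suitability": "Suitable",
                    "season": "Resident",
                    "major_importance": "",
                }
            )
        bundle.tables["plantspecific"].append(
            {"internal_taxon_id": tid, "growth_form": defaults.growth_form}
        )
        if taxon.occurrences is not None:
            for rec in taxon.occurrences.retained.records:
                bundle.points.append(
                    {
                        "internal_taxon_id": tid,
                        "binomial": name,
                        "dec_long": repr(float(rec.longitude)),
                        "dec_lat": repr(float(rec.latitude)),
                        "presence": "Extant",
                        "origin": "Native",
                        "seasonal": "Resident",
                        "source_id": rec.source_id,
                    }
                )
    return bundle


def _write_csv(fh, columns: list[str], rows: list[dict[str, str]]):
    writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
    writer.writeheader()
    for row in rows:
        writer.writerow({c: row.get(c, "") for c in columns})


def write_bundle(bundle: SISBundle, out_dir: str | Path) -> BundlePaths:
    """Write the seven table CSVs, their zip archive, and the points CSV.

    The zip contains exactly the seven table files (``allfields.csv`` …
    ``taxonomy.csv``); the point-distribution CSV is written alongside
    as its own download. All files are UTF-8, comma-delimited, quoted
    where needed.
    """
    schema = _load_schema()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        path = out_dir / f"{name}.csv"
        with path.open("w", encoding="utf-8", newline="") as fh:
            _write_csv(fh, schema["tables"][name], bundle.tables.get(name, []))
        csv_paths[name] = path
    zip_path = out_dir / "sis_bundle.zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in TABLE_NAMES:
            zf.write(csv_paths[name], arcname=f"{name}.csv")
    points_path = out_dir / "points.csv"
    with points_path.open("w", encoding="utf-8", newline="") as fh:
        _write_csv(fh, schema["points"], bundle.points)
    return BundlePaths(zip_path=zip_path, csv_paths=csv_paths, points_path=points_path)


def read_bundle(out_dir: str | Path) -> SISBundle:
    """Read a written bundle back from its directory of CSVs."""
    schema = _load_schema()
    out_dir = Path(out_dir)
    tables: dict[str, list[dict[str, str]]] = {}
    for name in TABLE_NAMES:
        with (out_dir / f"{name}.csv").open(encoding="utf-8", newline="") as fh:
            tables[name] = list(csv.DictReader(fh))
    with (out_dir / "points.csv").open(encoding="utf-8", newline="") as fh:
        points = list(csv.DictReader(fh))
    return SISBundle(tables=tables, points=points, schema_version=schema["version"])


def validate_bundle(bundle: SISBundle) -> list[str]:
    """Referential-integrity checks; an empty list means the bundle is valid.

    Checks: every key used anywhere appears in taxonomy; taxonomy and
    assessments carry exactly one row per taxon; every assessment's
    category is LC.
    """
    violations: list[str] = []
    taxonomy_rows = bundle.tables.get("taxonomy", [])
    tax_keys = [row["internal_taxon_id"] for row in taxonomy_rows]
    key_set = set(tax_keys)
    if len(tax_keys) != len(key_set):
        dupes = sorted({k for k in tax_keys if tax_keys.count(k) > 1})
        violations.append(f"duplicate taxonomy rows for internal_taxon_id {dupes}")
    for name in TABLE_NAMES:
        for row in bundle.tables.get(name, []):
            if row["internal_taxon_id"] not in key_set:
                violations.append(
                    f"orphan internal_taxon_id {row['internal_taxon_id']} in {name}"
                )
    for row in bundle.points:
        if row["internal_taxon_id"] not in key_set:
            violations.append(
                f"orphan internal_taxon_id {row['internal_taxon_id']} in points"
            )
    assess = bundle.tables.get("assessments", [])
    assess_keys = [row["internal_taxon_id"] for row in assess]
    if sorted(assess_keys) != sorted(tax_keys):
        violations.append("assessments must carry exactly one row per taxonomy key")
    for row in assess:
        if row.get("redlist_category") != "LC":
            violations.append(
                f"assessment for internal_taxon_id {row['internal_taxon_id']} "
                f"has category {row.get('redlist_category')!r}, expected 'LC'"
            )
    return violations
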