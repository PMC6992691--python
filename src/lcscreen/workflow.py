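"""End-to-end screening workflows composing the pipeline stages.

These are the library-level equivalents of the single-species and batch
runs: resolve names, retrieve and clean occurrences (from a backend or a
user-supplied point table), restrict to the native range, compute the
four range statistics and score them against the Least Concern
thresholds. The CLI is a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .backends import (
    FixtureBackbone,
    FixtureOccurrenceBackend,
    FixtureRangeProvider,
)
from .classify import LCThresholds, ResultsRow, evaluate
from .errors import ConfigurationError
from .metrics import DEFAULT_CELL_KM, compute_metrics
from .occurrences import OCC_LIMIT_DEFAULT, OccurrenceSet, fetch_occurrences
from .regions import GeometryStore, filter_to_native
from .sis import AssessedTaxon
from .taxa import (
    BatchScreenReport,
    MatchType,
    NameMatchResult,
    NativeRange,
    TaxonQuery,
    match_name,
    screen_batch,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Backends:
    """The three service backends plus the region geometry store."""

    backbone: object
    ranges: object
    occurrences: object
    store: GeometryStore


def load_fixture_backends(
    fixture_dir: str | Path, regions_dir: str | Path | None = None
) -> Backends:
    """Load the canned-JSON backends written by the fixture generator."""
    fixture_dir = Path(fixture_dir)
    return Backends(
        backbone=FixtureBackbone.from_json(fixture_dir / "backbone.json"),
        ranges=FixtureRangeProvider.from_json(fixture_dir / "ranges.json"),
        occurrences=FixtureOccurrenceBackend.from_json(fixture_dir / "occurrences.json"),
        store=GeometryStore.from_directory(regions_dir or fixture_dir / "regions"),
    )


def assess(
    match: NameMatchResult,
    native_range: NativeRange,
    occ_set: OccurrenceSet,
    store: GeometryStore,
    thresholds: LCThresholds | None = None,
    cell_km: float = DEFAULT_CELL_KM,
) -> AssessedTaxon:
    """Native-filter one taxon's occurrences, compute metrics and score."""
    filtered = filter_to_native(occ_set, native_range, store)
    metrics = compute_metrics(filtered, cell_km=cell_km)
    gauge = evaluate(metrics, thresholds)
    return AssessedTaxon(
        match=match,
        native_range=native_range,
        metrics=metrics,
        gauge=gauge,
        occurrences=filtered,
    )


def _row(name: str, powo_id: str, taxon: AssessedTaxon | None, warning: str = "") -> ResultsRow:
    if taxon is None:
        return ResultsRow(
            full_name=name, powo_id=powo_id, eoo_km2=0.0, aoo_km2=0.0,
            record_count=0, tdwg_count=0, least_concern=False, warning=warning,
        )
    m = taxon.metrics
    return ResultsRow(
        full_name=name, powo_id=powo_id, eoo_km2=m.eoo_km2, aoo_km2=m.aoo_km2,
        record_count=m.record_count, tdwg_count=m.tdwg_count,
        least_concern=taxon.gauge.least_concern, warning=taxon.gauge.warning,
    )


@dataclass
class BatchResult:
    """Everything a batch run produces before any file is written."""

    report: BatchScreenReport
    rows: list[ResultsRow]
    lc_taxa: list[AssessedTaxon]


def run_batch(
    queries: list[TaxonQuery],
    backends: Backends,
    thresholds: LCThresholds | None = None,
    occ_limit: int = OCC_LIMIT_DEFAULT,
    cell_km: float = DEFAULT_CELL_KM,
    user_points: dict[str, OccurrenceSet] | None = None,
) -> BatchResult:
    """Screen a batch of names end to end.

    The results table carries one row per input name: assessed taxa get
    their metrics, while synonyms and unmatched names get zero metrics
    and an explanatory warning. When ``user_points`` is given the
    occurrence backend is bypassed and points are taken from the mapping
    keyed by the input name.
    """
    report = screen_batch(queries, backends.backbone, backends.ranges)
    rows: list[ResultsRow] = []
    lc_taxa: list[AssessedTaxon] = []
    assessed: dict[str, ResultsRow] = {}
    for raw_name, match, nrange in report.accepted:
        if user_points is not None:
            occ = user_points.get(raw_name)
            if occ is None:
                assessed[raw_name] = _row(
                    raw_name, nrange.powo_id, None,
                    warning="no user-supplied occurrence points for this name",
                )
                continue
        else:
            occ = fetch_occurrences(
                match.usage_key, backends.occurrences, occ_limit,
                taxon_ref=match.canonical_name,
            )
        taxon = assess(match, nrange, occ, backends.store, thresholds, cell_km)
        assessed[raw_name] = _row(match.canonical_name, nrange.powo_id, taxon)
        if taxon.gauge.least_concern:
            lc_taxa.append(taxon)
        logger.info("assessed %s: LC=%s", match.canonical_name, taxon.gauge.least_concern)

    # one row per input name, in input order
    for query in queries:
        name = query.raw_name
        if name in assessed:
            rows.append(assessed[name])
        elif name in report.synonym_accepted_names:
            rows.append(
                _row(name, "", None,
                     warning="synonym of "
                     f"{report.synonym_accepted_names[name]}; excluded from analysis")
            )
        else:
            rows.append(_row(name, "", None, warning="name not matched to the checklist"))
    return BatchResult(report=report, rows=rows, lc_taxa=lc_taxa)


@dataclass
class SingleResult:
    """Outcome of a single-species run."""

    candidates: list[NameMatchResult]
    taxon: AssessedTaxon | None
    row: ResultsRow | None
    note: str = ""


def run_single(
    name: str,
    backends: Backends,
    thresholds: LCThresholds | None = None,
    occ_limit: int = OCC_LIMIT_DEFAULT,
    cell_km: float = DEFAULT_CELL_KM,
    strict_synonyms: bool = False,
) -> SingleResult:
    """Assess one species by name.

    The best backbone match is used. When it is a synonym the accepted
    name is followed by default (``strict_synonyms=True`` refuses
    instead, mirroring the batch behaviour).
    """
    query = TaxonQuery.from_raw(name)
    if not query.is_binomial:
        raise ConfigurationError(f"{name!r} is not a binomial")
    candidates = match_name(query, backends.backbone)
    usable = [c for c in candidates if c.match_type is not MatchType.HIGHERRANK]
    if not usable:
        return SingleResult(candidates, None, None, note="no name match")
    best = usable[0]
    if best.is_synonym:
        if strict_synonyms:
            return SingleResult(
                candidates, None, None,
                note=f"synonym of {best.accepted_name}; refusing (strict mode)",
            )
        accepted = match_name(TaxonQuery.from_raw(best.accepted_name), backends.backbone)
        accepted = [c for c in accepted if not c.is_synonym
                    and c.match_type is not MatchType.HIGHERRANK]
        if not accepted:
            return SingleResult(
                candidates, None, None,
                note=f"synonym of {best.accepted_name}, which has no backbone record",
            )
        best = accepted[0]
    nrange = backends.ranges.native_range(best.accepted_name or best.canonical_name)
    if nrange is None:
        return SingleResult(candidates, None, None, note="no checklist record")
    occ = fetch_occurrences(
        best.usage_key, backends.occurrences, occ_limit, taxon_ref=best.canonical_name
    )
    taxon = assess(best, nrange, occ, backends.store, thresholds, cell_km)
    return SingleResult(
        candidates, taxon, _row(best.canonical_name, nrange.powo_id, taxon)
    )
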