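"""Occurrence-record retrieval and cleaning.

Records come either from a pluggable occurrence backend (queried by the
backbone usage key, emulating an aggregator's occurrence API) or from a
user-supplied CSV of pre-cleaned points. Either way the same cleaning
pass applies before any spatial work: drop records without parseable
coordinates, drop coordinates outside the valid lon/lat domain, drop the
(0, 0) "null island" artefact, and collapse exact duplicate coordinate
pairs to a single record (range statistics are defined on unique
georeferenced records).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, SchemaError

#: Occurrence-download cap: permitted range and default.
OCC_LIMIT_MIN = 1000
OCC_LIMIT_MAX = 10000
OCC_LIMIT_DEFAULT = 3000


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single georeferenced occurrence."""

    longitude: float
    latitude: float
    source_id: str = ""
    has_geospatial_issue: bool = False


@dataclass(frozen=True)
class OccurrenceSet:
    """Cleaned records for one taxon, with retrieval provenance.

    ``truncated`` is set when the backend held more usable records than
    the requested limit; ``dropped_count`` counts rows removed during
    cleaning (unparseable, out of bounds, null island).
    """

    taxon_ref: str
    records: tuple[OccurrenceRecord, ...]
    requested_limit: int
    truncated: bool = False
    dropped_count: int = 0

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) > self.requested_limit:
            raise ValueError("more records retained than the requested limit")

    def __len__(self) -> int:
        return len(self.records)

    def coordinates(self) -> list[tuple[float, float]]:
        return [(r.longitude, r.latitude) for r in self.records]


def _is_clean(rec: OccurrenceRecord) -> bool:
    lon, lat = rec.longitude, rec.latitude
    if not (math.isfinite(lon) and math.isfinite(lat)):
        return False
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        return False
    if lon == 0.0 and lat == 0.0:  # aggregator null-island artefact
        return False
    if rec.has_geospatial_issue:
        return False
    return True


def clean_records(occ_set: OccurrenceSet) -> OccurrenceSet:
    """Drop unusable records and collapse duplicate coordinate pairs.

    Order of first appearance is preserved; the operation is idempotent
    and its output records are always a subset of the input records.
    """
    seen: set[tuple[float, float]] = set()
    kept: list[OccurrenceRecord] = []
    dropped = 0
    for rec in occ_set.records:
        if not _is_clean(rec):
            dropped += 1
            continue
        key = (rec.longitude, rec.latitude)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return replace(
        occ_set, records=tuple(kept), dropped_count=occ_set.dropped_count + dropped
    )


def fetch_occurrences(
    usage_key, backend, limit: int = OCC_LIMIT_DEFAULT, taxon_ref: str | None = None
) -> OccurrenceSet:
    """Retrieve up to ``limit`` clean records for a backbone usage key.

    Only georeferenced, issue-free records are retained, in the backend's
    stable order, truncated at the limit (no random subsample, so reruns
    are reproducible). The limit must lie in [1000, 10000].
    """
    if not OCC_LIMIT_MIN <= limit <= OCC_LIMIT_MAX:
        raise ConfigurationError(
            f"occurrence limit {limit} outside permitted range "
            f"[{OCC_LIMIT_MIN}, {OCC_LIMIT_MAX}]"
        )
    raw, total_available = backend.fetch(usage_key, limit)
    records = []
    for i, rec in enumerate(raw):
        lon = rec.get("decimalLongitude")
        lat = rec.get("decimalLatitude")
        if lon is None or lat is None:
            continue
        try:
            lon, lat = float(lon), float(lat)
        except (TypeError, ValueError):
            continue
        records.append(
            OccurrenceRecord(
                longitude=lon,
                latitude=lat,
                source_id=str(rec.get("gbifID", i)),
                has_geospatial_issue=bool(rec.get("hasGeospatialIssue", False)),
            )
        )
    out = OccurrenceSet(
        taxon_ref=str(taxon_ref if taxon_ref is not None else usage_key),
        records=tuple(records),
        requested_limit=limit,
        truncated=total_available > limit,
    )
    return clean_records(out)


def load_user_occurrences(
    path: str | Path,
    name_col: str = "name",
    lat_col: str = "decimalLatitude",
    lon_col: str = "decimalLongitude",
) -> dict[str, OccurrenceSet]:
    """Read user-supplied points, grouped and cleaned per name.

    The CSV must carry name / decimal latitude / decimal longitude
    columns (header names configurable). Rows whose coordinates do not
    parse are dropped and counted per name; the backend fetch is bypassed
    entirely for these sets.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in (name_col, lat_col, lon_col) if c not in df.columns]
    if missing:
        raise SchemaError(missing)

    lat = pd.to_numeric(df[lat_col], errors="coerce")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    out: dict[str, OccurrenceSet] = {}
    for name, idx in df.groupby(name_col, sort=False).groups.items():
        records = []
        dropped = 0
        for row_i, i in enumerate(idx):
            if pd.isna(lat[i]) or pd.isna(lon[i]):
                dropped += 1
                continue
            records.append(
                OccurrenceRecord(
                    longitude=float(lon[i]), latitude=float(lat[i]),
                    source_id=f"user-{row_i}",
                )
            )
        raw = OccurrenceSet(
            taxon_ref=str(name),
            records=tuple(records),
            requested_limit=max(1, len(idx)),
            truncated=False,
            dropped_count=dropped,
        )
        out[str(name)] = clean_records(raw)
    return out
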