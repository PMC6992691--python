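"""Pluggable service backends: name backbone, range provider, occurrences.

The pipeline never talks to a remote service directly; every lookup goes
through one of three narrow interfaces so that offline fixture backends
(canned JSON documents mimicking the live services' response shapes) and
thin live HTTP clients are interchangeable. Fixture backends are the
default everywhere and are what the test suite runs against.

Fixture document shapes
-----------------------
``backbone.json``::

    {"entries": [{"canonicalName": "Aloe zebrina", "authorship": "Baker",
                  "family": "Asphodelaceae", "usageKey": 2777724,
                  "status": "ACCEPTED", "acceptedName": null,
                  "rank": "SPECIES"}, ...]}

``ranges.json`` (keyed by accepted canonical name)::

    {"taxa": {"Aloe zebrina": {"powo_id": "530536-1",
                               "native": ["ANG", "ZAM"],
                               "introduced": []}}}

``occurrences.json`` (keyed by stringified usage key)::

    {"2777724": {"records": [{"decimalLongitude": 20.1,
                              "decimalLatitude": -14.2,
                              "gbifID": "r1",
                              "hasGeospatialIssue": false}, ...]}}
"""

from __future__ import annotations

import difflib
import json
from pathlib import Path
from typing import Protocol, runtime_checkable

from .errors import BackendUnavailableError
from .taxa import MatchType, NameMatchResult, NativeRange

#: Similarity ratio below which a candidate is not offered as a fuzzy match.
FUZZY_CUTOFF = 0.75


@runtime_checkable
class NameBackbone(Protocol):
    """A taxonomic name backbone supporting fuzzy search."""

    def search(self, normalized_name: str) -> list[NameMatchResult]:
        """Return scored candidate matches (unordered)."""
        ...


@runtime_checkable
class RangeProvider(Protocol):
    """A checklist service reporting native/introduced WGSRPD L3 codes."""

    def native_range(self, canonical_name: str) -> NativeRange | None:
        """Return the range for an accepted name, or None when unknown."""
        ...


@runtime_checkable
class OccurrenceBackend(Protocol):
    """An occurrence aggregator queried by backbone usage key."""

    def fetch(self, usage_key, limit: int) -> tuple[list[dict], int]:
        """Return (records, total_available).

        ``records`` are raw record dicts in the backend's stable order,
        at most ``limit`` of them; ``total_available`` is the number the
        backend holds for the key (used to set the truncation flag).
        """
        ...


def _score_candidate(query: str, entry: dict) -> NameMatchResult | None:
    """Score one backbone entry against a normalized query.

    Exact (case-insensitive) equality scores 100/EXACT; otherwise a
    similarity ratio >= FUZZY_CUTOFF yields FUZZY with confidence
    strictly below 100; a genus-rank entry equal to the query's genus
    yields a low-confidence HIGHERRANK fallback.
    """
    canonical = entry["canonicalName"]
    rank = entry.get("rank", "SPECIES")
    is_syn = entry.get("status", "ACCEPTED").upper() == "SYNONYM"
    accepted = entry.get("acceptedName") or (None if is_syn else canonical)
    base = dict(
        canonical_name=canonical,
        authorship=entry.get("authorship", ""),
        family=entry.get("family", ""),
        usage_key=entry.get("usageKey"),
        is_synonym=is_syn,
        accepted_name=accepted,
    )
    q = query.lower()
    c = canonical.lower()
    if rank == "GENUS":
        if q.split(" ")[0] == c:
            return NameMatchResult(
                confidence=50.0, match_type=MatchType.HIGHERRANK, **base
            )
        return None
    if q == c:
        return NameMatchResult(confidence=100.0, match_type=MatchType.EXACT, **base)
    ratio = difflib.SequenceMatcher(None, q, c).ratio()
    if ratio >= FUZZY_CUTOFF:
        return NameMatchResult(
            confidence=round(99.0 * ratio, 1), match_type=MatchType.FUZZY, **base
        )
    return None


class FixtureBackbone:
    """Name backbone backed by a canned entry list (see module docstring)."""

    def __init__(self, entries: list[dict]):
        self.entries = list(entries)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureBackbone":
        try:
            doc = json.loads(Path(path).read_text(encoding="utf-8"))
        except OSError as exc:  # missing/unreadable fixture = unreachable service
            raise BackendUnavailableError(f"cannot read backbone fixture: {exc}") from exc
        return cls(doc["entries"])

    def search(self, normalized_name: str) -> list[NameMatchResult]:
        out = []
        for entry in self.entries:
            cand = _score_candidate(normalized_name, entry)
            if cand is not None:
                out.append(cand)
        return out


class FixtureRangeProvider:
    """Range provider backed by a canned name → code-sets mapping."""

    def __init__(self, taxa: dict[str, dict]):
        self.taxa = dict(taxa)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureRangeProvider":
        try:
            doc = json.loads(Path(path).read_text(encoding="utf-8"))
        except OSError as exc:
            raise BackendUnavailableError(f"cannot read range fixture: {exc}") from exc
        return cls(doc["taxa"])

    def native_range(self, canonical_name: str) -> NativeRange | None:
        rec = self.taxa.get(canonical_name)
        if rec is None:
            return None
        return NativeRange(
            powo_id=str(rec.get("powo_id", "")),
            native_codes=frozenset(rec.get("native", [])),
            introduced_codes=frozenset(rec.get("introduced", [])),
        )


class FixtureOccurrenceBackend:
    """Occurrence backend backed by canned per-key record lists."""

    def __init__(self, records_by_key: dict[str, dict]):
        self.records_by_key = dict(records_by_key)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureOccurrenceBackend":
        try:
            doc = json.loads(Path(path).read_text(encoding="utf-8"))
        except OSError as exc:
            raise BackendUnavailableError(f"cannot read occurrence fixture: {exc}") from exc
        return cls(doc)

    def fetch(self, usage_key, limit: int) -> tuple[list[dict], int]:
        rec = self.records_by_key.get(str(usage_key), {"records": []})
        records = rec["records"]
        return records[:limit], len(records)
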