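"""Thin optional live HTTP clients for the name, range and occurrence services.

These talk to the public GBIF species/occurrence APIs and the POWO API
with stdlib ``urllib`` and satisfy the same backend protocols as the
fixture backends. They are a convenience for online use only: the whole
pipeline (and its test suite) runs on fixture backends, results depend on
the remote databases' current content, and the POWO API in particular is
unversioned. Transport failures raise
:class:`~lcscreen.errors.BackendUnavailableError` so callers can retry.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request

from .errors import BackendUnavailableError
from .taxa import MatchType, NameMatchResult, NativeRange

GBIF_API = "https://api.gbif.org/v1"
POWO_API = "https://powo.science.kew.org/api/2"
_TIMEOUT = 30.0


def _get_json(url: str) -> dict:
    try:
        with urllib.request.urlopen(url, timeout=_TIMEOUT) as resp:
            return json.loads(resp.read().decode("utf-8"))
    except (urllib.error.URLError, TimeoutError, json.JSONDecodeError) as exc:
        raise BackendUnavailableError(f"request failed: {url}: {exc}") from exc


def _from_gbif(doc: dict) -> NameMatchResult | None:
    mt = doc.get("matchType", "NONE")
    if mt == "NONE":
        return None
    if mt not in MatchType.__members__:
        mt = "FUZZY"
    is_syn = doc.get("status", "").upper() == "SYNONYM" or doc.get("synonym", False)
    return NameMatchResult(
        canonical_name=doc.get("canonicalName") or doc.get("scientificName", ""),
        authorship=doc.get("authorship", ""),
        family=doc.get("family", ""),
        usage_key=doc.get("usageKey"),
        confidence=float(doc.get("confidence", 0)),
        match_type=MatchType[mt],
        is_synonym=is_syn,
        accepted_name=doc.get("species") if is_syn else doc.get("canonicalName"),
    )


class LiveNameBackbone:
    """GBIF species-match client (verbose mode returns the alternatives)."""

    def search(self, normalized_name: str) -> list[NameMatchResult]:
        q = urllib.parse.urlencode({"name": normalized_name, "verbose": "true"})
        doc = _get_json(f"{GBIF_API}/species/match?{q}")
        out = []
        for cand in [doc] + doc.get("alternatives", []):
            res = _from_gbif(cand)
            if res is not None:
                out.append(res)
        return out


class LiveRangeProvider:
    """POWO lookup: search for the accepted name, then read its distribution."""

    def native_range(self, canonical_name: str) -> NativeRange | None:
        q = urllib.parse.urlencode({"q": canonical_name, "f": "accepted_names"})
        doc = _get_json(f"{POWO_API}/search?{q}")
        results = doc.get("results") or []
        hits = [r for r in results if r.get("name") == canonical_name]
        if not hits:
            return None
        fq_id = hits[0]["fqId"]
        taxon = _get_json(f"{POWO_API}/taxon/{urllib.parse.quote(fq_id)}?fields=distribution")
        dist = taxon.get("distribution", {})

        def codes(key: str) -> frozenset[str]:
            return frozenset(
                d["tdwgCode"][:3] for d in dist.get(key, []) if d.get("tdwgLevel") == 3
            )

        return NativeRange(
            powo_id=fq_id,
            native_codes=codes("natives"),
            introduced_codes=codes("introduced") - codes("natives"),
        )


class LiveOccurrenceBackend:
    """GBIF occurrence-search client, paginated up to the requested limit."""

    page_size = 300

    def fetch(self, usage_key, limit: int) -> tuple[list[dict], int]:
        records: list[dict] = []
        total = 0
        offset = 0
        while len(records) < limit:
            q = urllib.parse.urlencode(
                {
                    "taxonKey": usage_key,
                    "hasCoordinate": "true",
                    "hasGeospatialIssue": "false",
                    "limit": min(self.page_size, limit - len(records)),
                    "offset": offset,
                }
            )
            doc = _get_json(f"{GBIF_API}/occurrence/search?{q}")
            total = int(doc.get("count", 0))
            page = doc.get("results", [])
            if not page:
                break
            records.extend(page)
            offset += len(page)
            if doc.get("endOfRecords", True):
                break
        return records[:limit], total
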