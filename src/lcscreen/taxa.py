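"""Name resolution and native-range lookup.

A user-entered binomial is matched against a pluggable name backbone
(exact, fuzzy or higher-rank fallback), and a matched accepted name is
used to retrieve the taxon's native and introduced WGSRPD Level-3 range
codes from a pluggable checklist provider. The batch screen applies both
steps to a list of names and partitions it into accepted / synonym /
unmatched, since only accepted names with a known native range can be
assessed downstream.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import BatchLimitError, ConfigurationError, SchemaError

#: Default cap on batch size (large batches degrade the downstream
#: assessment database, so they are refused outright).
BATCH_LIMIT = 100

_INFRASPECIFIC_MARKERS = {"var.", "var", "subsp.", "subsp", "ssp.", "ssp", "f.", "forma"}

_L3_CODE_RE = re.compile(r"^[A-Z]{3}$")


class MatchType(enum.Enum):
    """How a candidate name was matched, best first."""

    EXACT = "EXACT"
    FUZZY = "FUZZY"
    HIGHERRANK = "HIGHERRANK"
    NONE = "NONE"

    @property
    def rank(self) -> int:
        return {"EXACT": 0, "FUZZY": 1, "HIGHERRANK": 2, "NONE": 3}[self.value]


@dataclass(frozen=True)
class TaxonQuery:
    """A user-entered name, normalized for backbone search.

    Normalization collapses whitespace, capitalizes the genus and
    lower-cases the epithet. Infraspecific rank markers (var., subsp., f.)
    and anything after them are stripped and flagged; only clean binomials
    are considered well-formed input.
    """

    raw_name: str
    normalized_name: str
    is_binomial: bool
    had_infraspecific: bool = False

    @classmethod
    def from_raw(cls, raw: str) -> "TaxonQuery":
        tokens = raw.strip().split()
        had_infra = False
        kept: list[str] = []
        for tok in tokens:
            if tok.lower() in _INFRASPECIFIC_MARKERS:
                had_infra = True
                break
            kept.append(tok)
        if len(kept) > 2:
            # trailing tokens beyond the epithet (authorship, infraspecific
            # epithet without marker) are dropped from the search string
            kept = kept[:2]
        if not kept:
            return cls(raw_name=raw, normalized_name="", is_binomial=False,
                       had_infraspecific=had_infra)
        genus = kept[0].capitalize()
        if len(kept) == 1:
            return cls(raw_name=raw, normalized_name=genus, is_binomial=False,
                       had_infraspecific=had_infra)
        epithet = kept[1].lower()
        return cls(raw_name=raw, normalized_name=f"{genus} {epithet}",
                   is_binomial=True, had_infraspecific=had_infra)


@dataclass(frozen=True)
class NameMatchResult:
    """One candidate resolution of a binomial against the backbone."""

    canonical_name: str
    authorship: str
    family: str
    usage_key: object
    confidence: float
    match_type: MatchType
    is_synonym: bool
    accepted_name: str | None

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 100.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 100]")
        if self.match_type is MatchType.NONE and self.usage_key is not None:
            raise ValueError("match_type NONE must not carry a usage key")
        if self.is_synonym and not self.accepted_name:
            raise ValueError("synonym matches must carry the accepted name")


@dataclass(frozen=True)
class NativeRange:
    """Native and introduced WGSRPD Level-3 code sets for one taxon."""

    powo_id: str
    native_codes: frozenset[str]
    introduced_codes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "native_codes", frozenset(self.native_codes))
        object.__setattr__(self, "introduced_codes", frozenset(self.introduced_codes))
        overlap = self.native_codes & self.introduced_codes
        if overlap:
            raise ValueError(f"codes both native and introduced: {sorted(overlap)}")
        for code in self.native_codes | self.introduced_codes:
            if not _L3_CODE_RE.match(code):
                raise ValueError(f"not an uppercase 3-letter WGSRPD L3 code: {code!r}")


@dataclass
class BatchScreenReport:
    """Partition of a batch name list after the checklist pre-screen."""

    accepted: list[tuple[str, NameMatchResult, NativeRange]] = field(default_factory=list)
    excluded_synonyms: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    #: input name -> accepted name, surfaced so the user can resubmit
    synonym_accepted_names: dict[str, str] = field(default_factory=dict)


def match_name(query: TaxonQuery, backbone) -> list[NameMatchResult]:
    """Search the backbone and return candidates, best match first.

    Candidates are ordered by confidence descending, ties broken by match
    type (EXACT > FUZZY > HIGHERRANK) then lexicographically by canonical
    name, so fixture runs are fully deterministic. An empty list means the
    backbone offered no candidate at all.
    """
    if not query.normalized_name:
        raise ConfigurationError("empty name: nothing to match")
    candidates = backbone.search(query.normalized_name)
    return sorted(
        candidates,
        key=lambda r: (-r.confidence, r.match_type.rank, r.canonical_name),
    )


def lookup_native_range(match: NameMatchResult, provider) -> NativeRange | None:
    """Fetch native/introduced L3 codes for a matched name.

    Absence from the provider is an ordinary outcome (None), not an error;
    only transport failures raise.
    """
    if match.match_type is MatchType.NONE:
        raise ConfigurationError("cannot look up a range for an unmatched name")
    name = match.accepted_name or match.canonical_name
    return provider.native_range(name)


def screen_batch(
    names: list[TaxonQuery], backbone, provider, batch_limit: int = BATCH_LIMIT
) -> BatchScreenReport:
    """Pre-screen a batch of names against the backbone and checklist.

    Names whose best match is a synonym are excluded (assessing the
    accepted taxon instead would silently change the subject of the
    assessment); names with no backbone match or no checklist record are
    unmatched. The three output lists partition the input.
    """
    if not names:
        raise ConfigurationError("empty batch: no names to screen")
    if len(names) > batch_limit:
        raise BatchLimitError(len(names), batch_limit)
    report = BatchScreenReport()
    for query in names:
        if not query.is_binomial:
            report.unmatched.append(query.raw_name)
            continue
        results = match_name(query, backbone)
        if not results or results[0].match_type is MatchType.HIGHERRANK:
            report.unmatched.append(query.raw_name)
            continue
        best = results[0]
        if best.is_synonym:
            report.excluded_synonyms.append(query.raw_name)
            report.synonym_accepted_names[query.raw_name] = best.accepted_name
            continue
        nrange = lookup_native_range(best, provider)
        if nrange is None:
            report.unmatched.append(query.raw_name)
            continue
        report.accepted.append((query.raw_name, best, nrange))
    return report


def load_batch_names(path: str | Path, column: str | None = None) -> list[TaxonQuery]:
    """Read a headered one-column CSV of binomials into queries."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] == 0:
        raise SchemaError(["name"])
    col = column if column is not None else df.columns[0]
    if col not in df.columns:
        raise SchemaError([col])
    return [TaxonQuery.from_raw(str(v)) for v in df[col].dropna()]
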