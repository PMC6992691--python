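"""WGSRPD Level-3 region geometries and native-range point filtering.

Aggregated occurrence data do not distinguish native from introduced
occurrences, so range metrics computed on raw points can be badly
overestimated. The filter here keeps only points lying inside (or on the
boundary of) the polygons of the taxon's native Level-3 "botanical
country" units, as reported by the checklist provider.

Point-in-polygon runs unprojected on lon/lat degrees, treating degrees as
planar — Level-3 units are large, and the store contract requires
polygons crossing the antimeridian to be pre-split into two lobes so all
coordinates live in [-180, 180]. Boundary points count as inside: the
precautionary choice, since excluding them could only shrink the range
metrics and push a genuinely widespread species towards a false
threatened call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .errors import MissingGeometryError
from .occurrences import OccurrenceSet
from .taxa import NativeRange

logger = logging.getLogger(__name__)

#: GeoJSON feature property carrying the Level-3 code.
L3_PROPERTY = "LEVEL3_COD"


@dataclass(frozen=True)
class RegionGeometry:
    """One Level-3 unit: code plus its (multi)polygon in lon/lat degrees."""

    l3_code: str
    geometry: shapely.Geometry


class GeometryStore:
    """Lookup of Level-3 codes to region polygons.

    Built either from a directory of GeoJSON FeatureCollections (one
    feature per Level-3 code, code in the ``LEVEL3_COD`` property) or
    directly from in-memory geometries.
    """

    def __init__(self, regions: dict[str, RegionGeometry]):
        self._regions = dict(regions)

    @classmethod
    def from_directory(cls, path: str | Path) -> "GeometryStore":
        regions: dict[str, RegionGeometry] = {}
        files = sorted(Path(path).glob("*.geojson"))
        for f in files:
            doc = json.loads(f.read_text(encoding="utf-8"))
            features = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
            for feat in features:
                code = feat["properties"][L3_PROPERTY]
                if code in regions:
                    raise ValueError(f"duplicate geometry for L3 code {code}")
                regions[code] = RegionGeometry(code, shape(feat["geometry"]))
        return cls(regions)

    @classmethod
    def from_geometries(cls, geoms: dict[str, shapely.Geometry]) -> "GeometryStore":
        return cls({c: RegionGeometry(c, g) for c, g in geoms.items()})

    def codes(self) -> set[str]:
        return set(self._regions)

    def get(self, code: str) -> RegionGeometry:
        return self._regions[code]

    def __contains__(self, code: str) -> bool:
        return code in self._regions

    def write_directory(self, path: str | Path) -> Path:
        """Serialize the store as one FeatureCollection GeoJSON file."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        features = [
            {
                "type": "Feature",
                "properties": {L3_PROPERTY: code},
                "geometry": mapping(reg.geometry),
            }
            for code, reg in sorted(self._regions.items())
        ]
        out = path / "regions.geojson"
        out.write_text(
            json.dumps({"type": "FeatureCollection", "features": features}),
            encoding="utf-8",
        )
        return out


@dataclass(frozen=True)
class FilteredOccurrences:
    """Occurrences restricted to the native range.

    ``regions_hit`` holds the native Level-3 codes containing at least
    one retained point; retained count plus removed count equals the
    input count.
    """

    retained: OccurrenceSet
    removed_count: int
    regions_hit: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "regions_hit", frozenset(self.regions_hit))


def filter_to_native(
    occ_set: OccurrenceSet, native_range: NativeRange, store: GeometryStore
) -> FilteredOccurrences:
    """Keep points inside (or on the boundary of) native-region polygons.

    Every native code must resolve in the geometry store; codes with no
    geometry raise, naming them. An empty native code set removes every
    point (the downstream metrics then carry a warning).
    """
    codes = sorted(native_range.native_codes)
    missing = [c for c in codes if c not in store]
    if missing:
        raise MissingGeometryError(missing)
    n = len(occ_set.records)
    if not codes:
        logger.warning(
            "taxon %s has an empty native range: all %d points removed",
            occ_set.taxon_ref, n,
        )
        return FilteredOccurrences(
            retained=replace(occ_set, records=()), removed_count=n,
            regions_hit=frozenset(),
        )
    if n == 0:
        return FilteredOccurrences(
            retained=occ_set, removed_count=0, regions_hit=frozenset()
        )

    pts = shapely.points(
        np.array([r.longitude for r in occ_set.records]),
        np.array([r.latitude for r in occ_set.records]),
    )
    keep = np.zeros(n, dtype=bool)
    hit: set[str] = set()
    for code in codes:
        # covers() includes the boundary, unlike contains()
        inside = shapely.covers(store.get(code).geometry, pts)
        if inside.any():
            hit.add(code)
        keep |= inside
    retained = tuple(r for r, k in zip(occ_set.records, keep) if k)
    return FilteredOccurrences(
        retained=replace(occ_set, records=retained),
        removed_count=int(n - keep.sum()),
        regions_hit=frozenset(hit),
    )
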