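"""Synthetic test-world generators.

Everything the pipeline consumes from remote services can be generated
here deterministically: clustered occurrence point clouds, toy
rectangular Level-3 region grids, canned backend documents (name
backbone, range provider, occurrence service) and validation tables with
planted class structure for threshold calibration. All generators are
fully deterministic under their seed, and the fixture writers emit the
same CSV/GeoJSON/JSON dialects the ingest modules read, so every module
is exercisable offline.

The generated world is a stylisation, not a simulation of real
collection data: point clouds are isotropic Gaussians (no roads-and-
rivers sampling bias, no duplicated specimens), region tiles are
rectangles, and validation metrics are independent lognormals per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .metrics import RangeMetrics
from .occurrences import OccurrenceRecord, OccurrenceSet
from .projection import ProjectionContext
from .regions import GeometryStore
from .sensitivity import ValidationRecord


@dataclass(frozen=True)
class CloudSpec:
    """An isotropic Gaussian occurrence cloud.

    Dispersion is the per-axis standard deviation in projected km (not
    degrees), so the cloud's expected footprint — and hence its expected
    AOO/EOO — does not depend on latitude.
    """

    lon: float
    lat: float
    dispersion_km: float
    n: int
    seed: int

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.dispersion_km < 0:
            raise ValueError("dispersion must be non-negative")


def gen_cloud(spec: CloudSpec, taxon_ref: str = "synthetic") -> OccurrenceSet:
    """Sample a deterministic Gaussian point cloud around a centroid."""
    rng = np.random.default_rng(spec.seed)
    ctx = ProjectionContext(spec.lon, spec.lat)
    cx, cy = ctx.forward(spec.lon, spec.lat)
    offsets = rng.normal(0.0, spec.dispersion_km, size=(spec.n, 2))
    lons, lats = ctx.inverse(cx + offsets[:, 0], cy + offsets[:, 1])
    records = tuple(
        OccurrenceRecord(longitude=float(lo), latitude=float(la), source_id=f"syn-{i}")
        for i, (lo, la) in enumerate(zip(np.atleast_1d(lons), np.atleast_1d(lats)))
    )
    return OccurrenceSet(
        taxon_ref=taxon_ref,
        records=records,
        requested_limit=max(1, spec.n),
        truncated=False,
    )


@dataclass(frozen=True)
class ToyRegionGrid:
    """Non-overlapping lon/lat rectangles standing in for Level-3 units."""

    #: (code, (lon_min, lat_min, lon_max, lat_max)) per region
    regions: tuple[tuple[str, tuple[float, float, float, float]], ...]

    def __post_init__(self):
        codes = [c for c, _ in self.regions]
        if len(codes) != len(set(codes)):
            raise ValueError("region codes must be unique")
        rects = [box(*bounds) for _, bounds in self.regions]
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                inter = rects[i].intersection(rects[j])
                if inter.area > 0:
                    raise ValueError(
                        f"regions {codes[i]} and {codes[j]} overlap"
                    )

    @classmethod
    def regular(
        cls,
        codes: list[str],
        n_cols: int,
        origin: tuple[float, float] = (0.0, 0.0),
        size_deg: float = 10.0,
    ) -> "ToyRegionGrid":
        """Lay codes out row-major on a regular tile grid."""
        lon0, lat0 = origin
        regions = []
        for k, code in enumerate(codes):
            r, c = divmod(k, n_cols)
            regions.append(
                (
                    code,
                    (
                        lon0 + c * size_deg,
                        lat0 + r * size_deg,
                        lon0 + (c + 1) * size_deg,
                        lat0 + (r + 1) * size_deg,
                    ),
                )
            )
        return cls(tuple(regions))

    def to_store(self) -> GeometryStore:
        return GeometryStore.from_geometries(
            {code: box(*bounds) for code, bounds in self.regions}
        )

    def centroid(self, code: str) -> tuple[float, float]:
        for c, (x0, y0, x1, y1) in self.regions:
            if c == code:
                return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
        raise KeyError(code)


# Per-class lognormal medians of the four metrics: the study conditions
# for calibration experiments. LC species are widespread (well above the
# default thresholds on median); threatened species are narrow.
LC_MEDIANS = {"eoo": 5e5, "aoo": 2e4, "records": 500.0, "tdwg": 12.0}
THREATENED_MEDIANS = {"eoo": 8e3, "aoo": 600.0, "records": 20.0, "tdwg": 2.0}

#: Deterministic metrics for a planted wide-ranging threatened outlier —
#: a species whose range statistics exceed any plausible threshold but
#: whose published category is Vulnerable (range-wide decline), so it is
#: a false positive in every threshold scenario.
OUTLIER_METRICS = RangeMetrics(
    eoo_km2=1e7, aoo_km2=1e6, record_count=100000, tdwg_count=50
)

_THREATENED_CYCLE = ("VU", "EN", "CR", "NT")


def gen_validation_table(
    n_lc: int,
    n_threatened: int,
    seed: int,
    lc_medians: dict[str, float] = LC_MEDIANS,
    threatened_medians: dict[str, float] = THREATENED_MEDIANS,
    sigma_log: float = 1.0,
    n_outliers: int = 0,
) -> list[ValidationRecord]:
    """Synthetic species with known categories and planted class structure.

    Metrics are drawn per class as independent lognormals around the
    class medians (``sigma_log`` is the log-space spread; the effect size
    of each metric is the log-ratio of its class medians). Count metrics
    are rounded and floored at 1, and AOO is clamped to its feasible band
    [cell area, records x cell area]. ``n_outliers`` appends planted
    wide-ranging threatened species (category VU, metrics above any
    plausible grid).
    """
    if n_lc < 0 or n_threatened < 0 or n_outliers < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[ValidationRecord] = []

    def draw(medians: dict[str, float]) -> RangeMetrics:
        vals = {
            k: float(m * np.exp(rng.normal(0.0, sigma_log)))
            for k, m in medians.items()
        }
        n_rec = max(1, round(vals["records"]))
        aoo = float(np.clip(vals["aoo"], 100.0, 100.0 * n_rec))
        return RangeMetrics(
            eoo_km2=vals["eoo"],
            aoo_km2=aoo,
            record_count=n_rec,
            tdwg_count=max(1, round(vals["tdwg"])),
        )

    for i in range(n_lc):
        records.append(ValidationRecord(f"lc_sp_{i}", "LC", draw(lc_medians)))
    for i in range(n_threatened):
        cat = _THREATENED_CYCLE[i % len(_THREATENED_CYCLE)]
        records.append(
            ValidationRecord(f"thr_sp_{i}", cat, draw(threatened_medians))
        )
    for i in range(n_outliers):
        records.append(
            ValidationRecord(f"outlier_sp_{i}", "VU", OUTLIER_METRICS)
        )
    return records


def write_validation_csv(records: list[ValidationRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "name": r.name,
                "category": r.published_category,
                "eoo_km2": r.metrics.eoo_km2,
                "aoo_km2": r.metrics.aoo_km2,
                "record_count": r.metrics.record_count,
                "tdwg_count": r.metrics.tdwg_count,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Demo fixture suite: a small self-consistent offline world.

#: Stylised 10-degree tiles labelled with real WGSRPD L3 codes (synthetic
#: rectangles, not the real region outlines).
DEMO_TILES = ToyRegionGrid(
    (
        ("CPP", (0.0, -30.0, 10.0, -20.0)),
        ("NAM", (10.0, -30.0, 20.0, -20.0)),
        ("BOT", (20.0, -30.0, 30.0, -20.0)),
        ("ZIM", (30.0, -30.0, 40.0, -20.0)),
        ("MOZ", (40.0, -30.0, 50.0, -20.0)),
        ("ANG", (10.0, -20.0, 20.0, -10.0)),
        ("ZAM", (20.0, -20.0, 30.0, -10.0)),
        ("MLW", (30.0, -20.0, 40.0, -10.0)),
        ("TAN", (40.0, -20.0, 50.0, -10.0)),
    )
)

_DEMO_BACKBONE = [
    {"canonicalName": "Aloe zebrina", "authorship": "Baker",
     "family": "Asphodelaceae", "usageKey": 2777724, "status": "ACCEPTED"},
    {"canonicalName": "Aloe platyphylla", "authorship": "Baker",
     "family": "Asphodelaceae", "usageKey": 2777900, "status": "SYNONYM",
     "acceptedName": "Aloe zebrina"},
    {"canonicalName": "Protea cynaroides", "authorship": "(L.) L.",
     "family": "Proteaceae", "usageKey": 5637947, "status": "ACCEPTED"},
    {"canonicalName": "Aloe pillansii", "authorship": "L.Guthrie",
     "family": "Asphodelaceae", "usageKey": 2777803, "status": "ACCEPTED"},
    {"canonicalName": "Aloe", "authorship": "L.", "family": "Asphodelaceae",
     "usageKey": 2777775, "status": "ACCEPTED", "rank": "GENUS"},
]

_DEMO_RANGES = {
    "Aloe zebrina": {
        "powo_id": "530536-1",
        "native": ["ANG", "BOT", "MLW", "MOZ", "NAM", "TAN", "ZAM", "ZIM"],
        "introduced": ["CPP"],
    },
    "Protea cynaroides": {"powo_id": "703148-1", "native": ["CPP"], "introduced": []},
    "Aloe pillansii": {"powo_id": "529210-1", "native": ["NAM"], "introduced": []},
}


def _demo_occurrence_records(seed: int) -> dict[str, dict]:
    def cloud_records(code: str, n: int, dispersion: float, sub_seed: int):
        lon, lat = DEMO_TILES.centroid(code)
        cloud = gen_cloud(CloudSpec(lon, lat, dispersion, n, sub_seed))
        return [
            {"decimalLongitude": r.longitude, "decimalLatitude": r.latitude,
             "gbifID": f"{code}-{i}", "hasGeospatialIssue": False}
            for i, r in enumerate(cloud.records)
        ]

    zebrina = []
    for k, code in enumerate(_DEMO_RANGES["Aloe zebrina"]["native"]):
        zebrina += cloud_records(code, 30, 80.0, seed + k)
    # introduced-range points (filtered out downstream) and dirty records
    zebrina += cloud_records("CPP", 10, 50.0, seed + 100)
    zebrina.append({"decimalLongitude": None, "decimalLatitude": None,
                    "gbifID": "nogeo-1", "hasGeospatialIssue": False})
    zebrina.append({"decimalLongitude": 25.0, "decimalLatitude": -15.0,
                    "gbifID": "flagged-1", "hasGeospatialIssue": True})

    cynaroides = cloud_records("CPP", 120, 60.0, seed + 200)
    pillansii = cloud_records("NAM", 8, 5.0, seed + 300)
    return {
        "2777724": {"records": zebrina},
        "5637947": {"records": cynaroides},
        "2777803": {"records": pillansii},
    }


def gen_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a self-consistent offline fixture world.

    Emits the canned backbone / range / occurrence JSON documents, a
    GeoJSON region store of stylised tiles, a batch name CSV (including a
    synonym and an unresolvable name) and a synthetic validation table.
    Returns the paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["backbone"] = out_dir / "backbone.json"
    paths["backbone"].write_text(
        json.dumps({"entries": _DEMO_BACKBONE}, indent=1), encoding="utf-8"
    )
    paths["ranges"] = out_dir / "ranges.json"
    paths["ranges"].write_text(
        json.dumps({"taxa": _DEMO_RANGES}, indent=1), encoding="utf-8"
    )
    paths["occurrences"] = out_dir / "occurrences.json"
    paths["occurrences"].write_text(
        json.dumps(_demo_occurrence_records(seed)), encoding="utf-8"
    )
    paths["regions"] = DEMO_TILES.to_store().write_directory(out_dir / "regions")
    paths["names"] = out_dir / "names.csv"
    pd.DataFrame(
        {"name": ["Aloe zebrina", "Protea cynaroides", "Aloe pillansii",
                  "Aloe platyphylla", "Fakeus notrealis"]}
    ).to_csv(paths["names"], index=False)
    paths["validation"] = write_validation_csv(
        gen_validation_table(60, 40, seed=seed + 1000, n_outliers=1),
        out_dir / "validation.csv",
    )
    return paths
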