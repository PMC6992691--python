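"""Threshold calibration by confusion-matrix sensitivity sweeps.

To choose screening thresholds, species with known published Red List
categories are re-scored over a grid of candidate thresholds, one
parameter at a time (the other three parameters are ignored during that
parameter's sweep). At each grid value a species is predicted Least
Concern iff the swept metric meets or exceeds the candidate threshold;
predictions are tallied against the published truth in a 2×2 confusion
matrix:

* positive truth = published LC;
* negative truth = published NT, VU, EN or CR (the screen's purpose is
  isolating LC from everything of elevated concern, so Near Threatened
  counts as negative);
* DD, NE and the non-extant categories (EX, EW) are excluded.

The tool's aim is a low false-positive rate (never calling a threatened
species LC) at a still-useful true-positive rate, so the curves of
accuracy / TPR / FPR against threshold are the basis for a precautionary
default choice. Note a wide-ranging species threatened by range-wide
pressure (over-harvesting, disease) stays a false positive at every
threshold — no range-based threshold can remove it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import LCThresholds
from .errors import ConfigurationError, SchemaError
from .metrics import RangeMetrics

PARAMETERS = ("eoo", "aoo", "records", "tdwg")

_METRIC_ATTR = {
    "eoo": "eoo_km2",
    "aoo": "aoo_km2",
    "records": "record_count",
    "tdwg": "tdwg_count",
}

POSITIVE_CATEGORIES = frozenset({"LC"})
NEGATIVE_CATEGORIES = frozenset({"NT", "VU", "EN", "CR"})
EXCLUDED_CATEGORIES = frozenset({"DD", "NE", "EX", "EW"})

#: Default sweep grids, spanning the plausible calibration range of each
#: parameter around its default threshold.
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "eoo": np.linspace(0.0, 60000.0, 51),
    "aoo": np.linspace(0.0, 6000.0, 51),
    "records": np.linspace(0.0, 150.0, 51),
    "tdwg": np.arange(0.0, 11.0),
}

CURVE_COLUMNS = [
    "parameter", "threshold", "tp", "fp", "tn", "fn",
    "accuracy", "tpr", "fpr", "chosen",
]


@dataclass(frozen=True)
class ValidationRecord:
    """One species with a published category and computed metrics."""

    name: str
    published_category: str
    metrics: RangeMetrics


@dataclass(frozen=True)
class SweepPoint:
    """Confusion-matrix tallies at one candidate threshold."""

    parameter: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    tpr: float | None  # None when no positive-truth records
    fpr: float | None  # None when no negative-truth records


def _truth_arrays(records: list[ValidationRecord], parameter: str):
    """Metric values and binary truths for the non-excluded records."""
    attr = _METRIC_ATTR[parameter]
    values, truths = [], []
    for rec in records:
        cat = rec.published_category.upper()
        if cat in EXCLUDED_CATEGORIES:
            continue
        if cat in POSITIVE_CATEGORIES:
            truths.append(True)
        elif cat in NEGATIVE_CATEGORIES:
            truths.append(False)
        else:
            raise ConfigurationError(f"unknown Red List category {rec.published_category!r}")
        values.append(float(getattr(rec.metrics, attr)))
    return np.asarray(values), np.asarray(truths, dtype=bool)


def sweep(
    records: list[ValidationRecord], parameter: str, grid
) -> list[SweepPoint]:
    """Confusion-matrix curve for one parameter over an ascending grid.

    At each grid value the prediction is positive iff that single
    parameter's metric meets or exceeds the candidate threshold. TPR and
    FPR are undefined (None) when a truth class is empty.
    """
    if parameter not in PARAMETERS:
        raise ConfigurationError(
            f"unknown parameter {parameter!r}; expected one of {PARAMETERS}"
        )
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("threshold grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ConfigurationError("threshold grid must be ascending")
    values, truths = _truth_arrays(records, parameter)
    if values.size == 0:
        raise ConfigurationError("no usable validation records after exclusions")
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    out = []
    for t in grid:
        pred = values >= t
        tp = int(np.sum(pred & truths))
        fp = int(np.sum(pred & ~truths))
        fn = n_pos - tp
        tn = n_neg - fp
        out.append(
            SweepPoint(
                parameter=parameter,
                threshold=float(t),
                tp=tp, fp=fp, tn=tn, fn=fn,
                accuracy=(tp + tn) / (n_pos + n_neg),
                tpr=tp / n_pos if n_pos else None,
                fpr=fp / n_neg if n_neg else None,
            )
        )
    return out


def sweep_all(
    records: list[ValidationRecord],
    grids: dict[str, np.ndarray] | None = None,
    chosen: LCThresholds | None = None,
) -> pd.DataFrame:
    """Tidy curve table over all four parameters, with chosen markers.

    The returned frame has one row per (parameter, grid value); the
    ``chosen`` column marks the grid value at or immediately above the
    configured threshold for that parameter (the dashed-line position
    on a calibration plot).
    """
    if not records:
        raise ConfigurationError("no validation records supplied")
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    chosen = chosen or LCThresholds()
    chosen_by_param = {
        "eoo": chosen.eoo_km2,
        "aoo": chosen.aoo_km2,
        "records": float(chosen.record_count),
        "tdwg": float(chosen.tdwg_count),
    }
    rows = []
    for parameter in PARAMETERS:
        pts = sweep(records, parameter, grids[parameter])
        target = chosen_by_param[parameter]
        at_or_above = [p.threshold for p in pts if p.threshold >= target]
        marker = min(at_or_above) if at_or_above else None
        for p in pts:
            rows.append(
                {
                    "parameter": p.parameter, "threshold": p.threshold,
                    "tp": p.tp, "fp": p.fp, "tn": p.tn, "fn": p.fn,
                    "accuracy": p.accuracy, "tpr": p.tpr, "fpr": p.fpr,
                    "chosen": marker is not None and p.threshold == marker,
                }
            )
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def load_validation_csv(path: str | Path) -> list[ValidationRecord]:
    """Read a validation table: name, category and the four metrics."""
    df = pd.read_csv(path)
    required = ["name", "category", "eoo_km2", "aoo_km2", "record_count", "tdwg_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    return [
        ValidationRecord(
            name=str(r["name"]),
            published_category=str(r["category"]),
            metrics=RangeMetrics(
                eoo_km2=float(r["eoo_km2"]),
                aoo_km2=float(r["aoo_km2"]),
                record_count=int(r["record_count"]),
                tdwg_count=int(r["tdwg_count"]),
            ),
        )
        for _, r in df.iterrows()
    ]
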