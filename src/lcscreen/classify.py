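"""Least Concern screening against adjustable thresholds.

A species is flagged as likely Least Concern when all four range
statistics meet or exceed their thresholds (inclusive comparison: a
metric exactly at its threshold passes). The defaults are deliberately
precautionary — chosen to keep false positives (calling a threatened
species Least Concern) rare — and are adjustable per run. A non-empty
warning on the metrics (e.g. no points in the native range) makes the
status undetermined, which is recorded as not-LC with the warning
propagated rather than dropping the species from the results.

Note the screen uses range-based statistics only: range-wide declines
that would trigger the population- or decline-based Red List criteria
must still be considered by the assessor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import RangeMetrics

RESULTS_COLUMNS = [
    "full_name", "powo_id", "eoo_km2", "aoo_km2",
    "record_count", "tdwg_count", "least_concern", "warning",
]


@dataclass(frozen=True)
class LCThresholds:
    """Minimum values for a likely-Least-Concern call (all inclusive)."""

    eoo_km2: float = 30000.0
    aoo_km2: float = 3000.0
    record_count: int = 75
    tdwg_count: int = 5

    def __post_init__(self):
        for name in ("eoo_km2", "aoo_km2", "record_count", "tdwg_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


@dataclass(frozen=True)
class GaugeResult:
    """Per-parameter pass flags plus the combined verdict."""

    eoo_pass: bool
    aoo_pass: bool
    records_pass: bool
    tdwg_pass: bool
    least_concern: bool
    warning: str = ""


@dataclass(frozen=True)
class ResultsRow:
    """One row of the batch results table."""

    full_name: str
    powo_id: str
    eoo_km2: float
    aoo_km2: float
    record_count: int
    tdwg_count: int
    least_concern: bool
    warning: str = ""


def evaluate(metrics: RangeMetrics, thresholds: LCThresholds | None = None) -> GaugeResult:
    """Score one species' metrics against the thresholds.

    Each gauge passes iff its metric meets or exceeds the threshold;
    the species is likely Least Concern iff all four pass and the
    metrics carry no warning (warnings dominate: an undetermined species
    is never reported LC).
    """
    if thresholds is None:
        thresholds = LCThresholds()
    flags = dict(
        eoo_pass=metrics.eoo_km2 >= thresholds.eoo_km2,
        aoo_pass=metrics.aoo_km2 >= thresholds.aoo_km2,
        records_pass=metrics.record_count >= thresholds.record_count,
        tdwg_pass=metrics.tdwg_count >= thresholds.tdwg_count,
    )
    lc = all(flags.values()) and not metrics.warning
    return GaugeResult(least_concern=lc, warning=metrics.warning, **flags)


def classify_batch(
    rows: list[tuple[str, str, RangeMetrics]],
    thresholds: LCThresholds | None = None,
) -> list[ResultsRow]:
    """Build the results table for a batch of (name, checklist id, metrics).

    Row order follows input order; re-running with different thresholds
    changes only the ``least_concern`` flags, never the metrics, so the
    table can be refreshed cheaply as thresholds are adjusted.
    """
    out = []
    for full_name, powo_id, metrics in rows:
        gauge = evaluate(metrics, thresholds)
        out.append(
            ResultsRow(
                full_name=full_name,
                powo_id=powo_id,
                eoo_km2=metrics.eoo_km2,
                aoo_km2=metrics.aoo_km2,
                record_count=metrics.record_count,
                tdwg_count=metrics.tdwg_count,
                least_concern=gauge.least_concern,
                warning=gauge.warning,
            )
        )
    return out


def results_to_frame(rows: list[ResultsRow]) -> pd.DataFrame:
    """Results table as a DataFrame with the fixed column order."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in RESULTS_COLUMNS} for r in rows],
        columns=RESULTS_COLUMNS,
    )
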